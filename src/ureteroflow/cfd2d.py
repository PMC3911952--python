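"""Steady laminar 2D flow at a stent side hole, by finite volumes (SIMPLE).

The computational domain is the extra-luminal gap between the stent outer
wall and the ureter wall, just downstream of a complete occlusion: a
rectangle ``channel_length x gap_height`` (default 10.8 x 1.5 mm) bounded by

* the occluding sphere on the left (``PS``, no-slip wall),
* the stent outer wall below (``SW``, no-slip) perforated by the side hole,
  a segment of width 0.8 mm through which fluid enters at uniform normal
  speed ``v_h`` (``IN``),
* the ureter wall above (``UMW``, no-slip),
* an outflow boundary on the right (``OUT``, zero streamwise gradient with a
  global mass correction).

The incompressible Navier-Stokes equations are discretised on a uniform
staggered grid (pressure at cell centres, velocity components on faces)
with hybrid central/upwind convection, and solved with the SIMPLE
pressure-velocity coupling: an under-relaxed implicit momentum predictor
followed by a pressure-correction Poisson solve, iterated until the scaled
momentum and continuity residuals fall below tolerance.  The dead-end
region between the occlusion and the hole develops slow counter-rotating
eddies, which are characterised from the streamfunction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .hydraulics import FluidSpec
from . import units

__all__ = [
    "DomainSpec2D",
    "Mesh2D",
    "SolverControls",
    "CFDResult",
    "Eddy",
    "CFDError",
    "ConvergenceError",
    "build_domain",
    "mesh_domain",
    "solve_simple",
    "centerline_speed",
    "centerline_minima",
    "detect_eddies",
    "advect_particles",
    "write_vtk",
    "write_field_csv",
]


class CFDError(ValueError):
    """Invalid CFD configuration (geometry, meshing, or regime)."""


class ConvergenceError(RuntimeError):
    """SIMPLE failed to reach the residual tolerance."""

    def __init__(self, message: str, residual_history):
        super().__init__(message)
        self.residual_history = residual_history


@dataclass(frozen=True)
class DomainSpec2D:
    """Rectangular side-hole domain; lengths in mm, x = 0 at the occlusion."""

    channel_length_mm: float = 10.8
    gap_height_mm: float = 1.5
    hole_center_x_mm: float = 5.4
    hole_width_mm: float = 0.8
    inlet_speed_m_s: float = 0.01
    inlet_on: str = "hole"  # "hole" (side hole on y=0) or "left" (plane channel)

    def __post_init__(self) -> None:
        if self.gap_height_mm <= 0 or self.channel_length_mm <= 0:
            raise CFDError("domain extents must be positive")
        if self.inlet_speed_m_s < 0:
            raise CFDError("inlet speed must be non-negative")
        if self.inlet_on not in ("hole", "left"):
            raise CFDError("inlet_on must be 'hole' or 'left'")
        if self.inlet_on == "hole":
            if not 0 < self.hole_width_mm < self.channel_length_mm:
                raise CFDError("need 0 < hole width < channel length")
            if self.hole_left_mm <= 0 or self.hole_right_mm >= self.channel_length_mm:
                raise CFDError("hole segment must lie strictly inside the channel")

    @property
    def hole_left_mm(self) -> float:
        return self.hole_center_x_mm - self.hole_width_mm / 2.0

    @property
    def hole_right_mm(self) -> float:
        return self.hole_center_x_mm + self.hole_width_mm / 2.0


def build_domain(
    occlusion_hole_distance_mm: float = 5.0,
    distance_to: str = "leading_edge",
    **overrides,
) -> DomainSpec2D:
    """Construct the side-hole domain from the occlusion-hole distance.

    The 5 mm occlusion-to-hole distance is measured to the hole *leading
    edge* by default; ``distance_to="center"`` measures it to the hole
    centre instead (the two readings differ by half a hole width).
    """
    hole_width = overrides.pop("hole_width_mm", 0.8)
    if distance_to == "leading_edge":
        center = occlusion_hole_distance_mm + hole_width / 2.0
    elif distance_to == "center":
        center = occlusion_hole_distance_mm
    else:
        raise CFDError("distance_to must be 'leading_edge' or 'center'")
    center = overrides.pop("hole_center_x_mm", center)
    return DomainSpec2D(
        hole_center_x_mm=center, hole_width_mm=hole_width, **overrides
    )


@dataclass(frozen=True)
class Mesh2D:
    """Uniform staggered grid over the domain rectangle."""

    domain: DomainSpec2D
    nx: int
    ny: int
    spacing_mm: float
    inlet_mask: np.ndarray  # bool over the nx bottom faces (hole inlet)

    @property
    def x_faces_mm(self) -> np.ndarray:
        return np.arange(self.nx + 1) * self.spacing_mm

    @property
    def y_faces_mm(self) -> np.ndarray:
        return np.arange(self.ny + 1) * self.spacing_mm

    @property
    def x_centers_mm(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.spacing_mm

    @property
    def y_centers_mm(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.spacing_mm

    def boundary_tags(self) -> dict[str, str]:
        """Human-readable boundary map (tag per wall segment)."""
        tags = {
            "left": "PS",
            "top": "UMW",
            "right": "OUT",
            "bottom": "SW (holes: IN)" if self.inlet_mask.any() else "SW",
        }
        if self.domain.inlet_on == "left":
            tags["left"] = "IN"
        return tags


def mesh_domain(domain: DomainSpec2D, spacing_mm: float) -> Mesh2D:
    """Mesh the domain with uniform square cells of the given spacing."""
    if spacing_mm <= 0:
        raise CFDError("spacing must be positive")
    if domain.inlet_on == "hole" and spacing_mm > domain.hole_width_mm / 4.0 + 1e-12:
        raise CFDError(
            f"spacing {spacing_mm} mm too coarse for the {domain.hole_width_mm} mm "
            "hole (need at least 4 cells across)"
        )
    nx = round(domain.channel_length_mm / spacing_mm)
    ny = round(domain.gap_height_mm / spacing_mm)
    if (
        abs(nx * spacing_mm - domain.channel_length_mm) > spacing_mm / 2
        or abs(ny * spacing_mm - domain.gap_height_mm) > spacing_mm / 2
        or nx < 2
        or ny < 2
    ):
        raise CFDError("spacing must divide the domain extents")
    # snap to an exactly uniform grid
    spacing = domain.channel_length_mm / nx
    if abs(domain.gap_height_mm / ny - spacing) > 1e-9 * spacing:
        raise CFDError("spacing must divide both extents to give square cells")
    xc = (np.arange(nx) + 0.5) * spacing
    if domain.inlet_on == "hole":
        inlet = (xc > domain.hole_left_mm) & (xc < domain.hole_right_mm)
        if not inlet.any():
            raise CFDError("no mesh face falls inside the hole segment")
    else:
        inlet = np.zeros(nx, dtype=bool)
    return Mesh2D(domain, nx, ny, spacing, inlet)


@dataclass(frozen=True)
class SolverControls:
    """SIMPLE iteration controls."""

    alpha_u: float = 0.7
    alpha_p: float = 0.3
    tol: float = 1e-6
    max_iter: int = 50_000
    re_cap: float = 500.0


@dataclass
class CFDResult:
    mesh: Mesh2D
    fluid: FluidSpec
    v_h_m_s: float
    u: np.ndarray  # (nx+1, ny) x-velocity on vertical faces
    v: np.ndarray  # (nx, ny+1) y-velocity on horizontal faces
    p: np.ndarray  # (nx, ny) gauge pressure at centres
    residual_history: list = field(default_factory=list)
    converged: bool = False
    iterations: int = 0

    @property
    def u_centers(self) -> np.ndarray:
        return 0.5 * (self.u[:-1, :] + self.u[1:, :])

    @property
    def v_centers(self) -> np.ndarray:
        return 0.5 * (self.v[:, :-1] + self.v[:, 1:])

    @property
    def speed_centers(self) -> np.ndarray:
        return np.hypot(self.u_centers, self.v_centers)

    def inlet_flux_m2_s(self) -> float:
        h = units.mm_to_m(self.mesh.spacing_mm)
        if self.mesh.domain.inlet_on == "left":
            return float(np.sum(self.u[0, :]) * h)
        return float(np.sum(self.v[self.mesh.inlet_mask, 0]) * h)

    def outlet_flux_m2_s(self) -> float:
        h = units.mm_to_m(self.mesh.spacing_mm)
        return float(np.sum(self.u[-1, :]) * h)

    def mass_defect(self) -> float:
        """|inlet flux - outlet flux| relative to the inlet flux."""
        qin = self.inlet_flux_m2_s()
        if qin == 0.0:
            return abs(self.outlet_flux_m2_s())
        return abs(qin - self.outlet_flux_m2_s()) / abs(qin)

    def streamfunction(self) -> np.ndarray:
        """Streamfunction (m^2/s) on grid nodes, psi=0 at the origin node."""
        h = units.mm_to_m(self.mesh.spacing_mm)
        nx, ny = self.mesh.nx, self.mesh.ny
        psi = np.zeros((nx + 1, ny + 1))
        psi[1:, 0] = -h * np.cumsum(self.v[:, 0])
        psi[:, 1:] = psi[:, [0]] + h * np.cumsum(self.u, axis=1)
        return psi


def _five_point_matrix(aP, aE, aW, aN, aS):
    """Matrix of aP*x - sum(aNb*x_nb) on an (m, n) grid, row-major."""
    m, n = aP.shape
    diags = [aP.ravel()]
    offsets = [0]
    if m > 1:
        diags += [-aE[:-1, :].ravel(), -aW[1:, :].ravel()]
        offsets += [n, -n]
    if n > 1:
        north = aN.copy()
        north[:, -1] = 0.0  # no wraparound across grid rows
        south = aS.copy()
        south[:, 0] = 0.0
        diags += [-north.ravel()[:-1], -south.ravel()[1:]]
        offsets += [1, -1]
    return sp.diags(diags, offsets, shape=(m * n, m * n), format="csc")


class _CachedLUSolver:
    """Direct solver that re-uses an LU factorisation across iterations.

    The five-point matrices drift slowly between SIMPLE iterations (the
    convective coefficients are small against diffusion at these Reynolds
    numbers), so a slightly stale factorisation is an excellent
    preconditioner: a handful of defect-correction sweeps recovers the
    exact solution of the *current* system.
    """

    def __init__(self, refresh_every: int = 25):
        self.refresh_every = refresh_every
        self._lu = None
        self._age = 0

    def solve(self, A, b):
        rhs = b.ravel()
        if self._lu is None or self._age >= self.refresh_every:
            self._lu = spla.splu(A)
            self._age = 0
        self._age += 1
        x = self._lu.solve(rhs)
        norm_b = np.linalg.norm(rhs)
        if norm_b == 0.0:
            return np.zeros_like(b)
        for _ in range(10):
            r = rhs - A @ x
            if np.linalg.norm(r) <= 1e-10 * norm_b:
                break
            x += self._lu.solve(r)
        else:  # stale factorisation no longer contracts: rebuild
            self._lu = spla.splu(A)
            self._age = 1
            x = self._lu.solve(rhs)
        return x.reshape(b.shape)


def solve_simple(
    mesh: Mesh2D,
    fluid: FluidSpec | None = None,
    v_h_m_s: float | None = None,
    controls: SolverControls | None = None,
) -> CFDResult:
    """Solve steady incompressible laminar flow on the meshed domain.

    Raises :class:`CFDError` if the hole Reynolds number exceeds the laminar
    cap, and :class:`ConvergenceError` (carrying the residual history) if
    the iteration stalls above tolerance.
    """
    fluid = fluid or FluidSpec()
    controls = controls or SolverControls()
    dom = mesh.domain
    v_h = dom.inlet_speed_m_s if v_h_m_s is None else float(v_h_m_s)
    if v_h < 0:
        raise CFDError("inlet speed must be non-negative")
    rho, mu = fluid.density_kg_m3, fluid.viscosity_pa_s
    l_char = units.mm_to_m(
        dom.hole_width_mm if dom.inlet_on == "hole" else dom.gap_height_mm
    )
    re = rho * v_h * l_char / mu
    if re > controls.re_cap:
        raise CFDError(
            f"Re = {re:.1f} exceeds the steady-laminar cap {controls.re_cap}"
        )

    nx, ny = mesh.nx, mesh.ny
    h = units.mm_to_m(mesh.spacing_mm)
    u = np.zeros((nx + 1, ny))
    v = np.zeros((nx, ny + 1))
    p = np.zeros((nx, ny))

    # fixed inlet values
    v_bottom = np.zeros(nx)
    u_left = np.zeros(ny)
    if dom.inlet_on == "hole":
        v_bottom[mesh.inlet_mask] = v_h
    else:
        u_left[:] = v_h
    v[:, 0] = v_bottom
    u[0, :] = u_left
    flux_in = (v_bottom.sum() + u_left.sum()) * h

    result = CFDResult(mesh, fluid, v_h, u, v, p)
    if flux_in == 0.0:
        result.converged = True
        return result

    u[-1, :] = flux_in / (ny * h)  # initial outlet guess

    alpha_u, alpha_p = controls.alpha_u, controls.alpha_p
    history: list[dict[str, float]] = []
    lu_u, lu_v, lu_p = _CachedLUSolver(), _CachedLUSolver(), _CachedLUSolver()

    for it in range(1, controls.max_iter + 1):
        # -- outflow: zero-gradient with global mass correction
        flux_out = u[-2, :].sum() * h
        if flux_out > 0.01 * flux_in:
            u[-1, :] = u[-2, :] * (flux_in / flux_out)
        else:
            u[-1, :] = flux_in / (ny * h)

        # -- u momentum (unknowns i = 1..nx-1) --------------------------------
        Fe = rho * h * 0.5 * (u[1:nx, :] + u[2:, :])
        Fw = rho * h * 0.5 * (u[:-2, :] + u[1:nx, :])
        Fn = rho * h * 0.5 * (v[:-1, 1:] + v[1:, 1:])
        Fs = rho * h * 0.5 * (v[:-1, :-1] + v[1:, :-1])
        aE = np.maximum(np.maximum(-Fe, mu - 0.5 * Fe), 0.0)
        aW = np.maximum(np.maximum(Fw, mu + 0.5 * Fw), 0.0)
        aN = np.maximum(np.maximum(-Fn, mu - 0.5 * Fn), 0.0)
        aS = np.maximum(np.maximum(Fs, mu + 0.5 * Fs), 0.0)
        # wall-adjacent CVs: tangential no-slip at half-cell distance
        aS[:, 0] = np.maximum(np.maximum(Fs[:, 0], 2 * mu + 0.5 * Fs[:, 0]), 0.0)
        aN[:, -1] = np.maximum(np.maximum(-Fn[:, -1], 2 * mu - 0.5 * Fn[:, -1]), 0.0)
        aP0u = aE + aW + aN + aS + (Fe - Fw) + (Fn - Fs)
        bu = (p[:-1, :] - p[1:, :]) * h
        bu[0, :] += aW[0, :] * u[0, :]
        bu[-1, :] += aE[-1, :] * u[-1, :]
        # (tangential wall values are zero: no b contribution from aS/aN edges)
        res_u_vec = (
            aP0u * u[1:nx, :]
            - _nb_sum(aE, aW, aN, aS, u[1:nx, :])
            - bu
        )
        scale_u = np.abs(aP0u * u[1:nx, :]).sum()
        res_u = np.abs(res_u_vec).sum() / scale_u if scale_u > 0 else 0.0
        extra = aP0u * (1.0 - alpha_u) / alpha_u
        Au = _five_point_matrix(aP0u + extra, aE, aW, aN, aS)
        u_star = lu_u.solve(Au, bu + extra * u[1:nx, :])

        # -- v momentum (unknowns j = 1..ny-1) --------------------------------
        Fe = rho * h * 0.5 * (u[1:, :-1] + u[1:, 1:])
        Fw = rho * h * 0.5 * (u[:-1, :-1] + u[:-1, 1:])
        Fn = rho * h * 0.5 * (v[:, 1:ny] + v[:, 2:])
        Fs = rho * h * 0.5 * (v[:, :-2] + v[:, 1:ny])
        aE = np.maximum(np.maximum(-Fe, mu - 0.5 * Fe), 0.0)
        aW = np.maximum(np.maximum(Fw, mu + 0.5 * Fw), 0.0)
        aN = np.maximum(np.maximum(-Fn, mu - 0.5 * Fn), 0.0)
        aS = np.maximum(np.maximum(Fs, mu + 0.5 * Fs), 0.0)
        # left boundary: tangential v = 0 (wall, and uniform inlet alike)
        aW[0, :] = np.maximum(np.maximum(Fw[0, :], 2 * mu + 0.5 * Fw[0, :]), 0.0)
        aE[-1, :] = 0.0  # outflow: zero streamwise diffusion of v
        aP0v = aE + aW + aN + aS + (Fe - Fw) + (Fn - Fs)
        bv = (p[:, :-1] - p[:, 1:]) * h
        bv[:, 0] += aS[:, 0] * v[:, 0]
        bv[:, -1] += aN[:, -1] * v[:, -1]
        res_v_vec = (
            aP0v * v[:, 1:ny] - _nb_sum(aE, aW, aN, aS, v[:, 1:ny]) - bv
        )
        scale_v = np.abs(aP0v * v[:, 1:ny]).sum()
        denom = scale_v if scale_v > 0 else max(abs(rho * flux_in * v_h), 1e-300)
        res_v = np.abs(res_v_vec).sum() / denom
        extra = aP0v * (1.0 - alpha_u) / alpha_u
        Av = _five_point_matrix(aP0v + extra, aE, aW, aN, aS)
        v_star = lu_v.solve(Av, bv + extra * v[:, 1:ny])

        u[1:nx, :] = u_star
        v[:, 1:ny] = v_star

        # -- pressure correction ----------------------------------------------
        du = np.zeros((nx + 1, ny))
        du[1:nx, :] = alpha_u * h / aP0u
        dv = np.zeros((nx, ny + 1))
        dv[:, 1:ny] = alpha_u * h / aP0v
        aEp = rho * h * du[1:, :]
        aWp = rho * h * du[:-1, :]
        aNp = rho * h * dv[:, 1:]
        aSp = rho * h * dv[:, :-1]
        bp = rho * h * (u[:-1, :] - u[1:, :] + v[:, :-1] - v[:, 1:])
        res_c = np.abs(bp).sum() / (rho * flux_in)
        aPp = aEp + aWp + aNp + aSp
        aPp[0, 0] += 1e6 * aPp.max()  # pin the pressure-correction level
        Ap = _five_point_matrix(aPp, aEp, aWp, aNp, aSp)
        p_prime = lu_p.solve(Ap, bp)
        p += alpha_p * p_prime
        u[1:nx, :] += du[1:nx, :] * (p_prime[:-1, :] - p_prime[1:, :])
        v[:, 1:ny] += dv[:, 1:ny] * (p_prime[:, :-1] - p_prime[:, 1:])

        history.append({"iter": it, "u": res_u, "v": res_v, "continuity": res_c})
        if it > 1 and max(res_u, res_v, res_c) < controls.tol:
            result.converged = True
            result.iterations = it
            break
    else:
        result.iterations = controls.max_iter
        result.residual_history = history
        raise ConvergenceError(
            f"SIMPLE did not reach tol={controls.tol} in {controls.max_iter} "
            f"iterations (last residuals: {history[-1]})",
            history,
        )

    # final mass-consistent outflow
    flux_out = u[-2, :].sum() * h
    if flux_out > 0:
        u[-1, :] = u[-2, :] * (flux_in / flux_out)
    result.residual_history = history
    return result


def _nb_sum(aE, aW, aN, aS, x):
    """Neighbour-coefficient action within the unknown grid (bc's are in b)."""
    out = np.zeros_like(x)
    out[:-1, :] += aE[:-1, :] * x[1:, :]
    out[1:, :] += aW[1:, :] * x[:-1, :]
    out[:, :-1] += aN[:, :-1] * x[:, 1:]
    out[:, 1:] += aS[:, 1:] * x[:, :-1]
    return out


# -- post-processing ---------------------------------------------------------


def _require_converged(result: CFDResult) -> None:
    if not result.converged:
        raise CFDError("result is not converged; refusing to post-process")


def centerline_speed(result: CFDResult) -> list[tuple[float, float]]:
    """(x_mm, |v|) along the mid-gap line y = gap/2; x = 0 at the occlusion."""
    _require_converged(result)
    mesh = result.mesh
    y_mid = mesh.domain.gap_height_mm / 2.0
    yc = mesh.y_centers_mm
    uc = np.array(
        [np.interp(y_mid, yc, result.u_centers[i, :]) for i in range(mesh.nx)]
    )
    vc = np.array(
        [np.interp(y_mid, yc, result.v_centers[i, :]) for i in range(mesh.nx)]
    )
    speeds = np.hypot(uc, vc)
    return list(zip(mesh.x_centers_mm.tolist(), speeds.tolist()))


def centerline_minima(result: CFDResult, x_max_mm: float | None = None) -> list[float]:
    """x positions of strict local minima of the centreline speed."""
    pts = centerline_speed(result)
    xs = np.array([x for x, _ in pts])
    ss = np.array([s for _, s in pts])
    keep = np.ones_like(xs, dtype=bool) if x_max_mm is None else xs <= x_max_mm
    minima = []
    for i in range(1, len(xs) - 1):
        if keep[i] and ss[i] < ss[i - 1] and ss[i] < ss[i + 1]:
            minima.append(float(xs[i]))
    return minima


@dataclass(frozen=True)
class Eddy:
    """A closed laminar recirculation region."""

    center_x_mm: float
    center_y_mm: float
    sense: int  # +1 counter-clockwise, -1 clockwise
    peak_speed_m_s: float
    streamfunction_m2_s: float


def detect_eddies(result: CFDResult, min_relative_strength: float = 1e-6) -> list[Eddy]:
    """Locate recirculation eddies from streamfunction extrema.

    An eddy is an interior strict local extremum of the streamfunction whose
    same-sign streamfunction region closes inside the domain (it does not
    reach the inlet or outflow boundary).  Counter-clockwise rotation
    corresponds to a streamfunction maximum.  Returns eddies ordered by x.
    """
    _require_converged(result)
    mesh = result.mesh
    psi = result.streamfunction()
    span = np.abs(psi).max()
    if span == 0.0:
        return []
    nx, ny = mesh.nx, mesh.ny

    # node-sampled speed for peak_speed
    u_nodes = np.zeros((nx + 1, ny + 1))
    u_nodes[:, 1:-1] = 0.5 * (result.u[:, :-1] + result.u[:, 1:])
    v_nodes = np.zeros((nx + 1, ny + 1))
    v_nodes[1:-1, :] = 0.5 * (result.v[:-1, :] + result.v[1:, :])
    v_nodes[0, :] = 0.0
    v_nodes[-1, :] = v_nodes[-2, :]
    speed_nodes = np.hypot(u_nodes, v_nodes)

    # open-boundary nodes: outflow column and inlet segment
    open_nodes = np.zeros((nx + 1, ny + 1), dtype=bool)
    open_nodes[-1, :] = True
    if mesh.domain.inlet_on == "left":
        open_nodes[0, :] = True
    else:
        idx = np.where(mesh.inlet_mask)[0]
        if idx.size:
            open_nodes[idx[0] : idx[-1] + 2, 0] = True

    tiny = 1e-9 * span
    pos_lbl, _ = ndimage.label(psi > tiny)
    neg_lbl, _ = ndimage.label(psi < -tiny)

    interior = np.zeros_like(psi, dtype=bool)
    interior[1:-1, 1:-1] = True
    is_max = (psi == ndimage.maximum_filter(psi, size=3)) & interior
    is_min = (psi == ndimage.minimum_filter(psi, size=3)) & interior

    eddies: list[Eddy] = []
    for mask, labels, sense in ((is_max, pos_lbl, +1), (is_min, neg_lbl, -1)):
        cand = np.argwhere(mask & (np.abs(psi) > min_relative_strength * span))
        seen_labels: set[int] = set()
        for i, j in cand:
            lab = labels[i, j]
            if lab == 0 or lab in seen_labels:
                continue
            seen_labels.add(lab)
            region = labels == lab
            exit_nodes = region & open_nodes
            # the recirculation fails to close only if its streamlines
            # actually leave: significant psi on an open boundary
            if exit_nodes.any() and (
                np.abs(psi[exit_nodes]).max() > 1e-3 * abs(psi[i, j])
            ):
                continue
            # take the strongest extremum within the region as the centre
            ri, rj = np.nonzero(region & mask)
            if ri.size == 0:
                ri, rj = np.array([i]), np.array([j])
            k = np.argmax(np.abs(psi[ri, rj]))
            ci, cj = int(ri[k]), int(rj[k])
            eddies.append(
                Eddy(
                    center_x_mm=float(ci * mesh.spacing_mm),
                    center_y_mm=float(cj * mesh.spacing_mm),
                    sense=sense,
                    peak_speed_m_s=float(speed_nodes[region].max()),
                    streamfunction_m2_s=float(psi[ci, cj]),
                )
            )
    eddies.sort(key=lambda e: e.center_x_mm)
    return eddies


def match_eddies(
    reference: list[Eddy], other: list[Eddy]
) -> list[tuple[Eddy, Eddy]]:
    """Pair each reference eddy with the nearest same-sense eddy in ``other``.

    Used to track how an eddy responds when a control parameter (e.g. the
    hole exit velocity) changes; unmatched eddies are dropped.
    """
    pairs: list[tuple[Eddy, Eddy]] = []
    for ref in reference:
        candidates = [e for e in other if e.sense == ref.sense]
        if candidates:
            pairs.append(
                (ref, min(candidates, key=lambda e: abs(e.center_x_mm - ref.center_x_mm)))
            )
    return pairs


# -- particle pathlines ------------------------------------------------------


@dataclass(frozen=True)
class StepControl:
    """Adaptive explicit integration controls for pathlines."""

    cfl: float = 0.25
    max_steps: int = 50_000
    max_length_mm: float | None = None


def _velocity_interpolators(result: CFDResult):
    from scipy.interpolate import RegularGridInterpolator

    mesh = result.mesh
    h = mesh.spacing_mm
    L, H = mesh.domain.channel_length_mm, mesh.domain.gap_height_mm
    # u lives on x-faces / y-centres; pad walls (u = 0 on top/bottom)
    xu = mesh.x_faces_mm
    yu = np.concatenate(([0.0], mesh.y_centers_mm, [H]))
    uu = np.zeros((len(xu), len(yu)))
    uu[:, 1:-1] = result.u
    # v lives on x-centres / y-faces; pad left wall (v = 0) and outlet (copy)
    xv = np.concatenate(([0.0], mesh.x_centers_mm, [L]))
    yv = mesh.y_faces_mm
    vv = np.zeros((len(xv), len(yv)))
    vv[1:-1, :] = result.v
    vv[-1, :] = result.v[-1, :]
    fu = RegularGridInterpolator((xu, yu), uu, bounds_error=False, fill_value=0.0)
    fv = RegularGridInterpolator((xv, yv), vv, bounds_error=False, fill_value=0.0)
    return fu, fv


def advect_particles(
    result: CFDResult,
    seed_points_mm,
    step_control: StepControl | None = None,
) -> list[np.ndarray | None]:
    """Integrate pathlines of the steady field from seed points (mm).

    Returns one ``(n, 2)`` array of mm coordinates per seed (RK4 with a
    speed-adaptive step), or ``None`` with a raised error recorded for
    seeds outside the domain.
    """
    _require_converged(result)
    ctrl = step_control or StepControl()
    mesh = result.mesh
    L, H = mesh.domain.channel_length_mm, mesh.domain.gap_height_mm
    max_len = ctrl.max_length_mm if ctrl.max_length_mm is not None else 20.0 * L
    fu, fv = _velocity_interpolators(result)
    h_mm = mesh.spacing_mm

    def vel(pt):  # mm -> mm/s
        q = np.atleast_2d(pt)
        return np.array([fu(q)[0], fv(q)[0]]) * 1e3

    paths: list[np.ndarray | None] = []
    for seed in seed_points_mm:
        x0 = np.asarray(seed, dtype=float)
        if not (0.0 <= x0[0] <= L and 0.0 <= x0[1] <= H):
            raise CFDError(f"seed {seed} lies outside the domain")
        pts = [x0.copy()]
        arc = 0.0
        x = x0.copy()
        for _ in range(ctrl.max_steps):
            v1 = vel(x)
            speed = float(np.hypot(*v1))
            if speed < 1e-15:
                break
            dt = ctrl.cfl * h_mm / speed
            k1 = v1
            k2 = vel(x + 0.5 * dt * k1)
            k3 = vel(x + 0.5 * dt * k2)
            k4 = vel(x + dt * k3)
            step = dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            x = x + step
            arc += float(np.hypot(*step))
            pts.append(x.copy())
            if not (0.0 <= x[0] <= L and 0.0 <= x[1] <= H):
                break
            if arc > max_len:
                break
        paths.append(np.array(pts))
    return paths


# -- field output ------------------------------------------------------------


def write_vtk(result: CFDResult, path) -> None:
    """Write cell-centre fields as a legacy ASCII structured-points VTK file."""
    mesh = result.mesh
    nx, ny = mesh.nx, mesh.ny
    h = mesh.spacing_mm
    uc, vc, p = result.u_centers, result.v_centers, result.p
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("ureteroflow side-hole flow field\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} 1\n")
        f.write(f"ORIGIN {h / 2} {h / 2} 0\n")
        f.write(f"SPACING {h} {h} 1\n")
        f.write(f"POINT_DATA {nx * ny}\n")
        f.write("VECTORS velocity double\n")
        for j in range(ny):
            for i in range(nx):
                f.write(f"{uc[i, j]:.9e} {vc[i, j]:.9e} 0.0\n")
        f.write("SCALARS pressure double 1\nLOOKUP_TABLE default\n")
        for j in range(ny):
            for i in range(nx):
                f.write(f"{p[i, j]:.9e}\n")


def write_field_csv(result: CFDResult, path) -> None:
    """Write cell-centre fields as long-format CSV x_mm,y_mm,u,v,p."""
    mesh = result.mesh
    xc, yc = mesh.x_centers_mm, mesh.y_centers_mm
    uc, vc, p = result.u_centers, result.v_centers, result.p
    with open(path, "w") as f:
        f.write("x_mm,y_mm,u,v,p\n")
        for i in range(mesh.nx):
            for j in range(mesh.ny):
                f.write(
                    f"{xc[i]:.6g},{yc[j]:.6g},{uc[i, j]:.9e},"
                    f"{vc[i, j]:.9e},{p[i, j]:.9e}\n"
                )
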