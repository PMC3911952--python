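"""Lumped laminar-resistance model of the stented, obstructed ureter.

The conduit is represented as a resistor network between the renal-pelvis
node (flow source, pressure unknown) and the bladder node (open end, gauge
pressure 0).  Urine can travel intra-luminally through the stent, or
extra-luminally through the annular space between stent outer wall and
ureter inner wall; stent side holes couple the two paths, and a drilled
sphere lodged in the upper tract throttles (or, at OB% = 100, severs) the
extra-luminal path.

Branch closures are fully developed laminar (creeping-flow) solutions:
Hagen-Poiseuille for circular conduits, the concentric-annulus solution for
the extra-luminal space, and a short-pipe approximation for side holes.
Because every branch is linear in flow, renal pelvic pressure is exactly
linear in the inflow rate and in viscosity; the pressure/flow slope is the
hydraulic resistance ``m`` in cmH2O/(ml/min).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from . import units
from .geometry import (
    GeometryError,
    ObstructionSpec,
    StentSpec,
    UreterProfile,
)

__all__ = [
    "FluidSpec",
    "Branch",
    "HydraulicNetwork",
    "NetworkSolution",
    "PressureMap",
    "NetworkError",
    "pipe_resistance",
    "tapered_pipe_resistance",
    "annulus_resistance",
    "orifice_resistance",
    "build_network",
    "solve_network",
    "hydraulic_resistance",
    "classify_pressure",
    "pressure_map",
    "PRESSURE_SAFE_MAX_CMH2O",
    "PRESSURE_DANGEROUS_MIN_CMH2O",
]

#: Renal pelvic pressure below this is safe for the kidney (cmH2O).
PRESSURE_SAFE_MAX_CMH2O = 15.0
#: Above this the pressure may cause irreversible kidney damage (cmH2O).
PRESSURE_DANGEROUS_MIN_CMH2O = 20.0


class NetworkError(ValueError):
    """Ill-posed hydraulic network (disconnected, non-physical resistance)."""


@dataclass(frozen=True)
class FluidSpec:
    """Working-fluid properties (urine analogue: water/glycerol mixtures)."""

    density_kg_m3: float = 1000.0
    viscosity_pa_s: float = 1e-3

    def __post_init__(self) -> None:
        if self.density_kg_m3 <= 0 or self.viscosity_pa_s <= 0:
            raise NetworkError("density and viscosity must be positive")

    @classmethod
    def from_cp(cls, viscosity_cp: float, density_kg_m3: float = 1000.0):
        return cls(density_kg_m3, units.cp_to_pas(viscosity_cp))

    @property
    def viscosity_cp(self) -> float:
        return self.viscosity_pa_s / units.PAS_PER_CP


# -- branch closures (SI units) ---------------------------------------------


def pipe_resistance(diameter_m: float, length_m: float, viscosity_pa_s: float) -> float:
    """Hagen-Poiseuille resistance 128*mu*L/(pi*D^4) of a circular pipe."""
    if diameter_m <= 0 or length_m <= 0 or viscosity_pa_s <= 0:
        raise NetworkError("pipe_resistance arguments must be positive")
    return 128.0 * viscosity_pa_s * length_m / (math.pi * diameter_m**4)


def tapered_pipe_resistance(
    d_in_m: float, d_out_m: float, length_m: float, viscosity_pa_s: float
) -> float:
    """Resistance of a linearly tapering circular pipe.

    Integrates 128*mu/(pi*D(x)^4) dx in closed form; reduces to
    :func:`pipe_resistance` for a uniform bore.
    """
    if d_in_m <= 0 or d_out_m <= 0 or length_m <= 0 or viscosity_pa_s <= 0:
        raise NetworkError("tapered_pipe_resistance arguments must be positive")
    if abs(d_out_m - d_in_m) < 1e-12 * max(d_in_m, d_out_m):
        return pipe_resistance(0.5 * (d_in_m + d_out_m), length_m, viscosity_pa_s)
    integral = (
        length_m / (3.0 * (d_out_m - d_in_m)) * (1.0 / d_in_m**3 - 1.0 / d_out_m**3)
    )
    return 128.0 * viscosity_pa_s / math.pi * integral


def annulus_resistance(
    outer_diameter_m: float,
    inner_diameter_m: float,
    length_m: float,
    viscosity_pa_s: float,
) -> float:
    """Laminar resistance of a concentric annular duct.

    Uses the classical solution for pressure-driven flow between coaxial
    cylinders: Q = pi*dP/(8*mu*L) * [Ro^4 - Ri^4 - (Ro^2 - Ri^2)^2/ln(Ro/Ri)].
    """
    if inner_diameter_m >= outer_diameter_m:
        raise NetworkError("annulus requires inner diameter < outer diameter")
    if inner_diameter_m <= 0 or length_m <= 0 or viscosity_pa_s <= 0:
        raise NetworkError("annulus_resistance arguments must be positive")
    ro = outer_diameter_m / 2.0
    ri = inner_diameter_m / 2.0
    geom = ro**4 - ri**4 - (ro**2 - ri**2) ** 2 / math.log(ro / ri)
    return 8.0 * viscosity_pa_s * length_m / (math.pi * geom)


def orifice_resistance(
    hole_diameter_m: float, wall_thickness_m: float, viscosity_pa_s: float
) -> float:
    """Side hole modelled as a short pipe across the stent wall."""
    if hole_diameter_m <= 0 or viscosity_pa_s <= 0 or wall_thickness_m < 0:
        raise NetworkError("orifice_resistance arguments must be positive")
    if wall_thickness_m == 0:
        return 0.0
    return pipe_resistance(hole_diameter_m, wall_thickness_m, viscosity_pa_s)


# -- network assembly --------------------------------------------------------


@dataclass(frozen=True)
class Branch:
    node_a: str
    node_b: str
    resistance_pa_s_m3: float
    kind: str  # lumen | annulus | hole | obstruction_gap

    def __post_init__(self) -> None:
        if self.resistance_pa_s_m3 < 0:
            raise NetworkError("branch resistance must be non-negative")


@dataclass
class HydraulicNetwork:
    """Resistor graph between the ``pelvis`` and ``bladder`` terminal nodes."""

    branches: list[Branch] = field(default_factory=list)
    pelvis: str = "pelvis"
    bladder: str = "bladder"

    def add(self, a: str, b: str, resistance: float, kind: str) -> None:
        self.branches.append(Branch(a, b, resistance, kind))

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for br in self.branches:
            seen.setdefault(br.node_a)
            seen.setdefault(br.node_b)
        return list(seen)

    def pruned(self) -> "HydraulicNetwork":
        """Drop dead-end sub-branches that cannot carry flow."""
        branches = list(self.branches)
        while True:
            degree: dict[str, int] = defaultdict(int)
            for br in branches:
                degree[br.node_a] += 1
                degree[br.node_b] += 1
            dead = {
                n
                for n, d in degree.items()
                if d <= 1 and n not in (self.pelvis, self.bladder)
            }
            if not dead:
                return HydraulicNetwork(branches, self.pelvis, self.bladder)
            branches = [
                br
                for br in branches
                if br.node_a not in dead and br.node_b not in dead
            ]


def _annulus_interval_resistance(
    profile: UreterProfile,
    stent: StentSpec,
    x0_mm: float,
    x1_mm: float,
    mu: float,
    n_sub: int = 8,
) -> float:
    """Series resistance of the extra-luminal space over [x0, x1] mm.

    The ureter bore varies axially; the interval is subdivided and each
    piece treated as a concentric annulus at its midpoint diameter.
    """
    total = 0.0
    edges = np.linspace(x0_mm, x1_mm, n_sub + 1)
    for a, b in zip(edges[:-1], edges[1:]):
        d_o = profile.diameter_at(0.5 * (a + b))
        total += annulus_resistance(
            units.mm_to_m(d_o),
            units.mm_to_m(stent.outer_diameter_mm),
            units.mm_to_m(b - a),
            mu,
        )
    return total


def build_network(
    profile: UreterProfile,
    stent: StentSpec | None = None,
    obstruction: ObstructionSpec | None = None,
    fluid: FluidSpec | None = None,
    side_holes: bool = True,
) -> HydraulicNetwork:
    """Assemble the resistor network for a (possibly stented) ureter.

    Without a stent the model is the bare conduit: a series chain of
    linearly tapering pipe segments between profile stations.  With a stent,
    an intra-luminal chain spans the full stent length (pelvic curl opening
    to bladder opening), an extra-luminal annulus chain spans the conduit,
    and one orifice branch per side hole couples the two; holes at negative
    axial coordinate sit in the renal-pelvis curl and open directly into the
    pelvis.  A sphere obstruction splits the annulus at its plane, inserting
    a short annular gap branch of area ``A_gap`` (omitted when A_gap = 0,
    i.e. OB% = 100, so no extra-luminal branch crosses the obstruction).
    """
    fluid = fluid or FluidSpec()
    mu = fluid.viscosity_pa_s
    net = HydraulicNetwork()
    L = profile.length_mm
    pos = profile.section_positions_mm

    if stent is None:
        if obstruction is not None:
            raise NetworkError("sphere obstruction requires a stent to thread")
        prev = net.pelvis
        for k in range(profile.n_sections - 1):
            nxt = net.bladder if k == profile.n_sections - 2 else f"x@{pos[k + 1]:.3f}"
            r = tapered_pipe_resistance(
                units.mm_to_m(profile.diameters_mm[k]),
                units.mm_to_m(profile.diameters_mm[k + 1]),
                units.mm_to_m(pos[k + 1] - pos[k]),
                mu,
            )
            net.add(prev, nxt, r, "lumen")
            prev = nxt
        return net

    if stent.length_mm < L:
        raise NetworkError("stent shorter than the ureter conduit")
    a_s = stent.cross_section_mm2
    for i, area in enumerate(profile.areas_mm2):
        if area < a_s - 1e-12:
            raise GeometryError(
                f"stent does not fit ureter section i={i} "
                f"(A_i={area:.4g} < A_s={a_s:.4g} mm^2)"
            )

    # Map conduit coordinate x (0 at UPJ) onto lumen arc length s, with the
    # extra stent length split evenly between the two curls.
    s0 = (stent.length_mm - L) / 2.0
    stent_len = stent.length_mm

    holes = stent.hole_positions_mm(up_to_mm=L) if side_holes else []
    holes = [x for x in holes if 0.0 < x + s0 < stent_len]
    conduit_holes = [x for x in holes if 0.0 < x < L]

    x_ob = None
    if obstruction is not None:
        idx = obstruction.axial_position_index
        if not 0 <= idx < profile.n_sections - 1:
            raise NetworkError(f"obstruction section index {idx} out of range")
        x_ob = 0.5 * (pos[idx] + pos[idx + 1])
        if side_holes:
            k = sum(1 for x in conduit_holes if x < x_ob)
            if k == 0 or k == len(conduit_holes):
                raise NetworkError(
                    "obstruction plane does not lie between two side holes"
                )

    # Intra-luminal chain with a node at every hole's arc position.
    lumen_nodes = [(x + s0, f"lum@{x:.3f}") for x in holes]
    r_hole = orifice_resistance(
        units.mm_to_m(stent.hole_diameter_mm),
        units.mm_to_m(stent.wall_thickness_mm),
        mu,
    )
    chain = [(0.0, net.pelvis)] + lumen_nodes + [(stent_len, net.bladder)]
    d_in = units.mm_to_m(stent.inner_diameter_mm)
    for (s_a, na), (s_b, nb) in zip(chain[:-1], chain[1:]):
        net.add(na, nb, pipe_resistance(d_in, units.mm_to_m(s_b - s_a), mu), "lumen")

    # Extra-luminal annulus chain with breakpoints at in-conduit holes and,
    # if present, at the obstruction plane.
    ann_break: list[tuple[float, str]] = [(0.0, net.pelvis)]
    for x in conduit_holes:
        ann_break.append((x, f"ann@{x:.3f}"))
    if x_ob is not None:
        r_sph = obstruction.sphere_diameter_mm / 2.0
        ann_break.append((max(x_ob - r_sph, 0.0), "ann@ob_up"))
        ann_break.append((min(x_ob + r_sph, L), "ann@ob_dn"))
    ann_break.append((L, net.bladder))
    ann_break.sort(key=lambda t: t[0])
    for (xa, na), (xb, nb) in zip(ann_break[:-1], ann_break[1:]):
        if x_ob is not None and na == "ann@ob_up" and nb == "ann@ob_dn":
            gap = obstruction.gap_area_mm2(stent)
            if gap <= 1e-12:
                continue  # complete occlusion: annulus severed here
            d_gap_outer = math.sqrt(stent.outer_diameter_mm**2 + 4.0 * gap / math.pi)
            r_gap = annulus_resistance(
                units.mm_to_m(d_gap_outer),
                units.mm_to_m(stent.outer_diameter_mm),
                units.mm_to_m(obstruction.sphere_diameter_mm),
                mu,
            )
            net.add(na, nb, r_gap, "obstruction_gap")
        elif xb - xa > 1e-9:
            r_ann = _annulus_interval_resistance(profile, stent, xa, xb, mu)
            net.add(na, nb, r_ann, "annulus")

    # Side-hole orifices couple lumen to annulus (or to the pelvis chamber
    # for holes on the pelvic curl).
    for x in holes:
        lum = f"lum@{x:.3f}"
        if x <= 0.0:
            net.add(lum, net.pelvis, r_hole, "hole")
        else:
            net.add(lum, f"ann@{x:.3f}", r_hole, "hole")
    return net


# -- nodal solution ----------------------------------------------------------


@dataclass(frozen=True)
class NetworkSolution:
    nodal_pressures_pa: dict[str, float]
    branch_flows_m3_s: tuple[float, ...]
    branches: tuple[Branch, ...]
    inflow_ml_min: float

    @property
    def pelvic_pressure_cmh2o(self) -> float:
        return units.pa_to_cmh2o(self.nodal_pressures_pa["pelvis"])

    @property
    def hydraulic_resistance_cmh2o_per_ml_min(self) -> float:
        if self.inflow_ml_min == 0:
            return float("nan")
        return self.pelvic_pressure_cmh2o / self.inflow_ml_min

    def max_conservation_defect(self) -> float:
        """Largest nodal flow imbalance relative to the inflow."""
        net_flow: dict[str, float] = defaultdict(float)
        for br, q in zip(self.branches, self.branch_flows_m3_s):
            net_flow[br.node_a] -= q
            net_flow[br.node_b] += q
        q_in = units.ml_min_to_m3s(self.inflow_ml_min)
        scale = abs(q_in) if q_in else 1.0
        worst = 0.0
        for node, f in net_flow.items():
            if node in ("pelvis", "bladder"):
                continue
            worst = max(worst, abs(f) / scale)
        return worst


def _connected(net: HydraulicNetwork) -> bool:
    adj: dict[str, list[str]] = defaultdict(list)
    for br in net.branches:
        adj[br.node_a].append(br.node_b)
        adj[br.node_b].append(br.node_a)
    stack, seen = [net.pelvis], {net.pelvis}
    while stack:
        n = stack.pop()
        if n == net.bladder:
            return True
        for m in adj[n]:
            if m not in seen:
                seen.add(m)
                stack.append(m)
    return False


def solve_network(net: HydraulicNetwork, inflow_ml_min: float) -> NetworkSolution:
    """Nodal analysis: inject the inflow at the pelvis, ground the bladder.

    Solves the symmetric positive-definite nodal-conductance system and
    returns nodal pressures (Pa gauge) and signed branch flows.
    """
    if inflow_ml_min < 0:
        raise NetworkError("inflow must be non-negative")
    net = net.pruned()
    if not _connected(net):
        raise NetworkError("pelvis and bladder are not hydraulically connected")
    nodes = [n for n in net.nodes if n != net.bladder]
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    g = np.zeros((n, n))
    for br in net.branches:
        cond = 1.0 / br.resistance_pa_s_m3
        ia = index.get(br.node_a)
        ib = index.get(br.node_b)
        if ia is not None:
            g[ia, ia] += cond
        if ib is not None:
            g[ib, ib] += cond
        if ia is not None and ib is not None:
            g[ia, ib] -= cond
            g[ib, ia] -= cond
    rhs = np.zeros(n)
    rhs[index[net.pelvis]] = units.ml_min_to_m3s(inflow_ml_min)
    p = np.linalg.solve(g, rhs)
    pressures = {net.bladder: 0.0}
    pressures.update({node: float(p[i]) for node, i in index.items()})
    flows = tuple(
        (pressures[br.node_a] - pressures[br.node_b]) / br.resistance_pa_s_m3
        for br in net.branches
    )
    return NetworkSolution(pressures, flows, tuple(net.branches), inflow_ml_min)


def hydraulic_resistance(net: HydraulicNetwork) -> float:
    """Pressure/flow slope m in cmH2O/(ml/min) (network is linear, zero offset)."""
    sol = solve_network(net, 1.0)
    return sol.pelvic_pressure_cmh2o


# -- pressure classification and maps ---------------------------------------


def classify_pressure(p_cmh2o: float) -> str:
    """Clinical banding of renal pelvic pressure: safe / warning / dangerous.

    Below 15 cmH2O is safe, above 20 cmH2O risks kidney damage; the band
    boundaries themselves are assigned to ``warning``.
    """
    if not math.isfinite(p_cmh2o):
        raise NetworkError("pressure must be finite")
    if p_cmh2o < 0:
        raise NetworkError("pressure must be non-negative")
    if p_cmh2o < PRESSURE_SAFE_MAX_CMH2O:
        return "safe"
    if p_cmh2o <= PRESSURE_DANGEROUS_MIN_CMH2O:
        return "warning"
    return "dangerous"


@dataclass(frozen=True)
class PressureMap:
    q_values_ml_min: tuple[float, ...]
    mu_values_cp: tuple[float, ...]
    pressure_grid_cmh2o: np.ndarray  # shape (len(q), len(mu))
    class_grid: np.ndarray  # same shape, dtype=object

    def to_records(self) -> list[dict]:
        rows = []
        for i, q in enumerate(self.q_values_ml_min):
            for j, mu in enumerate(self.mu_values_cp):
                rows.append(
                    {
                        "q_ml_min": q,
                        "mu_cP": mu,
                        "pressure_cmH2O": float(self.pressure_grid_cmh2o[i, j]),
                        "region": str(self.class_grid[i, j]),
                    }
                )
        return rows


def pressure_map(
    profile: UreterProfile,
    stent: StentSpec | None,
    obstruction: ObstructionSpec | None,
    q_values_ml_min,
    mu_values_cp,
    side_holes: bool = True,
) -> PressureMap:
    """Pelvic pressure and clinical banding over a (Q, mu) grid."""
    q_values = tuple(float(q) for q in q_values_ml_min)
    mu_values = tuple(float(m) for m in mu_values_cp)
    if not q_values or not mu_values:
        raise NetworkError("q_values and mu_values must be non-empty")
    grid = np.zeros((len(q_values), len(mu_values)))
    classes = np.empty_like(grid, dtype=object)
    for j, mu in enumerate(mu_values):
        net = build_network(
            profile, stent, obstruction, FluidSpec.from_cp(mu), side_holes
        )
        m = hydraulic_resistance(net)  # linear: one solve per viscosity
        for i, q in enumerate(q_values):
            p = m * q
            grid[i, j] = p
            classes[i, j] = classify_pressure(p)
    return PressureMap(q_values, mu_values, grid, classes)
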