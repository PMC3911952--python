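"""Synthetic inputs with the statistical structure of the bench study.

Everything the pipeline consumes can be generated here so that no stage
depends on an external download:

* a 16-station tapering pig-ureter diameter profile (length ~289 mm,
  narrowest station 2.2 mm at index 12, wide enough proximally for a
  6 mm sphere to lodge between the first two stations);
* replicate renal-pelvic-pressure recordings over the experimental grid
  (flow rates 5-20 ml/min, viscosities 1-6 cP, obstruction levels from the
  bare conduit through OB% = 100), linear in flow with additive Gaussian
  noise truncated at zero;
* analytic divergence-free vortex fields with known centres, as ground
  truth for the eddy detector.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .cfd2d import CFDResult, Mesh2D, CFDError
from .geometry import (
    GeometryError,
    ObstructionSpec,
    StentSpec,
    UreterProfile,
    circle_area,
    hole_area_for_severity,
)
from .hydraulics import FluidSpec, build_network, hydraulic_resistance
from .regression import PressureRecording, PressureRecordingSet
from . import units

__all__ = [
    "SynthConfig",
    "synth_ureter_profile",
    "make_network_model",
    "synth_pressure_recordings",
    "synth_vortex_field",
]

#: Experimental grid of the bench study.
DEFAULT_Q_ML_MIN = (5.0, 10.0, 15.0, 20.0)
DEFAULT_MU_CP = (1.0, 1.3, 1.7, 2.5, 3.7, 6.0)
DEFAULT_OB_LEVELS = (
    "0",
    "only_stent",
    "81",
    "84",
    "88",
    "91",
    "94",
    "96",
    "99",
    "100",
)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults are the study conditions."""

    seed: int = 0
    noise_sd_cmh2o: float = 0.1
    replicates: int = 3
    length_mean_mm: float = 289.0
    length_sd_mm: float = 20.0
    min_diameter_mm: float = 2.2
    min_diameter_index: int = 12
    n_stations: int = 16
    proximal_diameter_mm: float = 6.8
    distal_diameter_mm: float = 2.6
    diameter_jitter_sd_mm: float = 0.05
    stent_od_mm: float | None = 2.08
    q_values_ml_min: tuple[float, ...] = DEFAULT_Q_ML_MIN
    mu_values_cp: tuple[float, ...] = DEFAULT_MU_CP
    ob_levels: tuple[str, ...] = DEFAULT_OB_LEVELS

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd_cmh2o < 0:
            raise ValueError("noise sd must be non-negative")
        if not 0 < self.min_diameter_index < self.n_stations - 1:
            raise ValueError("minimum-diameter index must be interior")
        if (
            self.stent_od_mm is not None
            and self.min_diameter_mm < self.stent_od_mm
        ):
            raise GeometryError(
                "minimum-diameter target is below the stent outer diameter: "
                "the stent would not fit"
            )


def synth_ureter_profile(config: SynthConfig | None = None) -> UreterProfile:
    """Sample a tapering ureter profile consistent with the printed anchors.

    The deterministic base shape tapers from a wide upper tract to its
    single minimum at ``min_diameter_index``, then widens slightly toward
    the bladder.  Seeded Gaussian jitter perturbs every station except the
    minimum, which is pinned to the target; other stations are kept above
    it so the minimum's location is invariant.  Length is drawn from a
    normal with the configured mean/sd (exact at sd = 0), floored at half
    the mean to stay physical.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    i_min = cfg.min_diameter_index
    n = cfg.n_stations
    idx = np.arange(n, dtype=float)
    diam = np.empty(n)
    upper = idx <= i_min
    diam[upper] = cfg.min_diameter_mm + (
        cfg.proximal_diameter_mm - cfg.min_diameter_mm
    ) * ((i_min - idx[upper]) / i_min) ** 1.3
    lower = ~upper
    diam[lower] = cfg.min_diameter_mm + (
        cfg.distal_diameter_mm - cfg.min_diameter_mm
    ) * ((idx[lower] - i_min) / (n - 1 - i_min)) ** 1.5
    jitter = rng.normal(0.0, cfg.diameter_jitter_sd_mm, size=n)
    diam = diam + jitter
    diam[i_min] = cfg.min_diameter_mm  # printed anchor
    floor = cfg.min_diameter_mm + 0.05
    if cfg.stent_od_mm is not None:
        floor = max(floor, cfg.stent_od_mm + 0.05)
    other = np.arange(n) != i_min
    diam[other] = np.maximum(diam[other], floor)
    length = float(rng.normal(cfg.length_mean_mm, cfg.length_sd_mm))
    length = max(length, cfg.length_mean_mm / 2.0)
    return UreterProfile(tuple(diam), length)


def make_network_model(
    profile: UreterProfile,
    stent: StentSpec | None = None,
    sphere_diameter_mm: float = 6.07,
    obstruction_index: int = 0,
) -> Callable[[float, float, str], float]:
    """Pelvic-pressure predictor (q, mu, ob_label) -> cmH2O from the
    lumped network.

    ``ob_label`` selects the configuration: ``"0"`` is the bare conduit,
    ``"only_stent"`` the stented unobstructed ureter, and a numeric label
    adds a drilled sphere realising that OB% level.
    """
    stent = stent or StentSpec()
    sphere_area = circle_area(sphere_diameter_mm)
    cache: dict[tuple[float, str], float] = {}

    def predict(q_ml_min: float, mu_cp: float, ob_label: str) -> float:
        key = (mu_cp, ob_label)
        if key not in cache:
            fluid = FluidSpec.from_cp(mu_cp)
            if ob_label == "0":
                net = build_network(profile, None, None, fluid)
            elif ob_label == "only_stent":
                net = build_network(profile, stent, None, fluid)
            else:
                hole = hole_area_for_severity(
                    float(ob_label), sphere_area, stent.cross_section_mm2
                )
                obstruction = ObstructionSpec(
                    sphere_diameter_mm, hole, obstruction_index
                )
                net = build_network(profile, stent, obstruction, fluid)
            cache[key] = hydraulic_resistance(net)
        return cache[key] * q_ml_min

    return predict


def synth_pressure_recordings(
    network_model: Callable[[float, float, str], float],
    config: SynthConfig | None = None,
) -> PressureRecordingSet:
    """Replicate pressure recordings over the experimental grid.

    Each recording is the model prediction plus seeded Gaussian noise of
    sd ``noise_sd_cmh2o``, truncated at zero (a water-column transducer
    cannot read negative gauge pressure against an open bladder).
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed + 1)  # independent of profile draw
    records: list[PressureRecording] = []
    for ob in cfg.ob_levels:
        for mu in cfg.mu_values_cp:
            for q in cfg.q_values_ml_min:
                try:
                    p_true = network_model(q, mu, ob)
                except Exception as exc:
                    raise RuntimeError(
                        f"model unsolvable at (q={q}, mu={mu}, ob={ob})"
                    ) from exc
                for rep in range(cfg.replicates):
                    noise = (
                        rng.normal(0.0, cfg.noise_sd_cmh2o)
                        if cfg.noise_sd_cmh2o > 0
                        else 0.0
                    )
                    records.append(
                        PressureRecording(
                            q, mu, str(ob), rep, max(p_true + noise, 0.0)
                        )
                    )
    return PressureRecordingSet(tuple(records))


def synth_vortex_field(
    centers_mm,
    strengths_m2_s,
    mesh: Mesh2D,
    core_sigma_mm: float = 0.3,
) -> CFDResult:
    """Analytic superposition of Gaussian-streamfunction vortices on a mesh.

    Each vortex contributes ``psi_k = S_k * exp(-r^2 / (2 sigma^2))`` so the
    sampled field is divergence-free by construction and every centre is a
    known streamfunction extremum (positive strength = counter-clockwise).
    Returned as a converged :class:`CFDResult` for the post-processing
    stages to consume.
    """
    centers = [tuple(map(float, c)) for c in centers_mm]
    strengths = [float(s) for s in strengths_m2_s]
    if len(centers) != len(strengths):
        raise ValueError("one strength per centre required")
    L, H = mesh.domain.channel_length_mm, mesh.domain.gap_height_mm
    for cx, cy in centers:
        if not (0.0 < cx < L and 0.0 < cy < H):
            raise CFDError(f"vortex centre ({cx}, {cy}) outside the domain")
    sigma = units.mm_to_m(core_sigma_mm)

    def u_of(x, y):  # d(psi)/dy
        out = np.zeros(np.broadcast(x, y).shape)
        for (cx, cy), s in zip(centers, strengths):
            dx = x - units.mm_to_m(cx)
            dy = y - units.mm_to_m(cy)
            out += -s * dy / sigma**2 * np.exp(-(dx**2 + dy**2) / (2 * sigma**2))
        return out

    def v_of(x, y):  # -d(psi)/dx
        out = np.zeros(np.broadcast(x, y).shape)
        for (cx, cy), s in zip(centers, strengths):
            dx = x - units.mm_to_m(cx)
            dy = y - units.mm_to_m(cy)
            out += s * dx / sigma**2 * np.exp(-(dx**2 + dy**2) / (2 * sigma**2))
        return out

    xf = units.mm_to_m(mesh.x_faces_mm)
    yc = units.mm_to_m(mesh.y_centers_mm)
    xc = units.mm_to_m(mesh.x_centers_mm)
    yf = units.mm_to_m(mesh.y_faces_mm)
    u = u_of(xf[:, None], yc[None, :])
    v = v_of(xc[:, None], yf[None, :])
    p = np.zeros((mesh.nx, mesh.ny))
    result = CFDResult(mesh, FluidSpec(), 0.0, u, v, p)
    result.converged = True
    return result
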