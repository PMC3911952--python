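"""End-to-end reproducible pipeline: geometry -> network -> stats -> CFD.

``run_paper_pipeline`` drives the full study sequence from a single config
mapping: synthesise a ureter profile, solve the lumped network over the
experimental grid, generate replicate recordings, fit the resistance table,
build pressure maps with clinical banding, run the side-hole CFD at the two
reported hole velocities and report the detected eddies.  Every run writes
a manifest (config snapshot, seed, package version, per-stage outputs) next
to its artifacts so it can be reproduced bit-for-bit.
"""

from __future__ import annotations

import copy
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cfd2d import (
    build_domain,
    detect_eddies,
    mesh_domain,
    solve_simple,
    write_vtk,
)
from .geometry import (
    GeometryError,
    StentSpec,
    circle_area,
    hole_area_for_severity,
    write_profile,
)
from .hydraulics import pressure_map
from .regression import resistance_table
from .synthetic import (
    SynthConfig,
    make_network_model,
    synth_pressure_recordings,
    synth_ureter_profile,
)

__all__ = ["RunManifest", "default_config", "run_paper_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, manifest: "RunManifest | None" = None):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class RunManifest:
    seed: int
    config: dict
    package_version: str = __version__
    outputs: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def default_config() -> dict:
    """The study's parameter set; every value can be overridden."""
    return {
        "seed": 0,
        "stent": {
            "inner_diameter_mm": 1.28,
            "outer_diameter_mm": 2.08,
            "length_mm": 410.0,
            "hole_diameter_mm": 0.8,
            "hole_spacing_mm": 10.0,
            "first_hole_offset_mm": -35.0,
        },
        "sphere_diameter_mm": 6.07,
        "obstruction_index": 0,
        "profile": {
            "length_mean_mm": 289.0,
            "length_sd_mm": 20.0,
            "min_diameter_mm": 2.2,
            "min_diameter_index": 12,
        },
        "grid": {
            "q_ml_min": [5.0, 10.0, 15.0, 20.0],
            "mu_cp": [1.0, 1.3, 1.7, 2.5, 3.7, 6.0],
            "ob_levels": ["0", "only_stent", "81", "84", "88", "91", "94",
                          "96", "99", "100"],
        },
        "noise_sd_cmh2o": 0.1,
        "replicates": 3,
        "map_ob_levels": ["0", "only_stent", "88", "100"],
        "cfd": {
            "enabled": True,
            "spacing_mm": 0.025,
            "v_h_m_s": [0.01, 0.1],
        },
    }


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _validate(cfg: dict) -> None:
    stent = StentSpec(**cfg["stent"])
    sphere_area = circle_area(cfg["sphere_diameter_mm"])
    for ob in cfg["grid"]["ob_levels"]:
        if ob in ("0", "only_stent"):
            continue
        # raises GeometryError when the level is unattainable for this pairing
        hole_area_for_severity(float(ob), sphere_area, stent.cross_section_mm2)


def run_paper_pipeline(
    config: dict | None = None, out_dir: str | Path = "ureteroflow_run"
) -> RunManifest:
    """Run every stage of the study and write all artifacts plus a manifest.

    The configuration is validated up front (e.g. each requested OB% level
    must be attainable with the configured sphere and stent) so no stage
    starts on an impossible setup.  Any stage failure raises
    :class:`PipelineError` naming the stage, with the partial manifest
    attached.
    """
    cfg = _merge(default_config(), config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=int(cfg["seed"]), config=cfg)
    manifest_path = out / "manifest.json"

    def record(stage: str, path: Path) -> None:
        manifest.outputs.setdefault(stage, []).append(str(path))
        manifest.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.write(manifest_path)

    try:
        _validate(cfg)
    except GeometryError as exc:
        raise PipelineError("validate", str(exc), manifest) from exc

    stent = StentSpec(**cfg["stent"])
    synth_cfg = SynthConfig(
        seed=int(cfg["seed"]),
        noise_sd_cmh2o=cfg["noise_sd_cmh2o"],
        replicates=cfg["replicates"],
        length_mean_mm=cfg["profile"]["length_mean_mm"],
        length_sd_mm=cfg["profile"]["length_sd_mm"],
        min_diameter_mm=cfg["profile"]["min_diameter_mm"],
        min_diameter_index=cfg["profile"]["min_diameter_index"],
        stent_od_mm=stent.outer_diameter_mm,
        q_values_ml_min=tuple(cfg["grid"]["q_ml_min"]),
        mu_values_cp=tuple(cfg["grid"]["mu_cp"]),
        ob_levels=tuple(str(o) for o in cfg["grid"]["ob_levels"]),
    )

    stage = "profile"
    try:
        profile = synth_ureter_profile(synth_cfg)
        path = out / "profile.csv"
        write_profile(profile, path)
        record(stage, path)

        stage = "recordings"
        model = make_network_model(
            profile,
            stent,
            cfg["sphere_diameter_mm"],
            cfg["obstruction_index"],
        )
        recordings = synth_pressure_recordings(model, synth_cfg)
        path = out / "recordings.csv"
        recordings.write_csv(path)
        record(stage, path)

        stage = "resistance_table"
        table = resistance_table(recordings)
        path = out / "resistance_table.csv"
        table.to_csv(path)
        record(stage, path)

        stage = "pressure_maps"
        from .geometry import ObstructionSpec

        sphere_area = circle_area(cfg["sphere_diameter_mm"])
        rows = []
        for ob in cfg["map_ob_levels"]:
            if ob == "0":
                args = (profile, None, None)
            elif ob == "only_stent":
                args = (profile, stent, None)
            else:
                hole = hole_area_for_severity(
                    float(ob), sphere_area, stent.cross_section_mm2
                )
                args = (
                    profile,
                    stent,
                    ObstructionSpec(
                        cfg["sphere_diameter_mm"], hole, cfg["obstruction_index"]
                    ),
                )
            pmap = pressure_map(
                *args, cfg["grid"]["q_ml_min"], cfg["grid"]["mu_cp"]
            )
            for rec in pmap.to_records():
                rec["ob"] = ob
                rows.append(rec)
        path = out / "pressure_maps.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        record(stage, path)

        if cfg["cfd"]["enabled"]:
            stage = "cfd"
            domain = build_domain()
            mesh = mesh_domain(domain, cfg["cfd"]["spacing_mm"])
            eddy_rows = []
            for vh in cfg["cfd"]["v_h_m_s"]:
                result = solve_simple(mesh, v_h_m_s=vh)
                tag = f"vh{vh:g}"
                vtk_path = out / f"fields_{tag}.vtk"
                write_vtk(result, vtk_path)
                record(stage, vtk_path)
                for e in detect_eddies(result):
                    eddy_rows.append(
                        {
                            "v_h_m_s": vh,
                            "center_x_mm": e.center_x_mm,
                            "center_y_mm": e.center_y_mm,
                            "sense": e.sense,
                            "peak_speed_m_s": e.peak_speed_m_s,
                            "streamfunction_m2_s": e.streamfunction_m2_s,
                        }
                    )
            stage = "eddies"
            path = out / "eddies.csv"
            pd.DataFrame(eddy_rows).to_csv(path, index=False)
            record(stage, path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc), manifest) from exc

    manifest.write(manifest_path)
    return manifest
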