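"""Pressure-flow regression and hydraulic-resistance tables.

Renal pelvic pressure in the rigid ureter model is linear in the imposed
flow rate; the slope of the ordinary-least-squares line ``P = m*Q + c`` is
the hydraulic resistance ``m`` of the whole system, in cmH2O/(ml/min).
Fits are produced per (viscosity, obstruction-severity) cell, replicates
averaged first, mirroring how the bench recordings are reduced.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "PressureRecording",
    "PressureRecordingSet",
    "RegressionFit",
    "RegressionError",
    "fit_pressure_flow",
    "resistance_table",
    "count_exceedances",
]


class RegressionError(ValueError):
    """Degenerate regression input (rank deficiency, empty cells)."""


@dataclass(frozen=True)
class PressureRecording:
    q_ml_min: float
    mu_cp: float
    ob_label: str  # "0", "only_stent", "81", ..., "100"
    replicate: int
    pressure_cmh2o: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "q_ml_min", float(self.q_ml_min))
        object.__setattr__(self, "mu_cp", float(self.mu_cp))
        object.__setattr__(self, "ob_label", str(self.ob_label))
        object.__setattr__(self, "replicate", int(self.replicate))
        object.__setattr__(self, "pressure_cmh2o", float(self.pressure_cmh2o))
        if self.pressure_cmh2o < 0:
            raise RegressionError("pressures must be non-negative")


@dataclass(frozen=True)
class PressureRecordingSet:
    """Replicated renal pelvic pressure recordings over a (Q, mu, OB) grid."""

    records: tuple[PressureRecording, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise RegressionError("recording set is empty")

    @property
    def n_replicates(self) -> int:
        return max(r.replicate for r in self.records) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "q_ml_min": [r.q_ml_min for r in self.records],
                "mu_cP": [r.mu_cp for r in self.records],
                "ob": [r.ob_label for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "p_cmH2O": [r.pressure_cmh2o for r in self.records],
            }
        )

    def write_csv(self, dest: str | Path | TextIO) -> None:
        # %.17g keeps the round trip lossless for float64
        self.to_frame().to_csv(dest, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, source: str | Path | TextIO) -> "PressureRecordingSet":
        frame = pd.read_csv(source, float_precision="round_trip")
        required = {"q_ml_min", "mu_cP", "ob", "replicate", "p_cmH2O"}
        missing = required - set(frame.columns)
        if missing:
            raise RegressionError(f"recording file lacks columns {sorted(missing)}")
        return cls(
            tuple(
                PressureRecording(
                    float(r.q_ml_min),
                    float(r.mu_cP),
                    str(r.ob),
                    int(r.replicate),
                    float(r.p_cmH2O),
                )
                for r in frame.itertuples()
            )
        )


@dataclass(frozen=True)
class RegressionFit:
    """OLS line P = slope*Q + intercept; slope is the hydraulic resistance."""

    slope: float  # cmH2O per ml/min
    intercept: float  # cmH2O
    r_squared: float
    n_points: int
    slope_stderr: float

    def predict(self, q_ml_min: float) -> float:
        return self.slope * q_ml_min + self.intercept


def fit_pressure_flow(points: Iterable[tuple[float, float]]) -> RegressionFit:
    """Least-squares fit of pressure versus flow rate.

    ``points`` are (Q in ml/min, P in cmH2O) pairs; at least two distinct
    flow rates are required.
    """
    pts = list(points)
    q = np.array([p[0] for p in pts], dtype=float)
    p = np.array([p[1] for p in pts], dtype=float)
    if len(np.unique(q)) < 2:
        raise RegressionError("need at least 2 distinct flow rates to fit")
    res = _stats.linregress(q, p)
    # r_squared about the mean: 1 - SS_res/SS_tot
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    resid = p - (res.slope * q + res.intercept)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=len(pts),
        slope_stderr=float(res.stderr),
    )


def resistance_table(
    recordings: PressureRecordingSet, average_replicates: bool = True
) -> pd.DataFrame:
    """Hydraulic resistance (m) and R^2 per (OB, viscosity) cell.

    Rows are obstruction labels, columns a MultiIndex (mu_cP, {m, r_squared}).
    Cells spanning fewer than two flow rates are left missing (NaN) rather
    than failing the whole table.  Replicates are averaged per flow rate
    before fitting by default; with balanced replicates fitting raw records
    yields the same slope.
    """
    frame = recordings.to_frame()
    if average_replicates:
        frame = (
            frame.groupby(["ob", "mu_cP", "q_ml_min"], as_index=False)["p_cmH2O"]
            .mean()
        )
    mu_values = sorted(frame["mu_cP"].unique())
    ob_labels = _ordered_ob_labels(frame["ob"].unique())
    columns = pd.MultiIndex.from_product([mu_values, ["m", "r_squared"]])
    table = pd.DataFrame(index=ob_labels, columns=columns, dtype=float)
    table.index.name = "OB%"
    for ob in ob_labels:
        for mu in mu_values:
            cell = frame[(frame["ob"] == ob) & (frame["mu_cP"] == mu)]
            if cell["q_ml_min"].nunique() < 2:
                continue  # missing cell
            fit = fit_pressure_flow(zip(cell["q_ml_min"], cell["p_cmH2O"]))
            table.loc[ob, (mu, "m")] = fit.slope
            table.loc[ob, (mu, "r_squared")] = fit.r_squared
    return table


def _ordered_ob_labels(labels) -> list[str]:
    # table layout: bare conduit first, then stent-only, then sphere levels
    numeric = sorted((l for l in labels if l != "only_stent"), key=lambda x: float(x))
    out = []
    for l in numeric:
        out.append(l)
        if float(l) == 0 and "only_stent" in set(labels):
            out.append("only_stent")
    if "only_stent" in set(labels) and "only_stent" not in out:
        out.insert(0, "only_stent")
    return out


def count_exceedances(
    fit: RegressionFit, q_values: Sequence[float], threshold_cmh2o: float
) -> int:
    """Number of flow rates whose predicted pressure strictly exceeds the
    threshold (clinically, 20 cmH2O marks danger to the kidney)."""
    if threshold_cmh2o < 0:
        raise RegressionError("threshold must be non-negative")
    return int(sum(fit.predict(q) > threshold_cmh2o for q in q_values))
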