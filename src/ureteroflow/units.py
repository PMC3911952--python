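"""Centralised unit conversions.

Interfaces speak the clinical units (mm, cmH2O, ml/min, cP); all internal
physics is SI.  The conversion constants are fixed here and nowhere else.
"""

#: Pascals per centimetre of water column.
PA_PER_CMH2O = 98.0665

#: Cubic metres per second per (millilitre per minute).
M3S_PER_ML_MIN = 1.6667e-8

#: Pascal-seconds per centipoise.
PAS_PER_CP = 1e-3

#: Metres per millimetre.
M_PER_MM = 1e-3


def cmh2o_to_pa(p: float) -> float:
    return p * PA_PER_CMH2O


def pa_to_cmh2o(p: float) -> float:
    return p / PA_PER_CMH2O


def ml_min_to_m3s(q: float) -> float:
    return q * M3S_PER_ML_MIN


def m3s_to_ml_min(q: float) -> float:
    return q / M3S_PER_ML_MIN


def cp_to_pas(mu: float) -> float:
    return mu * PAS_PER_CP


def mm_to_m(x: float) -> float:
    return x * M_PER_MM
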