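"""Unit conversion constants and helpers.

All internal computation is in SI (m, Pa, m^3/s). Clinical interfaces
accept and emit mm, mmHg and mL/min, the units in which cerebral venous
pressures and flows are conventionally reported.
"""

MMHG_TO_PA: float = 133.322
"""Pascals per millimetre of mercury."""

ML_MIN_TO_M3_S: float = 1e-6 / 60.0
"""Cubic metres per second per (millilitre per minute)."""

MM_TO_M: float = 1e-3


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_TO_PA


def ml_min_to_m3_s(q: float) -> float:
    return q * ML_MIN_TO_M3_S


def m3_s_to_ml_min(q: float) -> float:
    return q / ML_MIN_TO_M3_S


def mm_to_m(x: float) -> float:
    return x * MM_TO_M


def m_to_mm(x: float) -> float:
    return x / MM_TO_M
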