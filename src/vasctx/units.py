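"""Unit conversions for the canonical internal system.

Everything inside the package is expressed in a single canonical system:
micrometres (length), minutes (time), millimolar (concentration), cubic
micrometres (volume) and pascal (pressure).  Mixing the published parameter
units (Pa·s viscosity, cm²/min diffusivities, nl/min flows, M/min maximal
rates, mmHg pressures) directly is the classic source of silent transport
bugs; every public entry point converts at the boundary and all operators
work in canonical units only.
"""

from __future__ import annotations

# 1 mmHg in Pa
MMHG_PA = 133.322
# 1 nl in µm³
NL_UM3 = 1.0e6
# 1 cm² in µm²
CM2_UM2 = 1.0e8
# 1 m in µm
M_UM = 1.0e6


def mmhg_to_pa(p: float) -> float:
    return p * MMHG_PA


def pa_to_mmhg(p: float) -> float:
    return p / MMHG_PA


def nl_per_min_to_um3_per_min(q: float) -> float:
    return q * NL_UM3


def um3_per_min_to_nl_per_min(q: float) -> float:
    return q / NL_UM3


def cm2_per_min_to_um2_per_min(d: float) -> float:
    """Diffusivity: cm²/min → µm²/min (e.g. glucose 5.46e-4 → 5.46e4)."""
    return d * CM2_UM2


def pa_s_to_pa_min(mu: float) -> float:
    """Dynamic viscosity: Pa·s → Pa·min."""
    return mu / 60.0


def um_per_s_to_um_per_min(u: float) -> float:
    return u * 60.0


def um_per_min_to_um_per_s(u: float) -> float:
    return u / 60.0


def molar_per_min_to_mm_per_min(v: float) -> float:
    """Maximal rates: M/min → mM/min."""
    return v * 1000.0


def minutes_to_seconds(t):
    return t * 60.0


def seconds_to_minutes(t):
    return t / 60.0
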