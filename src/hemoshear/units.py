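"""Unit conventions.

All geometry and physics are SI internally (m, s, Pa, kg, m³/s).  Millimetres
and mmHg appear only at I/O boundaries (image grids, ultrasound panels,
brachial pressure) and are converted explicitly with these helpers.
"""

PA_PER_MMHG = 133.322
MM_PER_M = 1000.0


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * PA_PER_MMHG


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / PA_PER_MMHG


def m_to_mm(x):
    return x * MM_PER_M


def mm_to_m(x):
    return x / MM_PER_M
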