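"""Unit system and conversion constants.

The internal unit system is mm-g-s: lengths in mm, areas in mm^2, flows in
mm^3/s, and pressures in Pa (the mm-g-s pressure unit coincides with the
pascal).  Clinical quantities are quoted in L/min and mmHg; the two fixed
conversion factors below are used everywhere so that round trips are exact.
"""

#: mm^3/s per L/min (fixed project-wide conversion).
MM3S_PER_L_MIN = 16_666.7

#: Pa per mmHg (fixed project-wide conversion).
PA_PER_MMHG = 133.322


def l_min_to_mm3s(q: float) -> float:
    """Convert a volumetric flow from L/min to mm^3/s."""
    return q * MM3S_PER_L_MIN


def mm3s_to_l_min(q: float) -> float:
    """Convert a volumetric flow from mm^3/s to L/min."""
    return q / MM3S_PER_L_MIN


def mmhg_to_pa(p: float) -> float:
    """Convert a pressure from mmHg to Pa."""
    return p * PA_PER_MMHG


def pa_to_mmhg(p: float) -> float:
    """Convert a pressure from Pa to mmHg."""
    return p / PA_PER_MMHG
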