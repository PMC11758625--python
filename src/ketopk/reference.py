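"""Published summary values of the oral 3-HB dosing study this package models.

The study's raw concentration tables and full fitted-parameter table are not
publicly deposited; what is printed are the disposition estimates (clearance,
basal concentration, volume of distribution), the mean peak summaries of the
2 g and 4 g arms, and the brain-ketone-metabolism threshold concentration.
These suffice to re-derive the absorption parameters by calibration
(:func:`reference_parameters`) and to reproduce the minimum-dose result.
"""

from __future__ import annotations

from .pk_core import PKParameters
from .pk_fit import calibrate_from_summary

__all__ = [
    "PUBLISHED_DISPOSITION",
    "PUBLISHED_PEAK_SUMMARIES",
    "TARGET_CMAX_MM",
    "reference_parameters",
]

#: Printed disposition estimates: clearance (L/min), basal serum
#: concentration (mM) and volume of distribution (L).
PUBLISHED_DISPOSITION: dict[str, float] = {"CL": 1.82, "C0": 0.063, "Vd": 85.7}

#: Printed mean peaks per dose arm: (dose g, Cmax mM, Tmax min).
PUBLISHED_PEAK_SUMMARIES: list[tuple[float, float, float]] = [
    (2.0, 0.266, 30.0),
    (4.0, 0.289, 45.0),
]

#: Serum concentration reported to initiate ketone metabolism in the brain, mM.
TARGET_CMAX_MM = 0.28


def reference_parameters(seed: int = 0) -> PKParameters:
    """Full parameter set with absorption calibrated to the printed peaks.

    Fixes CL, C0 and Vd at their published estimates and solves for
    (Vmax, Km', ka) so that simulated 2 g and 4 g profiles reproduce the
    published Cmax/Tmax summaries.  Deterministic given ``seed``.
    """
    return calibrate_from_summary(dict(PUBLISHED_DISPOSITION),
                                  PUBLISHED_PEAK_SUMMARIES, seed=seed)
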