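"""Minimum-dose search: smallest oral 3-HB dose reaching a target Cmax.

Peak concentration is strictly increasing in dose for this model (more drug
in the gut can only raise the absorption flux), so both a grid scan and a
continuous bisection are valid search strategies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .pk_core import DoseInput, ModelVariant, PKParameters, simulate, summarize_cmax

__all__ = ["DoseSearchSpec", "BracketingError", "find_min_dose_grid",
           "find_min_dose_bisect", "cmax_at_dose"]

logger = logging.getLogger(__name__)


class BracketingError(ValueError):
    """The dose bracket does not straddle the target Cmax."""


@dataclass(frozen=True)
class DoseSearchSpec:
    """Search settings: target peak, candidate dose grid, refinement."""

    target_cmax: float
    grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 8.0 + 0.25, 0.5))
    refine: bool = False
    bisect_tol: float = 0.01  # g
    t_end: float = 240.0      # min; absorption is complete well before
    grid_step: float = 0.1    # min, Cmax evaluation grid

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        if self.target_cmax <= 0:
            raise ValueError("target_cmax must be positive")
        if self.grid.size == 0 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be non-empty and strictly increasing")
        if np.any(self.grid < 0):
            raise ValueError("doses must be non-negative")
        if self.bisect_tol <= 0:
            raise ValueError("bisect_tol must be positive")


def cmax_at_dose(params: PKParameters, dose_g: float,
                 spec: DoseSearchSpec,
                 variant: ModelVariant = ModelVariant.FULL) -> float:
    """Refined peak concentration (mM) for one dose."""
    profile = simulate(params, DoseInput(dose_g), t_end=spec.t_end,
                       variant=variant, grid_step=spec.grid_step)
    return summarize_cmax(profile)[0]


def find_min_dose_grid(params: PKParameters, spec: DoseSearchSpec,
                       variant: ModelVariant = ModelVariant.FULL) -> float | None:
    """Smallest grid dose whose Cmax reaches the target; None if none does.

    A target at or below the basal concentration returns 0 g immediately
    (the baseline already meets it).  Equality counts as reaching the
    target.
    """
    if spec.target_cmax <= params.C0:
        logger.info("target %.4g mM does not exceed baseline %.4g mM; 0 g suffices",
                    spec.target_cmax, params.C0)
        return 0.0
    for dose_g in spec.grid:
        if dose_g == 0.0:
            continue  # Cmax(0) = C0 < target, established above
        if cmax_at_dose(params, float(dose_g), spec, variant) >= spec.target_cmax:
            return float(dose_g)
    return None


def find_min_dose_bisect(params: PKParameters, spec: DoseSearchSpec,
                         variant: ModelVariant = ModelVariant.FULL) -> float:
    """Continuous minimum dose by bisection, to within ``bisect_tol`` grams.

    Requires the bracket [0, max grid dose] to straddle the target: the
    baseline must sit below it and the largest candidate dose must reach
    it.  Exploits monotonicity of Cmax in dose; the returned dose d
    satisfies Cmax(d) >= target while Cmax(d - tol) < target.
    """
    if spec.target_cmax <= params.C0:
        return 0.0
    hi = float(spec.grid[-1])
    if cmax_at_dose(params, hi, spec, variant) < spec.target_cmax:
        raise BracketingError(
            f"Cmax at the maximum candidate dose {hi} g stays below the "
            f"target {spec.target_cmax} mM")
    lo = 0.0
    while hi - lo > spec.bisect_tol:
        mid = 0.5 * (lo + hi)
        if cmax_at_dose(params, mid, spec, variant) >= spec.target_cmax:
            hi = mid
        else:
            lo = mid
    return hi
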