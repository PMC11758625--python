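"""Synthetic data emulating the two studies the pipeline analyses.

Two generators:

* serum 3-HB concentration-time profiles — the model prediction perturbed
  by proportional (constant-CV) measurement noise, sampled on the study's
  schedule (0, 5, 15, 30, 45, 60, 120 min), with arm means computed exactly
  the way the fitting stage consumes them;
* 2x2 crossover change scores — an additive model with sequence, period and
  treatment effects, a subject-level random intercept and residual noise.

Noise is observation-level only: between-subject kinetic heterogeneity is
deliberately not modelled, because the fitting stage works on arm means.
All randomness flows through an explicit integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .efficacy import treatment_for
from .pk_core import DoseInput, ModelVariant, PKParameters, simulate_conc_at
from .pk_fit import ObservedArm

__all__ = [
    "STUDY_SCHEDULE_MIN",
    "EXAMPLE_TRUTH",
    "ProfileGenSpec",
    "TrialGenSpec",
    "ProfileData",
    "generate_serum_profiles",
    "generate_crossover_trial",
]

#: Post-dose sampling schedule of the dosing study, minutes.
STUDY_SCHEDULE_MIN = (0.0, 5.0, 15.0, 30.0, 45.0, 60.0, 120.0)

#: Default ground truth for simulation studies: disposition at the published
#: estimates, absorption split between a firmly saturated transporter
#: pathway (Km' well below the dosed amounts, so the split is identifiable)
#: and a first-order pathway of comparable initial flux.
EXAMPLE_TRUTH = PKParameters(CL=1.82, C0=0.063, ka=0.02, Km_prime=2.0,
                             Vd=85.7, Vmax=0.45)

DEFAULT_SEED = 20240101


@dataclass(frozen=True)
class ProfileGenSpec:
    """Settings for serum-profile generation.

    ``noise_cv`` is the coefficient of variation of the proportional
    measurement error (default 0.30, the SD-to-mean ratio of the observed
    peak concentrations); ``noise_floor`` truncates non-physical values
    from below (mM).
    """

    truth: PKParameters
    doses: tuple[float, ...] = (2.0, 4.0)
    times: tuple[float, ...] = STUDY_SCHEDULE_MIN
    n_subjects: int = 10
    noise_cv: float = 0.30
    noise_floor: float = 0.001
    variant: ModelVariant = ModelVariant.FULL
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject per arm")
        if len(self.times) < 2 or any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class ProfileData:
    """Generated profiles: per-subject long table plus per-arm means."""

    subjects: pd.DataFrame
    arms: list[ObservedArm]


def generate_serum_profiles(spec: ProfileGenSpec) -> ProfileData:
    """Simulate noisy serum 3-HB profiles and their arm means.

    Each subject's value at each timepoint is ``prediction * (1 + e)`` with
    ``e ~ Normal(0, noise_cv)``, truncated below at ``noise_floor``.  Arm
    means over subjects are packaged as :class:`~ketopk.pk_fit.ObservedArm`
    ready for fitting.  Byte-for-byte reproducible for a fixed seed.
    """
    times = np.asarray(spec.times, dtype=float)
    has_baseline = times[0] == 0.0
    if not has_baseline:
        warnings.warn("sampling does not start at 0 min: the baseline "
                      "anchor for C0 is lost and no fitting-ready arms are "
                      "built", UserWarning, stacklevel=2)
    rng = np.random.default_rng(spec.seed)
    rows = []
    arms: list[ObservedArm] = []
    for arm_idx, dose_g in enumerate(spec.doses):
        dose = DoseInput(float(dose_g))
        pred = simulate_conc_at(spec.truth, dose, times, variant=spec.variant)
        eps = rng.normal(0.0, spec.noise_cv, size=(spec.n_subjects, times.size))
        values = np.maximum(pred[None, :] * (1.0 + eps), spec.noise_floor)
        for s in range(spec.n_subjects):
            for j, t in enumerate(times):
                rows.append({"arm_id": f"arm{arm_idx + 1}",
                             "dose_g": float(dose_g), "subject": s + 1,
                             "time_min": float(t),
                             "conc_mM": float(values[s, j])})
        if has_baseline:
            arms.append(ObservedArm(
                dose=dose, times=times, conc_mean=values.mean(axis=0),
                conc_sd=(values.std(axis=0, ddof=1)
                         if spec.n_subjects > 1 else None),
                n_subjects=spec.n_subjects))
    return ProfileData(subjects=pd.DataFrame(rows), arms=arms)


@dataclass(frozen=True)
class TrialGenSpec:
    """Settings for 2x2 crossover trial generation.

    The change score follows

        change = mu + sequence_effect * 1[seq II] + period_effect * 1[period 2]
                 + true_effect * 1[active] + b_subject + eps,

    with ``b ~ Normal(0, subject_sd)`` and ``eps ~ Normal(0, residual_sd)``,
    so ``mu`` is the placebo-arm mean and ``true_effect`` the active-minus-
    placebo contrast.  Defaults mirror the mood-composite endpoint of the
    trial this package models: a -4.7-point treatment effect on change
    scores whose arm SDs were roughly 12-14 points, in a 40-subject trial
    split 20/20 across sequences.
    """

    n_subjects: int = 40
    true_effect: float = -4.7
    period_effect: float = 0.0
    sequence_effect: float = 0.0
    subject_sd: float = 8.0
    residual_sd: float = 10.5
    mu: float = 5.3
    pre_mean: float = 10.0
    pre_sd: float = 8.0
    endpoint: str = "poms2_tmd"
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("need at least 2 subjects per sequence")
        if self.subject_sd < 0 or self.residual_sd < 0 or self.pre_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def generate_crossover_trial(spec: TrialGenSpec) -> pd.DataFrame:
    """Simulate a complete two-period crossover trial.

    Subjects are split as evenly as possible across the two sequences
    (both must end up with at least 2 subjects); each contributes one
    record per period with treatment implied by (sequence, period).
    Returns a long table with columns subject_id, sequence, period,
    treatment, endpoint, pre, post, change.
    """
    rng = np.random.default_rng(spec.seed)
    n_seq1 = spec.n_subjects // 2
    n_seq2 = spec.n_subjects - n_seq1
    if min(n_seq1, n_seq2) < 2:
        raise ValueError("each sequence needs at least 2 subjects")
    sequences = ["I"] * n_seq1 + ["II"] * n_seq2
    b = rng.normal(0.0, spec.subject_sd, size=spec.n_subjects)
    rows = []
    for i, seq in enumerate(sequences):
        for period in (1, 2):
            treatment = treatment_for(seq, period)
            change = (spec.mu
                      + spec.sequence_effect * (seq == "II")
                      + spec.period_effect * (period == 2)
                      + spec.true_effect * (treatment == "active")
                      + b[i]
                      + rng.normal(0.0, spec.residual_sd))
            pre = rng.normal(spec.pre_mean, spec.pre_sd)
            rows.append({"subject_id": f"S{i + 1:03d}", "sequence": seq,
                         "period": period, "treatment": treatment,
                         "endpoint": spec.endpoint, "pre": pre,
                         "post": pre + change, "change": change})
    return pd.DataFrame(rows)
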