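"""Statistics for the 2x2 crossover efficacy trial.

Each subject receives both the active beverage and placebo, one per period,
in one of two sequences (I: active then placebo; II: placebo then active).
Endpoints are change scores (post minus pre within a visit).  The treatment
effect is estimated with a linear mixed model — sequence, period and
treatment as fixed effects, a random intercept per subject — fitted by
REML; inference uses the between-within degrees of freedom (subjects - 2
for the within-subject treatment contrast).  Baseline group comparisons use
the independent two-sample t-test, and the sex ratio Fisher's exact test.

Also provides the POMS2 total mood disturbance (TMD) composite: the sum of
the five negative-mood subscales minus vigor-activity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence as SeqT

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf

__all__ = [
    "SEQUENCES",
    "CrossoverResult",
    "Poms2Scores",
    "MissingDataError",
    "DesignError",
    "treatment_for",
    "validate_trial",
    "tmd_score",
    "compute_change_scores",
    "fit_crossover",
    "crossover_summary",
    "baseline_t_test",
    "t_test_from_summary",
    "fisher_exact",
]

logger = logging.getLogger(__name__)

SEQUENCES = ("I", "II")


class MissingDataError(ValueError):
    """A required score or column is absent."""


class DesignError(ValueError):
    """The crossover design is degenerate (aliased or single-sequence)."""


def treatment_for(sequence: str, period: int) -> str:
    """Treatment implied by (sequence, period): sequence I is active-first."""
    if sequence not in SEQUENCES:
        raise ValueError(f"unknown sequence {sequence!r}")
    if period not in (1, 2):
        raise ValueError(f"period must be 1 or 2, got {period!r}")
    active_first = sequence == "I"
    return "active" if (period == 1) == active_first else "placebo"


@dataclass(frozen=True)
class Poms2Scores:
    """POMS2 subscale scores for one assessment."""

    anger_hostility: float
    confusion_bewilderment: float
    depression_dejection: float
    fatigue_inertia: float
    tension_anxiety: float
    vigor_activity: float
    friendliness: float | None = None

    @property
    def tmd(self) -> float:
        return tmd_score(self.anger_hostility, self.confusion_bewilderment,
                         self.depression_dejection, self.fatigue_inertia,
                         self.tension_anxiety, self.vigor_activity)


def tmd_score(anger_hostility: float, confusion_bewilderment: float,
              depression_dejection: float, fatigue_inertia: float,
              tension_anxiety: float, vigor_activity: float) -> float:
    """Total mood disturbance: five negative subscales summed, minus vigor."""
    values = (anger_hostility, confusion_bewilderment, depression_dejection,
              fatigue_inertia, tension_anxiety, vigor_activity)
    for v in values:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise MissingDataError("all six TMD subscales must be present")
    return (anger_hostility + confusion_bewilderment + depression_dejection
            + fatigue_inertia + tension_anxiety) - vigor_activity


def validate_trial(records: pd.DataFrame) -> pd.DataFrame:
    """Check the crossover bookkeeping of a trial table.

    Requires columns subject_id, sequence, period, treatment; verifies that
    the stated treatment matches the one implied by (sequence, period) and
    that no subject contributes more than one record per period.
    """
    required = {"subject_id", "sequence", "period", "treatment"}
    missing = required - set(records.columns)
    if missing:
        raise MissingDataError(f"trial table lacks columns {sorted(missing)}")
    implied = [treatment_for(s, int(p))
               for s, p in zip(records["sequence"], records["period"])]
    bad = records.loc[np.asarray(implied) != records["treatment"].to_numpy()]
    if len(bad):
        raise DesignError(
            f"{len(bad)} records have a treatment inconsistent with their "
            f"(sequence, period), e.g. subject {bad.iloc[0]['subject_id']}")
    dup = records.duplicated(subset=["subject_id", "period"])
    if dup.any():
        raise DesignError("a subject contributes more than one record per period")
    return records


def compute_change_scores(records: pd.DataFrame,
                          pre: str = "pre", post: str = "post") -> pd.DataFrame:
    """Add the change score (post - pre); drop and log incomplete records."""
    if pre not in records.columns or post not in records.columns:
        raise MissingDataError(f"need columns {pre!r} and {post!r}")
    out = records.copy()
    complete = out[pre].notna() & out[post].notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("excluding %d record(s) with missing pre/post values",
                       n_dropped)
        out = out.loc[complete].copy()
    out["change"] = out[post] - out[pre]
    return out


@dataclass
class CrossoverResult:
    """Treatment contrast (active - placebo) from the crossover model."""

    effect: float
    ci_low: float
    ci_high: float
    p_value: float
    se: float
    df: int
    fixed_effects: dict[str, float]
    n_used: int


def fit_crossover(records: pd.DataFrame, outcome: str = "change") -> CrossoverResult:
    """Estimate the active-minus-placebo effect on a change-score endpoint.

    Fits ``outcome ~ sequence + period + treatment`` with a subject-level
    random intercept by REML.  The p-value and 95% CI use a t reference
    with subjects - 2 degrees of freedom (between-within partition for the
    within-subject treatment contrast in a 2x2 crossover).

    Completely deterministic data (zero residual variance after the fixed
    effects) are handled without the mixed-model machinery: the effect is
    the fixed-effects solution and p is 1 when it is zero.
    """
    validate_trial(records)
    if outcome not in records.columns:
        raise MissingDataError(f"outcome column {outcome!r} missing")
    data = records.dropna(subset=[outcome]).copy()
    seqs = data["sequence"].unique()
    if len(seqs) < 2:
        raise DesignError(
            "all subjects are in one sequence: the sequence effect is "
            "inestimable and treatment is aliased with period")
    per_seq = data.groupby("sequence")["subject_id"].nunique()
    if (per_seq < 2).any():
        raise DesignError("need at least 2 subjects per sequence")

    data["y"] = data[outcome].astype(float)
    data["treatment"] = pd.Categorical(data["treatment"],
                                       categories=["placebo", "active"])
    data["sequence"] = pd.Categorical(data["sequence"], categories=list(SEQUENCES))
    data["period"] = pd.Categorical(data["period"].astype(int), categories=[1, 2])
    n_subjects = data["subject_id"].nunique()
    df_t = n_subjects - 2

    formula = "y ~ C(sequence) + C(period) + C(treatment)"
    # Deterministic data break the variance estimation; use the exact
    # fixed-effects solution directly.
    ols = smf.ols(formula, data=data).fit()
    if ols.ssr < 1e-20 * max(1.0, float(np.abs(data["y"]).max()) ** 2):
        effect = float(ols.params.get("C(treatment)[T.active]", 0.0))
        if abs(effect) < 1e-9 * max(1.0, float(np.abs(data["y"]).max())):
            effect = 0.0  # solver round-off on exactly null data
        p = 1.0 if effect == 0.0 else 0.0
        fe = {k: float(v) for k, v in ols.params.items()}
        return CrossoverResult(effect=effect, ci_low=effect, ci_high=effect,
                               p_value=p, se=0.0, df=df_t, fixed_effects=fe,
                               n_used=n_subjects)

    model = smf.mixedlm(formula, data=data, groups=data["subject_id"])
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # boundary variance estimates are fine
        fit = model.fit(reml=True)
    term = "C(treatment)[T.active]"
    effect = float(fit.params[term])
    se = float(fit.bse[term])
    tcrit = st.t.ppf(0.975, df_t)
    tstat = effect / se if se > 0 else np.inf * np.sign(effect)
    p = 2.0 * float(st.t.sf(abs(tstat), df_t)) if se > 0 else 0.0
    fe = {k: float(v) for k, v in fit.fe_params.items()}
    return CrossoverResult(
        effect=effect, ci_low=effect - tcrit * se, ci_high=effect + tcrit * se,
        p_value=p, se=se, df=df_t, fixed_effects=fe, n_used=n_subjects)


def crossover_summary(records: pd.DataFrame,
                      outcome: str = "change") -> pd.Series:
    """One row of the endpoint table: arm means +- SD, difference (CI), p."""
    result = fit_crossover(records, outcome=outcome)
    active = records.loc[records["treatment"] == "active", outcome].astype(float)
    placebo = records.loc[records["treatment"] == "placebo", outcome].astype(float)
    return pd.Series({
        "active_mean": active.mean(), "active_sd": active.std(ddof=1),
        "placebo_mean": placebo.mean(), "placebo_sd": placebo.std(ddof=1),
        "effect": result.effect, "ci_low": result.ci_low,
        "ci_high": result.ci_high, "p_value": result.p_value,
        "n_used": result.n_used,
    })


def _degenerate_t(mean_a: float, mean_b: float, df: int) -> tuple[float, int, float]:
    if mean_a == mean_b:
        return 0.0, df, 1.0
    return math.inf if mean_a > mean_b else -math.inf, df, 0.0


def baseline_t_test(group_a: SeqT[float], group_b: SeqT[float],
                    equal_var: bool = True) -> tuple[float, float, float]:
    """Independent two-sample t-test; returns (t, df, two-sided p).

    Pooled-variance Student's t by default; set ``equal_var=False`` for
    Welch.  Zero within-group variance is resolved by the limiting
    contract: p = 1 for equal means, p -> 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return _degenerate_t(a.mean(), b.mean(), a.size + b.size - 2)
    res = st.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def t_test_from_summary(mean_a: float, sd_a: float, n_a: int,
                        mean_b: float, sd_b: float, n_b: int,
                        equal_var: bool = True) -> tuple[float, float, float]:
    """t-test from printed summary statistics (mean, SD, n per group)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 subjects")
    if sd_a == 0 and sd_b == 0:
        return _degenerate_t(mean_a, mean_b, n_a + n_b - 2)
    res = st.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                  equal_var=equal_var)
    if equal_var:
        df: float = n_a + n_b - 2
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return float(res.statistic), df, float(res.pvalue)


def fisher_exact(table: SeqT[SeqT[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Sums hypergeometric point probabilities no larger than that of the
    observed table.  A zero margin makes every admissible table equally
    likely, so p = 1 by convention (logged).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    t = t.astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        logger.info("zero margin in 2x2 table; p = 1 by convention")
        return 1.0
    return float(st.fisher_exact(t, alternative="two-sided")[1])
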