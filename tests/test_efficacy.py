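"""Unit tests for the crossover-trial statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hs

from ketopk.efficacy import (
    DesignError,
    MissingDataError,
    Poms2Scores,
    baseline_t_test,
    compute_change_scores,
    crossover_summary,
    fisher_exact,
    fit_crossover,
    t_test_from_summary,
    tmd_score,
    treatment_for,
    validate_trial,
)

scores = hs.floats(min_value=-50, max_value=50, allow_nan=False)


def paired_contrast(records: pd.DataFrame) -> float:
    """Closed-form crossover estimator: sequence-averaged mean of the
    within-subject active-minus-placebo change."""
    piv = records.pivot_table(index=["subject_id", "sequence"],
                              columns="treatment", values="change").reset_index()
    piv["diff"] = piv["active"] - piv["placebo"]
    return float(piv.groupby("sequence")["diff"].mean().mean())


def balanced_trial(n_per_seq=10, effect=-4.7, period=2.0, seq=1.0,
                   subject_sd=8.0, resid_sd=5.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_per_seq):
        s = "I" if i < n_per_seq else "II"
        b = rng.normal(0, subject_sd)
        for p in (1, 2):
            tr = treatment_for(s, p)
            change = (5.0 + seq * (s == "II") + period * (p == 2)
                      + effect * (tr == "active") + b + rng.normal(0, resid_sd))
            rows.append({"subject_id": f"S{i:03d}", "sequence": s, "period": p,
                         "treatment": tr, "change": change})
    return pd.DataFrame(rows)


class TestTmd:
    def test_all_zero(self):
        assert tmd_score(0, 0, 0, 0, 0, 0) == 0

    def test_hand_arithmetic(self):
        assert tmd_score(2, 2, 2, 2, 2, 3) == 7

    @settings(max_examples=50, derandomize=True)
    @given(scores, scores, scores, scores, scores, scores,
           hs.floats(min_value=-10, max_value=10, allow_nan=False))
    def test_vigor_enters_with_unit_negative_weight(self, a, c, d, f, t, v, delta):
        base = tmd_score(a, c, d, f, t, v)
        shifted = tmd_score(a, c, d, f, t, v + delta)
        assert shifted == pytest.approx(base - delta, abs=1e-9)

    def test_missing_subscale_rejected(self):
        with pytest.raises(MissingDataError):
            tmd_score(1, 2, 3, 4, np.nan, 5)

    def test_dataclass_composite(self):
        s = Poms2Scores(anger_hostility=1, confusion_bewilderment=2,
                        depression_dejection=3, fatigue_inertia=4,
                        tension_anxiety=5, vigor_activity=6)
        assert s.tmd == 15 - 6


class TestChangeScores:
    def test_post_minus_pre(self):
        df = pd.DataFrame({"pre": [40.1, 10.0], "post": [73.8, 10.0]})
        out = compute_change_scores(df)
        assert out["change"].tolist() == pytest.approx([33.7, 0.0])

    def test_missing_records_dropped_and_logged(self, caplog):
        df = pd.DataFrame({"pre": [1.0, np.nan, 3.0], "post": [2.0, 5.0, np.nan]})
        with caplog.at_level("WARNING"):
            out = compute_change_scores(df)
        assert len(out) == 1
        assert "excluding 2" in caplog.text


class TestTrialValidation:
    def test_treatment_implied_by_sequence_and_period(self):
        assert treatment_for("I", 1) == "active"
        assert treatment_for("I", 2) == "placebo"
        assert treatment_for("II", 1) == "placebo"
        assert treatment_for("II", 2) == "active"

    def test_mismatched_treatment_rejected(self):
        df = balanced_trial(n_per_seq=3)
        df.loc[0, "treatment"] = "placebo"
        with pytest.raises(DesignError):
            validate_trial(df)

    def test_duplicate_period_rejected(self):
        df = balanced_trial(n_per_seq=3)
        with pytest.raises(DesignError):
            validate_trial(pd.concat([df, df.iloc[[0]]]))


class TestFitCrossover:
    def test_matches_closed_form_on_balanced_data(self):
        df = balanced_trial(seed=3)
        res = fit_crossover(df)
        assert res.effect == pytest.approx(paired_contrast(df), abs=1e-10)
        assert res.ci_low <= res.effect <= res.ci_high

    def test_constant_within_subject_difference_recovered_exactly(self, rng):
        rows = []
        for i in range(20):
            s = "I" if i < 10 else "II"
            base = float(rng.normal(50, 10))
            for p in (1, 2):
                tr = treatment_for(s, p)
                rows.append({"subject_id": f"S{i}", "sequence": s, "period": p,
                             "treatment": tr,
                             "change": base + (28.8 if tr == "active" else 0.0)})
        res = fit_crossover(pd.DataFrame(rows))
        assert res.effect == pytest.approx(28.8, abs=1e-8)

    def test_identical_changes_give_null_result(self):
        df = balanced_trial(n_per_seq=3)
        df["change"] = 4.2
        res = fit_crossover(df)
        assert res.effect == 0.0
        assert res.p_value == 1.0

    def test_single_sequence_inestimable(self):
        df = balanced_trial(n_per_seq=5)
        with pytest.raises(DesignError):
            fit_crossover(df[df["sequence"] == "I"])

    def test_period_relabelling_flips_period_not_treatment(self):
        df = balanced_trial(seed=9)
        res = fit_crossover(df)
        flipped = df.copy()
        flipped["period"] = 3 - flipped["period"]
        flipped["sequence"] = flipped["sequence"].map({"I": "II", "II": "I"})
        res_f = fit_crossover(flipped)
        assert res_f.effect == pytest.approx(res.effect, abs=1e-8)
        assert res_f.fixed_effects["C(period)[T.2]"] == pytest.approx(
            -res.fixed_effects["C(period)[T.2]"], abs=1e-6)

    def test_summary_row_mirrors_endpoint_table(self):
        df = balanced_trial(seed=4)
        row = crossover_summary(df)
        active = df.loc[df["treatment"] == "active", "change"]
        assert row["active_mean"] == pytest.approx(active.mean())
        assert row["ci_low"] <= row["effect"] <= row["ci_high"]
        assert row["n_used"] == 20


class TestBaselineTTest:
    def test_identical_groups(self):
        t, df, p = baseline_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_zero_variance_unequal_means(self):
        t, _, p = baseline_t_test([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(t)
        assert p == 0.0

    def test_printed_age_row_reproduced_from_summaries(self):
        # group means 52.0 +- 6.4 and 52.2 +- 6.5 with n = 20 each
        _, df, p = t_test_from_summary(52.0, 6.4, 20, 52.2, 6.5, 20)
        assert df == 38
        assert abs(p - 0.922) < 0.01

    def test_pooled_t_matches_permutation_oracle(self, rng):
        # under normal samples the permutation p and pooled-t p agree
        # to within Monte-Carlo error
        n, B = 12, 2000
        for _ in range(15):
            a = rng.normal(0.0, 1.0, n)
            b = rng.normal(0.5, 1.0, n)
            _, _, p_t = baseline_t_test(a, b)
            pooled = np.concatenate([a, b])
            obs = abs(a.mean() - b.mean())
            count = 0
            for _ in range(B):
                perm = rng.permutation(pooled)
                count += abs(perm[:n].mean() - perm[n:].mean()) >= obs - 1e-12
            assert abs(p_t - count / B) < 0.05


class TestFisherExact:
    def test_symmetric_table_is_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_zero_margin_convention(self):
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0

    def test_agrees_with_hypergeometric_enumeration(self, rng):
        # independent oracle: sum the point probabilities of all tables
        # with the observed margins that are no more likely than observed
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            n, r1, c1 = a + b + c + d, a + b, a + c
            dist = st.hypergeom(n, r1, c1)
            support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
            pmf = dist.pmf(support)
            p_obs = dist.pmf(a)
            expected = pmf[pmf <= p_obs * (1 + 1e-9)].sum()
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                float(expected), abs=1e-10)

    def test_rejects_invalid_tables(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            fisher_exact([[-1, 2], [3, 4]])
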