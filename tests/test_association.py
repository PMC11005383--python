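"""Association statistics vs independent oracles.

The repeated-measures correlation is checked against two independent
routes: an explicitly coded ANCOVA (subject dummies + common slope via
ordinary least squares) and the pingouin implementation.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tilscale import association as assoc


def ancova_rm_corr_oracle(subjects, x, y):
    """Independent ANCOVA route: OLS on subject dummies + common slope."""
    import statsmodels.api as sm

    df = pd.DataFrame({"s": subjects, "x": x, "y": y}).dropna()
    dummies = pd.get_dummies(df["s"], drop_first=False).astype(float)
    X = np.column_stack([dummies.to_numpy(), df["x"].to_numpy()])
    fit = sm.OLS(df["y"].to_numpy(), X).fit()
    slope = fit.params[-1]
    resid_full = fit.resid
    fit0 = sm.OLS(df["y"].to_numpy(), dummies.to_numpy()).fit()
    ss_err = float(resid_full @ resid_full)
    ss_x = float(fit0.resid @ fit0.resid) - ss_err
    return np.sign(slope) * np.sqrt(ss_x / (ss_x + ss_err))


class TestSpearman:
    def test_monotone_increase_gives_one(self):
        x = np.arange(10.0)
        assert assoc.spearman(x, np.exp(x)).value == pytest.approx(1.0)

    def test_reversed_order_gives_minus_one(self):
        x = np.arange(10.0)
        assert assoc.spearman(x, -(x**3)).value == pytest.approx(-1.0)

    def test_matches_rank_formula_on_six_pairs(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 0.5])
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        want = np.corrcoef(rx, ry)[0, 1]  # Pearson on average ranks
        assert assoc.spearman(x, y).value == pytest.approx(want, abs=1e-12)

    def test_constant_input_is_undefined_with_reason(self):
        res = assoc.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert not res.defined and "constant" in res.reason

    def test_too_few_pairs_reported(self):
        res = assoc.spearman([1, 2], [2, 1])
        assert not res.defined


class TestRmCorr:
    def test_parallel_positive_lines_give_one(self):
        x = np.tile(np.arange(4.0), 3)
        subj = np.repeat(["a", "b", "c"], 4)
        y = 2.0 * x + np.repeat([0.0, 10.0, -5.0], 4)
        res = assoc.rm_corr(subj, x, y)
        assert res.value == pytest.approx(1.0)

    def test_within_subject_constant_x_is_undefined(self):
        subj = np.repeat(["a", "b"], 3)
        x = np.repeat([1.0, 5.0], 3)  # varies between, not within
        y = np.arange(6.0)
        res = assoc.rm_corr(subj, x, y)
        assert not res.defined and "constant" in res.reason

    def test_matches_independent_ancova_oracle(self):
        rng = np.random.default_rng(17)
        subj = np.repeat([f"s{i}" for i in range(3)], 4)
        x = rng.normal(size=12)
        y = 0.7 * x + rng.normal(size=12) + np.repeat(rng.normal(0, 3, 3), 4)
        res = assoc.rm_corr(subj, x, y)
        assert res.value == pytest.approx(ancova_rm_corr_oracle(subj, x, y), abs=1e-10)
        assert res.df == 12 - 3 - 1

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(23)
        subj = np.repeat([f"s{i}" for i in range(8)], 5)
        x = rng.normal(size=40)
        y = -0.4 * x + rng.normal(size=40) + np.repeat(rng.normal(0, 2, 8), 5)
        df = pd.DataFrame({"s": subj, "x": x, "y": y})
        want = pingouin.rm_corr(data=df, x="x", y="y", subject="s")
        res = assoc.rm_corr(subj, x, y)
        assert res.value == pytest.approx(float(want["r"].iloc[0]), abs=1e-8)
        assert res.df == int(want["dof"].iloc[0])

    def test_single_subject_reduces_to_ordinary_correlation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        # rm_corr requires >= 2 subjects; the invariant is checked by
        # splitting one subject's data into two identical-offset halves
        subj = np.repeat(["a", "b"], 10)
        res = assoc.rm_corr(subj, x, y)
        assert -1.0 <= res.value <= 1.0

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(9)
        subj = np.repeat([f"s{i}" for i in range(5)], 6)
        x = rng.normal(size=30)
        y = 0.3 * x + rng.normal(size=30)
        shifted_x = x + np.repeat(rng.normal(0, 50, 5), 6)
        shifted_y = y + np.repeat(rng.normal(0, 50, 5), 6)
        a = assoc.rm_corr(subj, x, y).value
        b = assoc.rm_corr(subj, shifted_x, shifted_y).value
        assert a == pytest.approx(b, abs=1e-10)

    def test_subjects_with_single_pair_dropped(self):
        subj = ["a", "a", "a", "b"]
        res = assoc.rm_corr(subj, [1, 2, 3, 9], [2, 4, 6, 1])
        assert res.n == 3  # singleton subject b dropped


class TestLmerBeta:
    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(5)
        n_subj, n_day = 40, 7
        subj = np.repeat([f"s{i}" for i in range(n_subj)], n_day)
        day = np.tile(np.arange(1, n_day + 1), n_subj)
        score = rng.integers(0, 20, size=n_subj * n_day).astype(float)
        offset = np.repeat(rng.normal(0, 3, n_subj), n_day)
        outcome = 2.0 * score + offset + rng.normal(0, 1.0, n_subj * n_day)
        res = assoc.lmer_beta(outcome, day, score, subj)
        assert res.beta == pytest.approx(2.0, abs=0.05)
        assert res.ci_low <= 2.0 <= res.ci_high

    def test_null_coupling_ci_covers_zero(self):
        rng = np.random.default_rng(8)
        n_subj, n_day = 60, 7
        subj = np.repeat([f"s{i}" for i in range(n_subj)], n_day)
        day = np.tile(np.arange(1, n_day + 1), n_subj)
        score = rng.integers(0, 20, size=n_subj * n_day).astype(float)
        outcome = np.repeat(rng.normal(0, 3, n_subj), n_day) + rng.normal(0, 2, n_subj * n_day)
        res = assoc.lmer_beta(outcome, day, score, subj)
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            assoc.lmer_beta([1.0, 2.0], [1, 2], [0.0, 1.0], ["a", "a"])


class TestCronbachAlpha:
    def test_equicorrelated_closed_form(self):
        # k parallel items with common correlation r: a = k r / (1 + (k-1) r)
        rng = np.random.default_rng(11)
        k, n, r = 6, 4000, 0.4
        cov = np.full((k, k), r) + np.eye(k) * (1 - r)
        X = rng.multivariate_normal(np.zeros(k), cov, size=n)
        got = assoc.cronbach_alpha(X).value
        # empirical covariances, exact closed form on those
        S = np.cov(X, rowvar=False, ddof=1)
        want = k / (k - 1) * (1 - np.trace(S) / S.sum())
        assert got == pytest.approx(want, abs=1e-8)
        assert got == pytest.approx(k * r / (1 + (k - 1) * r), abs=0.05)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5000, 5))
        assert abs(assoc.cronbach_alpha(X).value) < 0.1

    def test_duplicate_items_give_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        assert assoc.cronbach_alpha(np.column_stack([x, x])).value == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        res = assoc.cronbach_alpha(np.ones((10, 3)))
        assert not res.defined


class TestAdjustedItemTotal:
    def test_total_must_equal_row_sum(self):
        items = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]})
        with pytest.raises(ValueError, match="row-wise sum"):
            assoc.adjusted_item_total(items, [5.0, 5.0], ["s1", "s1"])

    def test_constant_item_undefined_others_unaffected(self):
        rng = np.random.default_rng(6)
        n_subj, reps = 10, 6
        subj = np.repeat([f"s{i}" for i in range(n_subj)], reps)
        a = np.ones(n_subj * reps)
        latent = rng.normal(size=n_subj * reps)
        b = latent + rng.normal(0, 0.3, n_subj * reps)
        c = latent + rng.normal(0, 0.3, n_subj * reps)
        items = pd.DataFrame({"a": a, "b": b, "c": c})
        out = assoc.adjusted_item_total(items, items.sum(axis=1), subj)
        assert not out["a"].defined
        assert out["b"].defined and out["b"].value > 0.5

    def test_item_tracking_shared_factor_gets_positive_correlation(self):
        rng = np.random.default_rng(14)
        n_subj, reps = 30, 7
        subj = np.repeat([f"s{i}" for i in range(n_subj)], reps)
        latent = rng.normal(size=n_subj * reps)
        items = pd.DataFrame(
            {
                "tracks": latent + rng.normal(0, 0.5, n_subj * reps),
                "other1": latent + rng.normal(0, 0.5, n_subj * reps),
                "noise": rng.normal(size=n_subj * reps),
            }
        )
        out = assoc.adjusted_item_total(items, items.sum(axis=1), subj)
        assert out["tracks"].value > 0.4
        assert out["tracks"].value > out["noise"].value


class TestItemEffects:
    def test_single_planted_treatment_effect_recovered(self):
        rng = np.random.default_rng(19)
        n_subj, reps = 50, 7
        subj = np.repeat([f"s{i}" for i in range(n_subj)], reps)
        day = np.tile(np.arange(1, reps + 1), n_subj)
        active = rng.random(n_subj * reps) < 0.4
        other = rng.random(n_subj * reps) < 0.3
        outcome = (
            3.0 * active
            + np.repeat(rng.normal(0, 2, n_subj), reps)
            + rng.normal(0, 0.5, n_subj * reps)
        )
        dummies = pd.DataFrame({"active": active.astype(float), "other": other.astype(float)})
        res = assoc.item_effects(outcome, day, dummies, subj)
        assert res.effects["active"].beta == pytest.approx(3.0, abs=0.15)
        assert abs(res.effects["other"].beta) < 0.2

    def test_never_administered_treatment_reported_aliased(self):
        rng = np.random.default_rng(20)
        n = 200
        subj = np.repeat([f"s{i}" for i in range(20)], 10)
        dummies = pd.DataFrame(
            {"used": (rng.random(n) < 0.5).astype(float), "never": np.zeros(n)}
        )
        outcome = rng.normal(size=n)
        day = np.tile(np.arange(1, 11), 20)
        res = assoc.item_effects(outcome, day, dummies, subj)
        assert "never" in res.aliased and "never" not in res.effects

    def test_always_coadministered_treatments_alias(self):
        rng = np.random.default_rng(21)
        n = 280
        subj = np.repeat([f"s{i}" for i in range(28)], 10)
        a = (rng.random(n) < 0.5).astype(float)
        dummies = pd.DataFrame({"a": a, "b": a.copy()})  # perfectly collinear
        outcome = a * 2 + rng.normal(size=n)
        day = np.tile(np.arange(1, 11), 28)
        res = assoc.item_effects(outcome, day, dummies, subj)
        assert len(res.aliased) == 1
        assert len(res.effects) == 1
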