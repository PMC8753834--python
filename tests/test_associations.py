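import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from histosig import (
    cox_regression,
    dichotomize,
    feature_association,
    logrank_test,
    rank_correlation,
    response_classification,
)
from histosig.simulate import generate_admixed_cohort, generate_survival


def _survival_frame(time, event):
    idx = pd.Index([f"s{i}" for i in range(len(time))], name="sample_id")
    return pd.DataFrame({"time": time, "event": event}, index=idx)


class TestDichotomize:
    def test_median_split(self):
        s = pd.Series([-1.0, 0.0, 1.0, 2.0], index=list("abcd"))
        high = dichotomize(s, "median")
        assert list(high[high].index) == ["c", "d"]

    def test_zero_cutoff_sends_ties_low(self):
        s = pd.Series([-1.0, 0.0, 1.0, 2.0], index=list("abcd"))
        high = dichotomize(s, "zero")
        assert list(high[high].index) == ["c", "d"]
        assert not high["b"]  # exactly at the cutoff -> low group

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            dichotomize(pd.Series([1.0, 1.0, 1.0]), "median")

    def test_balanced_split_on_distinct_scores(self, rng):
        s = pd.Series(rng.normal(size=101))
        high = dichotomize(s.rename(lambda i: f"s{i}"), "median")
        assert high.sum() == 50  # floor(n/2) above the median


class TestLogrank:
    def test_identical_groups_null(self):
        surv = _survival_frame([5, 8, 12, 5, 8, 12], [1, 0, 1, 1, 0, 1])
        groups = pd.Series([True] * 3 + [False] * 3, index=surv.index)
        chi2, p = logrank_test(groups, surv)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_event_is_uninformative(self):
        surv = _survival_frame([10, 10, 10, 10, 10, 7], [0, 0, 0, 0, 0, 1])
        groups = pd.Series([True, True, True, False, False, False], index=surv.index)
        _, p = logrank_test(groups, surv)
        assert p >= 0.3

    def test_invariant_to_label_swap(self, rng):
        surv = _survival_frame(rng.exponential(20, 40), rng.integers(0, 2, 40))
        groups = pd.Series(rng.random(40) < 0.5, index=surv.index)
        a = logrank_test(groups, surv)
        b = logrank_test(~groups, surv)
        assert a == pytest.approx(b)

    def test_strong_effect_detected(self, rng):
        """Exponential survival with hazard ratio 3, 150 per group."""
        rejected = 0
        for rep in range(10):
            r = np.random.default_rng(500 + rep)
            t_low = r.exponential(30.0, 150)
            t_high = r.exponential(10.0, 150)
            time = np.concatenate([t_low, t_high])
            event = (r.random(300) > 0.2).astype(int)
            surv = _survival_frame(time, event)
            groups = pd.Series([False] * 150 + [True] * 150, index=surv.index)
            _, p = logrank_test(groups, surv)
            rejected += p < 0.001
        assert rejected >= 9

    def test_empty_group_rejected(self):
        surv = _survival_frame([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError):
            logrank_test(pd.Series([True, True, True], index=surv.index), surv)


class TestCox:
    def test_hazard_ratio_recovery(self):
        """True HR 2 per SD of the risk score, n=300."""
        r = np.random.default_rng(77)
        z = r.normal(size=300)
        time = r.exponential(1.0 / (0.02 * np.exp(np.log(2) * z)))
        event = np.ones(300, int)
        surv = _survival_frame(time, event)
        fit = cox_regression(pd.Series(z, index=surv.index), surv)
        assert 1.6 <= fit.loc["score", "hr"] <= 2.5
        assert fit.loc["score", "ci_lower"] < fit.loc["score", "hr"] < fit.loc["score", "ci_upper"]

    def test_null_ci_coverage_near_nominal(self):
        covered = 0
        reps = 150
        for rep in range(reps):
            r = np.random.default_rng(3000 + rep)
            z = r.normal(size=100)
            surv = _survival_frame(r.exponential(20.0, 100), np.ones(100, int))
            fit = cox_regression(pd.Series(z, index=surv.index), surv)
            covered += fit.loc["score", "ci_lower"] <= 1.0 <= fit.loc["score", "ci_upper"]
        assert 0.90 <= covered / reps <= 0.99

    def test_multivariate_covariates_reported(self):
        r = np.random.default_rng(5)
        n = 120
        surv = _survival_frame(r.exponential(15.0, n), r.integers(0, 2, n))
        cov = pd.DataFrame(
            {"age": r.normal(65, 8, n), "sex": r.integers(0, 2, n), "stage": r.integers(0, 2, n)},
            index=surv.index,
        )
        fit = cox_regression(pd.Series(r.normal(size=n), index=surv.index), surv, cov)
        assert set(fit.index) == {"score", "age", "sex", "stage"}

    def test_all_censored_rejected(self):
        surv = _survival_frame([5.0, 6.0, 7.0, 8.0], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="events"):
            cox_regression(pd.Series([1.0, 2.0, 3.0, 4.0], index=surv.index), surv)


class TestFeatureAssociation:
    def test_exact_wilcoxon_bottom_three(self):
        """Altered group = 3 lowest of 10 distinct scores: p = 2/120."""
        scores = pd.Series(np.arange(1.0, 11.0), index=[f"s{i}" for i in range(10)])
        feats = pd.DataFrame(
            [[1, 1, 1, 0, 0, 0, 0, 0, 0, 0]], index=["mutA"], columns=scores.index
        )
        res = feature_association(scores, feats, min_count=3, alpha=0.05)
        assert res.loc["mutA", "p"] == pytest.approx(2 / 120, rel=1e-12)
        assert res.loc["mutA", "direction"] == -1
        assert bool(res.loc["mutA", "significant"])

    def test_min_count_boundary_excludes_feature(self, rng):
        scores = pd.Series(rng.normal(size=100), index=[f"s{i}" for i in range(100)])
        feats = pd.DataFrame(
            {
                "rare": (np.arange(100) < 19).astype(int),
                "common": (np.arange(100) < 25).astype(int),
            }
        ).T
        feats.columns = scores.index
        res = feature_association(scores, feats, min_count=20)
        assert "rare" not in res.index and "common" in res.index

    def test_no_feature_passing_filter_rejected(self, rng):
        scores = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        feats = pd.DataFrame([[1] * 5 + [0] * 25], index=["f"], columns=scores.index)
        with pytest.raises(ValueError, match="at least 20"):
            feature_association(scores, feats)

    def test_non_binary_rejected(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        feats = pd.DataFrame([[0, 1, 2]], index=["f"], columns=scores.index)
        with pytest.raises(ValueError, match="binary"):
            feature_association(scores, feats, min_count=1)


class TestRankCorrelation:
    def test_monotone_extremes(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        assert rank_correlation(s, s * 2 + 1)[0] == pytest.approx(1.0, abs=1e-12)
        assert rank_correlation(s, -s)[0] == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_rho(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        y = pd.Series([3.0, 1.0, 2.0, 5.0, 4.0], index=list("abcde"))
        rho, _ = rank_correlation(s, y)
        assert rho == pytest.approx(0.6)  # 1 - 6*8/(5*24)

    def test_missing_pairs_dropped_and_floor_enforced(self):
        s = pd.Series([1.0, 2, 3, 4, 5, 6], index=list("abcdef"))
        y = pd.Series([1.0, np.nan, 3, 4, 5, 6], index=list("abcdef"))
        rho, _ = rank_correlation(s, y)
        assert rho == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError, match="at least 5"):
            rank_correlation(s.iloc[:5], y.iloc[:5])


class TestResponseClassification:
    def test_perfect_separation(self):
        s = pd.Series([1.0, 2, 3, 10, 11, 12], index=list("abcdef"))
        y = pd.Series([0, 0, 0, 1, 1, 1], index=list("abcdef"))
        assert response_classification(s, y).auc == 1.0

    def test_all_scores_tied_gives_half(self):
        s = pd.Series([5.0] * 6, index=list("abcdef"))
        y = pd.Series([0, 0, 0, 1, 1, 1], index=list("abcdef"))
        assert response_classification(s, y).auc == 0.5

    def test_single_class_rejected(self):
        s = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError, match="classes"):
            response_classification(s, pd.Series([1, 1], index=list("ab")))

    def test_auc_equals_rank_sum_identity(self, rng):
        """AUC == U/(n1*n2) with ties counted one half, on every input."""
        for _ in range(50):
            n = int(rng.integers(6, 40))
            s = pd.Series(
                rng.choice([0.0, 0.5, 1.0, 2.0, 3.5], size=n),
                index=[f"s{i}" for i in range(n)],
            )
            y = pd.Series(rng.integers(0, 2, n), index=s.index)
            if y.min() == y.max():
                continue
            roc = response_classification(s, y)
            u = stats.mannwhitneyu(
                s[y == 1], s[y == 0], alternative="two-sided", method="asymptotic"
            ).statistic
            assert roc.auc == pytest.approx(u / (roc.n_pos * roc.n_neg), abs=1e-12)


class TestSyntheticSurvivalRecovery:
    def test_protective_lepidic_fraction(self):
        """Higher latent lepidic fraction lengthens survival in the generator."""
        _, truth = generate_admixed_cohort(
            n_samples=300, n_genes=100, n_planted_per_subtype=10, seed=21
        )
        surv = generate_survival(truth, seed=22, censoring_rate=0.0)
        frac = truth.fractions["lepidic"]
        risk = -(frac - frac.mean()) / frac.std(ddof=0)
        fit = cox_regression(risk, surv)
        assert 1.6 <= fit.loc["score", "hr"] <= 2.5
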