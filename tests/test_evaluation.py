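"""Evaluation statistics against brute-force and library oracles."""

import numpy as np
import pytest
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.metrics import silhouette_score

from contrasurv.data import EmbeddingMatrix, SurvivalOutcome, ValidationError
from contrasurv.evaluation import (UndefinedMetricError, bootstrap_ci,
                                   concordance_index, logrank_statistic,
                                   median_split_logrank, paired_fold_ttest,
                                   paired_model_compare,
                                   silhouette_by_survival)
from conftest import random_outcomes


def c_index_bruteforce(risks, outcomes):
    conc = ties = comp = 0
    n = len(outcomes)
    for i in range(n):
        for j in range(n):
            if outcomes.event[i] == 1 and outcomes.time[i] < outcomes.time[j]:
                comp += 1
                if risks[i] > risks[j]:
                    conc += 1
                elif risks[i] == risks[j]:
                    ties += 1
    return (conc + 0.5 * ties) / comp


class TestConcordance:
    def test_perfect_reverse_ordering(self):
        o = SurvivalOutcome([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert concordance_index([5, 4, 3, 2, 1], o) == 1.0

    def test_all_tied_risks_give_half(self):
        o = SurvivalOutcome([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index(np.ones(4), o) == 0.5

    def test_worked_example_with_censoring(self):
        o = SurvivalOutcome([1, 2, 3, 4], [1, 1, 0, 1])
        assert concordance_index([4, 2, 3, 1], o) == pytest.approx(0.8)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(500):
            n = int(rng.integers(3, 25))
            o = random_outcomes(rng, n, with_ties=bool(rng.integers(2)))
            risks = np.round(rng.standard_normal(n), 1)  # induce risk ties
            try:
                mine = concordance_index(risks, o)
            except UndefinedMetricError:
                with pytest.raises(ZeroDivisionError):
                    c_index_bruteforce(risks, o)
                continue
            assert mine == pytest.approx(c_index_bruteforce(risks, o),
                                         abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        o = random_outcomes(rng, 40)
        risks = rng.standard_normal(40)
        base = concordance_index(risks, o)
        assert concordance_index(np.exp(risks), o) == base
        assert concordance_index(3 * risks - 7, o) == base

    def test_reverse_risk_complement_identity(self, rng):
        o = random_outcomes(rng, 30)
        risks = rng.standard_normal(30)  # continuous, no ties
        assert concordance_index(risks, o) + concordance_index(-risks, o) \
            == pytest.approx(1.0)

    def test_no_comparable_pairs_is_undefined(self):
        o = SurvivalOutcome([1.0, 2.0], [0, 0])
        with pytest.raises(UndefinedMetricError):
            concordance_index([1.0, 2.0], o)


class TestBootstrapCI:
    def test_degenerate_metric_gives_point_interval(self, rng):
        o = random_outcomes(rng, 30)
        point, lo, hi = bootstrap_ci(np.ones(30), o, n_boot=200, seed=1)
        assert (point, lo, hi) == (0.5, 0.5, 0.5)

    def test_seeded_determinism(self, rng):
        o = random_outcomes(rng, 40)
        risks = rng.standard_normal(40)
        assert bootstrap_ci(risks, o, n_boot=200, seed=9) == \
            bootstrap_ci(risks, o, n_boot=200, seed=9)

    def test_interval_brackets_point_for_smooth_cases(self, rng):
        o = random_outcomes(rng, 60)
        risks = rng.standard_normal(60)
        point, lo, hi = bootstrap_ci(risks, o, n_boot=300, seed=2)
        assert lo <= point <= hi


class TestPairedCompare:
    def test_identical_models_give_p_one(self, rng):
        o = random_outcomes(rng, 30)
        risks = rng.standard_normal(30)
        assert paired_model_compare(risks, risks.copy(), o, n_boot=200,
                                    seed=0) == 1.0

    def test_symmetry_under_swap(self, rng):
        o = random_outcomes(rng, 40)
        a, b = rng.standard_normal(40), rng.standard_normal(40)
        assert paired_model_compare(a, b, o, n_boot=300, seed=5) == \
            paired_model_compare(b, a, o, n_boot=300, seed=5)

    def test_signal_vs_noise_detected(self, rng):
        from contrasurv.simulate import simulate_survival_times
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            lp = r.standard_normal(300) * 1.5
            o = simulate_survival_times(lp, 0.2, 0.3, seed=seed)
            noise = r.standard_normal(300)
            p = paired_model_compare(lp, noise, o, n_boot=300, seed=seed)
            hits += p < 0.05
        assert hits >= 9


class TestLogrankAndKM:
    def test_exchangeable_groups_give_null(self):
        t = np.array([1, 2, 3, 4, 1, 2, 3, 4], float)
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        o = SurvivalOutcome(t, e)
        groups = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        stat, p = logrank_statistic(o, groups)
        assert stat == pytest.approx(0.0, abs=1e-12) and p == 1.0

    def test_matches_hand_computed_hypergeometric_formula(self):
        t = np.array([1.0, 2, 3, 4, 5, 1.5, 2.5, 3.5, 4.5, 5.5])
        e = np.ones(10, int)
        g = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], bool)
        o = SurvivalOutcome(t, e)
        O1 = E1 = V = 0.0
        for tau in np.sort(t):
            at = t >= tau
            nj, n1j = at.sum(), (at & g).sum()
            dj = 1
            O1 += float(g[t == tau][0])
            E1 += dj * n1j / nj
            if nj > 1:
                V += (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
        stat, _ = logrank_statistic(o, g)
        assert stat == pytest.approx((O1 - E1) ** 2 / V, abs=1e-10)

    def test_agrees_with_lifelines(self, rng):
        o = random_outcomes(rng, 60)
        g = rng.integers(0, 2, 60).astype(bool)
        stat, p = logrank_statistic(o, g)
        ref = logrank_test(o.time[g], o.time[~g], o.event[g], o.event[~g])
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_label_swap_invariance(self, rng):
        o = random_outcomes(rng, 40)
        g = rng.integers(0, 2, 40).astype(bool)
        assert logrank_statistic(o, g)[0] == pytest.approx(
            logrank_statistic(o, ~g)[0], abs=1e-10)

    def test_median_split_curves_non_increasing_from_one(self, rng):
        o = random_outcomes(rng, 50)
        risks = rng.standard_normal(50)
        labels, curves, stat, p = median_split_logrank(risks, o)
        for curve in curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] <= 1.0 + 1e-12
            assert np.all(np.diff(s) <= 1e-12)
        assert 0 < p <= 1
        assert set(labels) == {"high", "low"}

    def test_no_event_group_stays_at_one(self):
        o = SurvivalOutcome([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0])
        risks = np.array([10, 9, 8, 1, 2, 3], float)
        _, curves, _, _ = median_split_logrank(risks, o)
        assert np.all(curves["low"]["survival"].to_numpy() == 1.0)

    def test_degenerate_split_rejected(self):
        o = SurvivalOutcome([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(UndefinedMetricError):
            median_split_logrank(np.ones(4), o)


class TestSilhouette:
    def make_embeddings(self, X):
        return EmbeddingMatrix([f"p{i}" for i in range(len(X))], X)

    def test_coincident_separated_pairs_score_one(self):
        X = np.array([[0, 0], [0, 0], [9, 9], [9, 9]], float)
        o = SurvivalOutcome([1, 1.5, 20, 30], [1, 1, 0, 0])
        assert silhouette_by_survival(self.make_embeddings(X), o,
                                      horizon=5.0) == pytest.approx(1.0)

    def test_identical_embeddings_score_zero(self):
        X = np.zeros((6, 3))
        o = SurvivalOutcome([1, 2, 3, 20, 30, 40], [1, 1, 1, 0, 0, 0])
        assert silhouette_by_survival(self.make_embeddings(X), o) == 0.0

    def test_matches_hand_computed_planar_example(self):
        X = np.array([[0.0, 0], [1, 0], [10, 0], [11, 0]])
        o = SurvivalOutcome([1, 2, 20, 30], [1, 1, 0, 0])
        s = np.empty(4)
        for i, (a_idx, b_idx) in enumerate([( [1], [2, 3]), ([0], [2, 3]),
                                            ([3], [0, 1]), ([2], [0, 1])]):
            a = np.mean([np.linalg.norm(X[i] - X[j]) for j in a_idx])
            b = np.mean([np.linalg.norm(X[i] - X[j]) for j in b_idx])
            s[i] = (b - a) / max(a, b)
        assert silhouette_by_survival(self.make_embeddings(X), o) == \
            pytest.approx(s.mean(), abs=1e-12)

    def test_censored_before_horizon_excluded(self):
        X = np.vstack([np.zeros((3, 2)), np.ones((3, 2)) * 5,
                       np.full((1, 2), 100.0)])
        o = SurvivalOutcome([1, 2, 3, 20, 30, 40, 2.0],
                            [1, 1, 1, 0, 0, 0, 0])  # last: censored @2
        with_ = silhouette_by_survival(self.make_embeddings(X), o)
        without = silhouette_by_survival(self.make_embeddings(X[:6]),
                                         SurvivalOutcome(o.time[:6],
                                                         o.event[:6]))
        assert with_ == pytest.approx(without)

    def test_agrees_with_sklearn_on_generic_data(self, rng):
        X = rng.standard_normal((30, 4))
        t = np.where(np.arange(30) < 15, 2.0, 50.0)
        o = SurvivalOutcome(t, np.where(np.arange(30) < 15, 1, 0))
        labels = (t <= 5).astype(int)
        assert silhouette_by_survival(self.make_embeddings(X), o) == \
            pytest.approx(silhouette_score(X, labels), abs=1e-10)

    def test_single_class_is_undefined(self):
        X = np.zeros((4, 2))
        o = SurvivalOutcome([20, 30, 40, 50], [0, 0, 0, 0])
        with pytest.raises(UndefinedMetricError):
            silhouette_by_survival(self.make_embeddings(X), o)


class TestPairedFoldTTest:
    def test_equal_scores_give_p_one(self):
        t, p = paired_fold_ttest([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert t == 0.0 and p == 1.0

    def test_consistent_improvement_gives_tiny_p(self, rng):
        a = np.array([0.50, 0.52, 0.51, 0.53, 0.50])
        b = a + 0.04 + rng.normal(0, 1e-4, 5)
        _, p = paired_fold_ttest(a, b)
        assert p < 1e-4

    def test_matches_t_distribution_oracle(self, rng):
        a = rng.uniform(0.4, 0.6, 5)
        b = a + rng.normal(0.01, 0.02, 5)
        t, p = paired_fold_ttest(a, b)
        d = b - a
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_ref = float(stats.t.sf(t_ref, df=4))
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_permuting_patients_leaves_metrics_unchanged(self, rng):
        o = random_outcomes(rng, 30)
        risks = rng.standard_normal(30)
        perm = rng.permutation(30)
        assert concordance_index(risks, o) == concordance_index(
            risks[perm], o.subset(perm))
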