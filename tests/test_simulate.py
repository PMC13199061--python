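"""Synthetic cohort generator: determinism, calibration, ground truth."""

import dataclasses

import numpy as np
import pytest
from sksurv.linear_model import CoxPHSurvivalAnalysis

from contrasurv.objectives import ConfigurationError
from contrasurv.simulate import (SimulationConfig, generate_cohort,
                                 generate_tile_embeddings,
                                 linear_predictor_from_truth,
                                 simulate_survival_times,
                                 strong_signal_config)


class TestConfigValidation:
    def test_causal_count_cannot_exceed_gene_count(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_mutation_genes=5, n_causal_mutations=6)

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_patients=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(tile_dim=0)

    def test_prevalence_range_must_be_inside_unit_interval(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(mutation_prevalence_range=(0.0, 0.5))

    def test_hazard_vector_length_must_match(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_causal_mutations=3,
                             mutation_log_hazards=np.ones(2))


class TestGenerateCohort:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_patients=10, n_mutation_genes=5, seed=7,
                               n_causal_mutations=3, tile_dim=4,
                               n_risk_classes=3)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.mutation_matrix.equals(b.mutation_matrix)
        assert a.clinical_table.equals(b.clinical_table)
        assert np.array_equal(a.outcomes.time, b.outcomes.time)
        assert np.array_equal(a.outcomes.event, b.outcomes.event)
        for p in a.patient_ids:
            assert np.array_equal(a.tile_embeddings[p], b.tile_embeddings[p])

    def test_zero_image_weight_decouples_tiles_from_hazard(self):
        cfg = SimulationConfig(n_patients=50, seed=3, image_signal_weight=0.0)
        cohort = generate_cohort(cfg)
        assert np.allclose(linear_predictor_from_truth(cohort),
                           cohort.true_linear_predictor)
        # all image-class effects are exactly zero
        assert all(v == 0.0 for v in
                   cohort.true_coefficients["image_class"].values())

    def test_event_rate_hits_target_within_five_points(self):
        cfg = SimulationConfig(n_patients=500, seed=1,
                               censoring_rate_target=0.76)
        cohort = generate_cohort(cfg)
        assert abs(cohort.outcomes.event_rate - 0.24) <= 0.05

    def test_truth_reproduces_linear_predictor_exactly(self):
        cohort = generate_cohort(SimulationConfig(n_patients=80, seed=9))
        assert np.allclose(linear_predictor_from_truth(cohort),
                           cohort.true_linear_predictor, atol=1e-12)

    def test_causal_prevalence_within_configured_range(self):
        cfg = SimulationConfig(n_patients=2000, seed=5,
                               mutation_prevalence_range=(0.2, 0.4))
        cohort = generate_cohort(cfg)
        prev = cohort.mutation_matrix.iloc[:, :cfg.n_causal_mutations].mean()
        assert ((prev > 0.12) & (prev < 0.48)).all()

    def test_prevalence_override_applies(self):
        cfg = dataclasses.replace(strong_signal_config(800, seed=2),
                                  mutation_prevalence_overrides={0: 0.02})
        cohort = generate_cohort(cfg)
        assert cohort.mutation_matrix.iloc[:, 0].mean() < 0.06


class TestSimulateSurvivalTimes:
    def test_no_censoring_limit_gives_all_events(self):
        out = simulate_survival_times(np.zeros(200), 0.1, 0.0, seed=1)
        assert out.event_rate == 1.0

    def test_exponential_race_probability(self):
        # lp (0, +2): P(high-risk dies first) = e^2/(1+e^2) ~ 0.8808
        rng_seed = 123
        lp = np.zeros(2 * 10_000)
        lp[1::2] = 2.0
        out = simulate_survival_times(lp, 1.0, 0.0, seed=rng_seed)
        t = out.time.reshape(-1, 2)
        frac = np.mean(t[:, 1] < t[:, 0])
        expected = np.exp(2) / (1 + np.exp(2))
        assert frac == pytest.approx(expected, abs=0.01)

    def test_seeded_determinism(self):
        lp = np.linspace(-1, 1, 30)
        a = simulate_survival_times(lp, 0.1, 0.5, seed=4)
        b = simulate_survival_times(lp, 0.1, 0.5, seed=4)
        assert np.array_equal(a.time, b.time)
        assert np.array_equal(a.event, b.event)

    def test_invalid_censoring_target_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_survival_times(np.zeros(5), 0.1, 1.2, seed=0)

    def test_no_tied_times(self):
        out = simulate_survival_times(np.zeros(500), 5.0, 0.3, seed=2)
        assert len(np.unique(out.time)) == 500


class TestTileEmbeddings:
    def test_exact_tile_counts_for_degenerate_range(self):
        cfg = SimulationConfig(n_patients=20, seed=1,
                               n_tiles_per_patient_range=(5, 5))
        cohort = generate_cohort(cfg)
        assert all(t.shape[0] == 5 for t in cohort.tile_embeddings.values())

    def test_zero_separation_means_indistinguishable(self):
        from scipy.stats import ttest_ind
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cls = rng.integers(0, 2, size=40)
            tiles = generate_tile_embeddings(cls, np.full(40, 10), 8, 0.0,
                                             seed)
            means = np.array([t.mean(axis=0) for t in tiles])
            _, p = ttest_ind(means[cls == 0, 0], means[cls == 1, 0])
            hits += p >= 0.05
        assert hits >= 18  # non-significant in >= 90% of seeds

    def test_high_separation_recovers_labels(self):
        rng = np.random.default_rng(0)
        cls = rng.integers(0, 3, size=300)
        tiles = generate_tile_embeddings(cls, np.full(300, 15), 8, 10.0,
                                         seed=1)
        means = np.array([t.mean(axis=0) for t in tiles])
        centroids = np.array([means[cls == k].mean(axis=0) for k in range(3)])
        pred = np.argmin(
            ((means[:, None, :] - centroids[None]) ** 2).sum(-1), axis=1)
        assert (pred == cls).mean() >= 0.99

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_tile_embeddings(np.zeros(3, int), np.zeros(3, int), 4,
                                     1.0, 0)


def test_hazard_faithfulness_cox_recovers_generating_coefficients():
    """A standard Cox fit on the true features of a large uncensored cohort
    recovers each generating log-hazard within +/-0.15."""
    cfg = SimulationConfig(n_patients=2000, seed=21, censoring_rate_target=0.0,
                           image_signal_weight=0.4)
    cohort = generate_cohort(cfg)
    rec = cohort.true_coefficients
    # design: causal mutations + standardised age + category indicators +
    # image-class indicators (reference class 0)
    cols, truth = [], []
    for gene, beta in rec["mutations"].items():
        cols.append(cohort.mutation_matrix[gene].to_numpy(float))
        truth.append(beta)
    for key, info in rec["clinical"].items():
        if "=" in key:
            name, level = key.split("=", 1)
            cols.append((cohort.clinical_table[name] == level).to_numpy(float))
        else:
            cols.append(((cohort.clinical_table[key] - info["center"])
                         / info["scale"]).to_numpy())
        truth.append(info["coef"])
    for k in (1, 2):
        cols.append((cohort.risk_class == k).astype(float))
        truth.append(rec["image_class"][str(k)] - rec["image_class"]["0"])
    X = np.column_stack(cols)
    y = np.array(list(zip(cohort.outcomes.event.astype(bool),
                          cohort.outcomes.time)),
                 dtype=[("e", bool), ("t", float)])
    fit = CoxPHSurvivalAnalysis().fit(X, y)
    assert np.max(np.abs(fit.coef_ - np.array(truth))) <= 0.15
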