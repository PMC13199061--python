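"""Mutation screening and clinical feature building."""

import io

import numpy as np
import pandas as pd
import pytest
from sksurv.linear_model import CoxPHSurvivalAnalysis

from contrasurv.data import SurvivalOutcome, ValidationError
from contrasurv.preprocess import (PreprocessState, build_feature_matrix,
                                   read_maf, screen_mutations,
                                   transform_mutations, univariate_cox)
from contrasurv.simulate import simulate_survival_times


def make_cohort(rng, n=200, beta=1.2, prevalence=0.3, n_null=5):
    causal = (rng.uniform(size=n) < prevalence).astype(int)
    nulls = rng.integers(0, 2, size=(n, n_null))
    outcomes = simulate_survival_times(beta * causal, 0.2, 0.3,
                                       seed=int(rng.integers(2**31)))
    genes = {"CAUSAL": causal}
    genes.update({f"N{j}": nulls[:, j] for j in range(n_null)})
    return pd.DataFrame(genes), outcomes


class TestScreenMutations:
    def test_zero_prevalence_excluded_before_testing(self, rng):
        muts, outcomes = make_cohort(rng)
        muts["EMPTY"] = 0
        selected, pvals = screen_mutations(muts, outcomes)
        assert "EMPTY" not in pvals.index
        assert "EMPTY" not in selected

    def test_all_zero_prevalence_warns_and_returns_empty(self, rng, caplog):
        muts = pd.DataFrame({"A": np.zeros(10, int), "B": np.zeros(10, int)})
        outcomes = SurvivalOutcome(np.arange(1, 11), np.ones(10, int))
        selected, pvals = screen_mutations(muts, outcomes)
        assert selected == [] and len(pvals) == 0

    def test_non_binary_matrix_rejected(self, rng):
        muts = pd.DataFrame({"A": [0, 1, 2]})
        outcomes = SurvivalOutcome([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValidationError, match="binary"):
            screen_mutations(muts, outcomes)

    def test_selection_monotone_in_alpha(self, rng):
        muts, outcomes = make_cohort(rng, n=150)
        s1, _ = screen_mutations(muts, outcomes, alpha=0.01)
        s2, _ = screen_mutations(muts, outcomes, alpha=0.10)
        assert set(s1) <= set(s2)

    def test_strong_gene_detected_with_high_power(self, rng):
        hits = 0
        for _ in range(30):
            muts, outcomes = make_cohort(rng, n=400, beta=1.5)
            selected, _ = screen_mutations(muts, outcomes, alpha=0.05)
            hits += "CAUSAL" in selected
        assert hits >= 29

    def test_breslow_estimates_match_scikit_survival(self, rng):
        muts, outcomes = make_cohort(rng, n=120)
        # force ties to exercise the shared-risk-set handling
        outcomes = SurvivalOutcome(np.round(outcomes.time, 1) + 0.05,
                                   outcomes.event)
        beta, _ = univariate_cox(muts.to_numpy(float), outcomes)
        y = np.array(list(zip(outcomes.event.astype(bool), outcomes.time)),
                     dtype=[("e", bool), ("t", float)])
        for j in range(muts.shape[1]):
            ref = CoxPHSurvivalAnalysis().fit(
                muts.to_numpy(float)[:, [j]], y).coef_[0]
            assert beta[j] == pytest.approx(ref, abs=1e-6)


class TestTransformMutations:
    def test_absent_genes_zero_filled(self):
        muts = pd.DataFrame({"A": [1, 0]}, index=["p1", "p2"])
        out = transform_mutations(muts, ["A", "B"])
        assert list(out.columns) == ["A", "B"]
        assert (out["B"] == 0).all()


class TestBuildFeatureMatrix:
    def test_zscore_symmetric_case(self):
        # sample SD (n-1) of [1,2,3] is exactly 1
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=list("abc"))
        fm, _ = build_feature_matrix(df, {"x": "continuous"})
        np.testing.assert_allclose(fm.values[:, 0], [-1.0, 0.0, 1.0],
                                   atol=1e-12)

    def test_onehot_with_missing_category_partitions(self):
        df = pd.DataFrame({"g": ["A", "B", None]}, index=list("abc"))
        fm, state = build_feature_matrix(df, {"g": "categorical"},
                                         missing_category=True)
        assert fm.values.shape[1] == 3
        np.testing.assert_allclose(fm.values.sum(axis=1), 1.0)
        assert "g=missing" in fm.feature_names

    def test_mean_imputation_before_scaling(self):
        df = pd.DataFrame({"x": [10.0, np.nan, 30.0]}, index=list("abc"))
        fm, state = build_feature_matrix(df, {"x": "continuous"})
        assert state.impute_values["x"] == pytest.approx(20.0)
        assert fm.values[1, 0] == pytest.approx(0.0)  # imputed to the mean

    def test_transform_idempotence(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(20),
                           "g": rng.choice(["u", "v"], 20)},
                          index=[f"p{i}" for i in range(20)])
        schema = {"x": "continuous", "g": "categorical"}
        fm, state = build_feature_matrix(df, schema)
        fm2, _ = build_feature_matrix(df, schema, state=state)
        np.testing.assert_array_equal(fm.values, fm2.values)

    def test_no_leakage_state_unchanged_by_transform(self, rng):
        train = pd.DataFrame({"x": rng.standard_normal(10),
                              "g": rng.choice(["u", "v"], 10)},
                             index=[f"p{i}" for i in range(10)])
        schema = {"x": "continuous", "g": "categorical"}
        _, state = build_feature_matrix(train, schema)
        snapshot = {"means": dict(state.means), "sds": dict(state.sds),
                    "levels": {k: list(v) for k, v in state.levels.items()}}
        extreme = pd.DataFrame({"x": [1e9, -1e9], "g": ["zzz", "u"]},
                               index=["q1", "q2"])
        build_feature_matrix(extreme, schema, state=state)
        assert state.means == snapshot["means"]
        assert state.sds == snapshot["sds"]
        assert {k: list(v) for k, v in state.levels.items()} == \
            snapshot["levels"]

    def test_unseen_level_maps_to_all_zero_indicators(self, rng):
        train = pd.DataFrame({"g": ["u", "v", "u"]}, index=list("abc"))
        _, state = build_feature_matrix(train, {"g": "categorical"})
        test = pd.DataFrame({"g": ["w"]}, index=["z"])
        fm, _ = build_feature_matrix(test, {"g": "categorical"}, state=state)
        np.testing.assert_array_equal(fm.values, [[0.0, 0.0]])

    def test_constant_column_becomes_zeros(self):
        df = pd.DataFrame({"x": [5.0, 5.0, 5.0]}, index=list("abc"))
        fm, state = build_feature_matrix(df, {"x": "continuous"})
        assert state.sds["x"] == 1.0
        np.testing.assert_array_equal(fm.values[:, 0], np.zeros(3))

    def test_continuous_features_standardised_on_fit_cohort(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(50) * 7 + 3},
                          index=[f"p{i}" for i in range(50)])
        fm, _ = build_feature_matrix(df, {"x": "continuous"})
        assert fm.values[:, 0].mean() == pytest.approx(0.0, abs=1e-6)
        assert fm.values[:, 0].std(ddof=1) == pytest.approx(1.0, abs=1e-6)

    def test_state_round_trips_through_json(self, rng, tmp_path):
        df = pd.DataFrame({"x": rng.standard_normal(8),
                           "g": rng.choice(["u", "v"], 8)},
                          index=[f"p{i}" for i in range(8)])
        schema = {"x": "continuous", "g": "categorical"}
        fm, state = build_feature_matrix(df, schema)
        state.to_json(tmp_path / "state.json")
        loaded = PreprocessState.from_json(tmp_path / "state.json")
        fm2, _ = build_feature_matrix(df, schema, state=loaded)
        np.testing.assert_allclose(fm.values, fm2.values)


def test_maf_reader_collapses_to_binary_and_drops_silent():
    maf = io.StringIO(
        "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n"
        "TP53\tP1\tMissense_Mutation\n"
        "TP53\tP1\tNonsense_Mutation\n"
        "IDH1\tP2\tMissense_Mutation\n"
        "EGFR\tP1\tSilent\n")
    table = read_maf(maf)
    assert table.loc["P1", "TP53"] == 1
    assert table.loc["P2", "IDH1"] == 1
    assert "EGFR" not in table.columns
    assert set(table.to_numpy().ravel()) <= {0, 1}
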