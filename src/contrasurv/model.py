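"""High-level modelling interface.

:class:`MultimodalCoxModel` is built from a :class:`~contrasurv.data.Cohort`
(or the underlying tables) and ``fit()`` runs the full three-stage,
cross-validated pipeline, returning a :class:`MultimodalCoxResults`
carrying per-fold and pooled concordance estimates with bootstrap
uncertainty, risk stratification diagnostics, representation-quality
scores, and the post-selection feature-importance table.

Example
-------
>>> from contrasurv import MultimodalCoxModel, SimulationConfig, generate_cohort
>>> cohort = generate_cohort(SimulationConfig(n_patients=200, seed=1))
>>> model = MultimodalCoxModel.from_cohort(cohort)
>>> results = model.fit(k=3, seed=1)
>>> print(results.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import pipeline as pl
from .data import Cohort, EmbeddingMatrix, SurvivalOutcome, ValidationError
from .interpret import ImportanceTable, lasso_ols_importance
from .io import default_schema_for, derive_seed
from .preprocess import FeatureMatrix

__all__ = ["MultimodalCoxModel", "MultimodalCoxResults"]


class MultimodalCoxModel:
    """Contrastive multimodal Cox survival model.

    Parameters
    ----------
    cohort : aligned multimodal cohort (mutations, clinical, tile
        embeddings, outcomes).
    schema : clinical column kinds ({name: "continuous"|"categorical"});
        inferred from dtypes when omitted.
    training : optional :class:`~contrasurv.pipeline.TrainingConfig`.
    """

    def __init__(self, cohort: Cohort, schema: dict[str, str] | None = None,
                 training: pl.TrainingConfig | None = None,
                 screening_alpha: float = 0.05):
        self.cohort = cohort
        self.schema = schema or default_schema_for(cohort.clinical_table)
        self.training = training or pl.TrainingConfig()
        self.screening_alpha = screening_alpha

    @classmethod
    def from_cohort(cls, cohort: Cohort, **kwargs) -> "MultimodalCoxModel":
        return cls(cohort, **kwargs)

    @classmethod
    def from_dataframes(cls, clinical: pd.DataFrame, mutations: pd.DataFrame,
                        tile_embeddings: dict[str, np.ndarray],
                        outcomes: pd.DataFrame, **kwargs
                        ) -> "MultimodalCoxModel":
        ids = [str(i) for i in clinical.index]
        cohort = Cohort(patient_ids=ids, mutation_matrix=mutations.loc[ids],
                        clinical_table=clinical,
                        tile_embeddings=tile_embeddings,
                        outcomes=SurvivalOutcome.from_frame(
                            outcomes.loc[ids]))
        return cls(cohort, **kwargs)

    def fit(self, k: int = 5, seed: int = 0, use_stage2: bool = True,
            n_boot: int = 1000) -> "MultimodalCoxResults":
        """Run event-stratified k-fold cross-validation of the pipeline."""
        self.training.seed = derive_seed(seed, "training")
        folds = pl.make_folds(self.cohort.outcomes, k, derive_seed(seed,
                                                                   "folds"))
        cv = pl.cross_validate(self.cohort, self.training, folds, self.schema,
                               alpha=self.screening_alpha,
                               use_stage2=use_stage2)
        return MultimodalCoxResults(model=self, cv=cv, seed=seed,
                                    n_boot=n_boot, use_stage2=use_stage2)


@dataclass
class MultimodalCoxResults:
    """Fit artifacts and the evaluation/interpretation stack over them."""

    model: MultimodalCoxModel
    cv: pl.CVResult
    seed: int
    n_boot: int = 1000
    use_stage2: bool = True
    _cache: dict = field(default_factory=dict, repr=False)

    # -- risks and concordance ----------------------------------------------
    @property
    def outcomes(self) -> SurvivalOutcome:
        return self.model.cohort.outcomes

    def risks(self, modality: str = "fused") -> pd.Series:
        """Out-of-fold validation risks, aligned to cohort order."""
        return self.cv.val_risks[modality].reindex(
            self.model.cohort.patient_ids)

    def fold_c_index(self, modality: str = "fused") -> pd.Series:
        return self.cv.fold_c_indices[modality]

    def c_index(self, modality: str = "fused") -> tuple[float, float, float]:
        """Pooled out-of-fold c-index with a percentile bootstrap CI."""
        key = ("ci", modality)
        if key not in self._cache:
            self._cache[key] = ev.bootstrap_ci(
                self.risks(modality).to_numpy(), self.outcomes,
                n_boot=self.n_boot, seed=derive_seed(self.seed, "bootstrap"))
        return self._cache[key]

    def compare(self, modality_a: str, modality_b: str) -> float:
        """Paired bootstrap p-value for c(a) - c(b) on shared resamples."""
        return ev.paired_model_compare(
            self.risks(modality_a).to_numpy(),
            self.risks(modality_b).to_numpy(), self.outcomes,
            n_boot=self.n_boot, seed=derive_seed(self.seed, "compare"))

    def ensemble_risks(self, modality: str = "fused") -> pd.Series:
        key = ("ens", modality)
        if key not in self._cache:
            self._cache[key] = pl.ensemble_risk(
                self.cv, self.model.cohort, self.model.schema, modality)
        return self._cache[key]

    # -- stratification & representations ------------------------------------
    def stratify(self, modality: str = "fused"):
        """Median split -> KM curves -> log-rank (labels, curves, stat, p)."""
        return ev.median_split_logrank(self.risks(modality).to_numpy(),
                                       self.outcomes)

    def silhouette_by_fold(self, which: str = "post",
                           horizon: float = 5.0) -> np.ndarray:
        """Per-fold silhouette of validation fused embeddings by survival
        status; ``which`` selects 'pre' (before contrastive alignment) or
        'post' (after)."""
        scores = []
        for fold, embs in enumerate(self.cv.fold_embeddings):
            emb: EmbeddingMatrix = embs[which]
            idx = np.where(self.cv.folds.assignments == fold)[0]
            scores.append(ev.silhouette_by_survival(
                emb, self.outcomes.subset(idx), horizon))
        return np.array(scores)

    def silhouette_change(self, horizon: float = 5.0):
        """Paired t-test on per-fold silhouettes pre vs post alignment."""
        pre = self.silhouette_by_fold("pre", horizon)
        post = self.silhouette_by_fold("post", horizon)
        t, p = ev.paired_fold_ttest(pre, post)
        return {"pre": pre, "post": post, "t": t, "p": p}

    # -- interpretation -------------------------------------------------------
    def importance(self, response: str = "risk",
                   seed: int | None = None) -> ImportanceTable:
        """Lasso -> OLS importance of non-image features.

        ``response``: 'risk' (fused out-of-fold prediction, default),
        'time' (log follow-up) or 'event'.
        """
        data, state = pl.prepare_cohort(self.model.cohort, self.model.schema,
                                        alpha=self.model.screening_alpha)
        X = np.hstack([data.mutation_X, data.clinical_X])
        from .io import _clinical_feature_names
        names = state.selected_genes + _clinical_feature_names(
            self.model.cohort, self.model.schema, state)
        fm = FeatureMatrix(self.model.cohort.patient_ids, names, X)
        if response == "risk":
            y = self.risks("fused").to_numpy()
        elif response == "time":
            y = np.log(self.outcomes.time)
        elif response == "event":
            y = self.outcomes.event.astype(float)
        else:
            raise ValidationError("response must be risk, time, or event")
        return lasso_ols_importance(
            fm, y, seed=derive_seed(seed if seed is not None else self.seed,
                                    "lasso"))

    # -- external cohorts ----------------------------------------------------
    def adapt(self, external_cohort: Cohort, fraction: float = 0.2,
              epochs: int = 10, seed: int | None = None,
              fold: int = 0) -> tuple[dict, dict]:
        """Zero-shot and domain-adapted evaluation of one fold model on an
        external cohort preprocessed with that fold's fitted state."""
        return pl.domain_adapt_evaluate(
            self.cv.fold_models[fold], self.cv.fold_states[fold],
            external_cohort, self.model.schema, fraction=fraction,
            epochs=epochs,
            seed=derive_seed(seed if seed is not None else self.seed,
                             "adapt"), n_boot=self.n_boot)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        lines = ["Contrastive multimodal Cox survival model",
                 "=" * 57,
                 f"patients: {len(self.model.cohort):>5d}   "
                 f"events: {self.outcomes.n_events} "
                 f"({100 * self.outcomes.event_rate:.1f}%)   "
                 f"folds: {self.cv.folds.k}   stage 2: "
                 f"{'on' if self.use_stage2 else 'off'}",
                 "-" * 57,
                 f"{'modality':<12} {'c-index':>8} {'95% CI':>18} "
                 f"{'fold mean':>10}"]
        for modality in self.cv.fold_c_indices.columns:
            point, lo, hi = self.c_index(modality)
            lines.append(f"{modality:<12} {point:8.3f} "
                         f"[{lo:7.3f}, {hi:7.3f}] "
                         f"{self.fold_c_index(modality).mean():10.3f}")
        try:
            _, _, stat, p = self.stratify("fused")
            lines.append("-" * 57)
            lines.append(f"median-split log-rank: chi2(1) = {stat:.2f}, "
                         f"p = {p:.2e}")
        except Exception:
            pass
        lines.append("=" * 57)
        return "\n".join(lines)
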