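"""Non-image preprocessing: mutation screening, encoding, scaling, imputation.

Mutation columns are binary presence/absence per gene. Screening removes
zero-prevalence genes and keeps genes whose single-covariate Cox
proportional-hazards Wald test reaches ``p < alpha``. Clinical tables are
one-hot encoded (categorical) and z-scored (continuous, sample SD with
denominator n-1) with mean/mode imputation or an explicit "missing"
category; all statistics are fitted once on training data and carried in a
:class:`PreprocessState` so that transforming validation or external data
never refits anything.

The univariate Cox screen is a vectorised Newton-Raphson solver across
genes (Breslow tie handling), since screening runs inside every
cross-validation fold and calibration tests sweep thousands of null genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data import SurvivalOutcome, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["PreprocessState", "FeatureMatrix", "screen_mutations",
           "build_feature_matrix", "transform_mutations", "read_maf",
           "univariate_cox"]

MISSING_LEVEL = "missing"


# --------------------------------------------------------------------------
# univariate Cox screening
# --------------------------------------------------------------------------

def univariate_cox(X: np.ndarray, outcomes: SurvivalOutcome,
                   max_iter: int = 40, tol: float = 1e-9,
                   beta_cap: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Single-covariate Cox PH fits for every column of ``X`` at once.

    Returns (coefficients, two-sided Wald p-values). Breslow handling:
    the risk set at an event time T is every patient with time >= T,
    tied event times sharing the same risk set. Columns with zero
    variance get beta = 0, p = 1. Monotone-likelihood fits are capped at
    ``|beta| <= beta_cap``.
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, g = X.shape
    order = np.argsort(outcomes.time, kind="stable")
    t = outcomes.time[order]
    d = outcomes.event[order]
    Xs = X[order]
    event_pos = np.where(d == 1)[0]
    # suffix start index of each event's risk set (ties share a set)
    risk_start = np.searchsorted(t, t[event_pos], side="left")

    def score_info(Xa: np.ndarray, b: np.ndarray):
        w = np.exp(np.clip(Xa * b[None, :], -700, 700))
        s0 = np.cumsum(w[::-1], axis=0)[::-1]
        s1 = np.cumsum((Xa * w)[::-1], axis=0)[::-1]
        s2 = np.cumsum((Xa**2 * w)[::-1], axis=0)[::-1]
        r0 = s0[risk_start]
        mu = s1[risk_start] / r0
        U = (Xa[event_pos] - mu).sum(axis=0)
        I = np.maximum((s2[risk_start] / r0 - mu**2).sum(axis=0), 1e-12)
        return U, I

    variable = Xs.std(axis=0) > 0
    beta = np.zeros(g)
    pvals = np.ones(g)
    if variable.any():
        Xa = Xs[:, variable]
        b = np.zeros(int(variable.sum()))
        for _ in range(max_iter):
            U, I = score_info(Xa, b)
            step = np.clip(U / I, -1.0, 1.0)
            b = np.clip(b + step, -beta_cap, beta_cap)
            if np.max(np.abs(step)) < tol:
                break
        _, I = score_info(Xa, b)
        se = 1.0 / np.sqrt(I)
        beta[variable] = b
        pvals[variable] = 2.0 * stats.norm.sf(np.abs(b / se))
    return beta, pvals


def screen_mutations(mutations: pd.DataFrame, outcomes: SurvivalOutcome,
                     alpha: float = 0.05) -> tuple[list[str], pd.Series]:
    """Select survival-associated genes by univariate Cox Wald tests.

    Zero-prevalence genes are removed before testing; remaining genes with
    Wald p < ``alpha`` are returned in their original column order,
    together with the per-gene p-values of every tested gene.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0,1)")
    vals = mutations.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValidationError("mutation matrix must be binary 0/1")
    if len(mutations) != len(outcomes):
        raise ValidationError("mutations and outcomes misaligned")
    prevalence = vals.sum(axis=0)
    testable = prevalence > 0
    if not testable.any():
        logger.warning("all genes have zero prevalence; empty selection")
        return [], pd.Series(dtype=float)
    tested_genes = mutations.columns[testable]
    _, pvals = univariate_cox(vals[:, testable], outcomes)
    pseries = pd.Series(pvals, index=tested_genes, name="p_value")
    selected = [g for g in mutations.columns
                if g in pseries.index and pseries[g] < alpha]
    return selected, pseries


def transform_mutations(mutations: pd.DataFrame,
                        selected_genes: list[str]) -> pd.DataFrame:
    """Restrict to the screened gene list; absent genes are zero-filled.

    Zero-filling mirrors deployment on external cohorts whose sequencing
    panel lacks some training-cohort genes.
    """
    out = pd.DataFrame(0, index=mutations.index, columns=selected_genes,
                       dtype=float)
    present = [g for g in selected_genes if g in mutations.columns]
    absent = [g for g in selected_genes if g not in mutations.columns]
    if absent:
        logger.warning("zero-filling %d genes absent from cohort: %s",
                       len(absent), absent[:5])
    out[present] = mutations[present].astype(float)
    return out


# --------------------------------------------------------------------------
# clinical feature building
# --------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Fully numeric, NA-free design matrix with per-feature provenance."""

    patient_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    provenance: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids,
                            columns=self.feature_names)


@dataclass
class PreprocessState:
    """Fitted preprocessing statistics; fit once, transform many times."""

    schema: dict[str, str]
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    impute_values: dict[str, object] = field(default_factory=dict)
    levels: dict[str, list[str]] = field(default_factory=dict)
    selected_genes: list[str] = field(default_factory=list)
    screening_pvalues: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessState":
        return cls(**json.loads(Path(path).read_text()))


def build_feature_matrix(clinical: pd.DataFrame, schema: dict[str, str],
                         state: PreprocessState | None = None,
                         missing_category: bool = True,
                         ) -> tuple[FeatureMatrix, PreprocessState]:
    """Encode a mixed-type clinical table into a numeric design matrix.

    When ``state`` is None the means/SDs/modes/levels are fitted on
    ``clinical``; otherwise the fitted state is applied unchanged.
    Continuous columns: mean-impute then z-score (sample SD, n-1);
    constant columns become all-zeros. Categorical columns: one indicator
    per fitted level, with an explicit "missing" level when
    ``missing_category`` and NAs were seen at fit time; unseen levels at
    transform time map to all-zero indicators.
    """
    fitting = state is None
    if fitting:
        state = PreprocessState(schema=dict(schema))
    cols, names, prov = [], [], {}
    for col, kind in schema.items():
        series = clinical[col] if col in clinical else pd.Series(
            np.nan, index=clinical.index)
        if kind == "continuous":
            x = pd.to_numeric(series, errors="coerce")
            if fitting:
                mean = float(x.mean()) if x.notna().any() else 0.0
                filled = x.fillna(mean)
                sd = float(filled.std(ddof=1)) if len(filled) > 1 else 0.0
                if not np.isfinite(sd) or sd == 0:
                    sd = 1.0
                    logger.warning("constant continuous column %r", col)
                state.means[col] = mean
                state.sds[col] = sd
                state.impute_values[col] = mean
            mean, sd = state.means[col], state.sds[col]
            z = (x.fillna(state.impute_values[col]) - mean) / sd
            cols.append(z.to_numpy(float))
            names.append(col)
            prov[col] = {"source": col, "encoding": "zscore",
                         "imputation": "mean"}
        elif kind == "categorical":
            x = series.astype(object).where(series.notna(), other=None)
            if fitting:
                observed = sorted({str(v) for v in x if v is not None})
                has_na = any(v is None for v in x)
                if has_na and missing_category:
                    observed = observed + [MISSING_LEVEL]
                    mode = MISSING_LEVEL
                else:
                    counts = pd.Series([str(v) for v in x if v is not None])
                    mode = counts.mode().iloc[0] if len(counts) else MISSING_LEVEL
                state.levels[col] = observed
                state.impute_values[col] = mode
            lv = state.levels[col]
            fill = state.impute_values[col]
            vals = [fill if v is None else str(v) for v in x]
            unseen = sorted({v for v in vals if v not in lv})
            if unseen:
                logger.warning("unseen levels in %r mapped to zeros: %s",
                               col, unseen)
            for level in lv:
                cols.append(np.array([1.0 if v == level else 0.0
                                      for v in vals]))
                names.append(f"{col}={level}")
                prov[f"{col}={level}"] = {"source": col, "encoding": "onehot",
                                          "imputation": str(fill)}
        else:
            raise ValidationError(f"unknown column kind {kind!r} for {col!r}")
    values = np.column_stack(cols) if cols else np.empty((len(clinical), 0))
    fm = FeatureMatrix(list(map(str, clinical.index)), names, values, prov)
    return fm, state


# --------------------------------------------------------------------------
# MAF ingestion
# --------------------------------------------------------------------------

def read_maf(path: str | Path,
             exclude_classes: tuple[str, ...] = ("Silent",)) -> pd.DataFrame:
    """Collapse a MAF file to a binary patient x gene mutation matrix."""
    maf = pd.read_csv(path, sep="\t", comment="#", low_memory=False)
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode"}
    if not required.issubset(maf.columns):
        raise ValidationError(f"MAF must contain columns {sorted(required)}")
    if "Variant_Classification" in maf.columns and exclude_classes:
        maf = maf[~maf["Variant_Classification"].isin(exclude_classes)]
    table = pd.crosstab(maf["Tumor_Sample_Barcode"], maf["Hugo_Symbol"])
    return (table > 0).astype(int).rename_axis(index=None, columns=None)
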