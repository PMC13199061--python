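"""Survival evaluation statistics.

Harrell's concordance index with percentile-bootstrap confidence
intervals and paired bootstrap model comparison, median-split risk
stratification with Kaplan-Meier curves and the two-group log-rank test,
silhouette scores of embeddings labelled by 5-year survival status, and a
paired t-test across cross-validation folds.

Conventions (stated because survival toolkits differ): a pair (i, j) is
comparable when T_i < T_j and patient i had the event; tied risk scores
in a comparable pair count 0.5; pairs with equal times and both events
are excluded. Patients censored before the silhouette horizon have
unknown 5-year status and are excluded from the labelling (counts are
reported). The median split sends risks exactly at the median to the
low-risk group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from scipy.spatial.distance import cdist

from .data import EmbeddingMatrix, SurvivalOutcome, ValidationError

__all__ = ["EvaluationReport", "concordance_index", "bootstrap_ci",
           "paired_model_compare", "median_split_logrank",
           "silhouette_by_survival", "paired_fold_ttest", "evaluate_risks"]


class UndefinedMetricError(ValueError):
    pass


def _pair_masks(outcomes: SurvivalOutcome):
    t, e = outcomes.time, outcomes.event
    return (t[:, None] < t[None, :]) & (e[:, None] == 1)


def concordance_index(risks: np.ndarray, outcomes: SurvivalOutcome) -> float:
    """Harrell's c: fraction of comparable pairs ranked correctly."""
    r = np.asarray(risks, float)
    if r.shape[0] != len(outcomes):
        raise ValidationError("risks and outcomes misaligned")
    comparable = _pair_masks(outcomes)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise UndefinedMetricError("no comparable pairs")
    higher = r[:, None] > r[None, :]
    tied = r[:, None] == r[None, :]
    concordant = (higher & comparable).sum()
    ties = (tied & comparable).sum()
    return float((concordant + 0.5 * ties) / n_comp)


def bootstrap_ci(risks: np.ndarray, outcomes: SurvivalOutcome,
                 n_boot: int = 1000, seed: int = 0, level: float = 0.95,
                 ) -> tuple[float, float, float]:
    """Percentile bootstrap interval for the c-index.

    Patients are resampled with replacement; replicates without a
    comparable pair are redrawn (their count is tracked but rare beyond
    toy sizes). Returns (point estimate, low, high).
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    r = np.asarray(risks, float)
    n = len(outcomes)
    point = concordance_index(r, outcomes)
    reps = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                reps[b] = concordance_index(r[idx], outcomes.subset(idx))
                break
            except UndefinedMetricError:
                redraws += 1
                if redraws > 100 * n_boot:
                    raise
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [a, 1.0 - a])
    return point, float(lo), float(hi)


def paired_model_compare(risks_a: np.ndarray, risks_b: np.ndarray,
                         outcomes: SurvivalOutcome, n_boot: int = 1000,
                         seed: int = 0) -> float:
    """Two-sided bootstrap p-value for c(a) - c(b), same resamples for both."""
    ra, rb = np.asarray(risks_a, float), np.asarray(risks_b, float)
    if ra.shape != rb.shape or ra.shape[0] != len(outcomes):
        raise ValidationError("risk vectors must align with outcomes")
    rng = np.random.default_rng(seed)
    n = len(outcomes)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            sub = outcomes.subset(idx)
            try:
                deltas[b] = (concordance_index(ra[idx], sub)
                             - concordance_index(rb[idx], sub))
                break
            except UndefinedMetricError:
                continue
    n_le = int((deltas <= 0).sum())
    n_ge = int((deltas >= 0).sum())
    p = 2.0 * min((n_le + 1) / (n_boot + 1), (n_ge + 1) / (n_boot + 1))
    return float(min(p, 1.0))


def _km_curve(outcomes: SurvivalOutcome) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(outcomes.time, outcomes.event)
    sf = kmf.survival_function_.iloc[:, 0]
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
    return pd.DataFrame({"time": sf.index.to_numpy(),
                         "survival": sf.to_numpy(),
                         "at_risk": at_risk.to_numpy()})


def logrank_statistic(outcomes: SurvivalOutcome,
                      groups: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank test: (O-E)^2/V against chi-square(1)."""
    g = np.asarray(groups).astype(bool)
    t, e = outcomes.time, outcomes.event
    event_times = np.unique(t[e == 1])
    O1 = E1 = V = 0.0
    for tau in event_times:
        at_risk = t >= tau
        n_j = at_risk.sum()
        n1_j = (at_risk & g).sum()
        d_j = ((t == tau) & (e == 1)).sum()
        d1_j = ((t == tau) & (e == 1) & g).sum()
        O1 += d1_j
        E1 += d_j * n1_j / n_j
        if n_j > 1:
            V += d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    if V <= 0:
        return 0.0, 1.0
    stat = (O1 - E1) ** 2 / V
    return float(stat), float(stats.chi2.sf(stat, df=1))


def median_split_logrank(risks: np.ndarray, outcomes: SurvivalOutcome):
    """Median risk split -> KM curves per group -> log-rank test.

    Returns (group labels, {"high": df, "low": df}, statistic, p_value).
    """
    r = np.asarray(risks, float)
    if r.size < 4:
        raise ValidationError("need at least 4 patients for a median split")
    med = np.median(r)
    high = r > med
    if high.all() or (~high).all():
        raise UndefinedMetricError(
            "degenerate median split: all risks on one side")
    curves = {"high": _km_curve(outcomes.subset(high)),
              "low": _km_curve(outcomes.subset(~high))}
    stat, p = logrank_statistic(outcomes, high)
    labels = np.where(high, "high", "low")
    return labels, curves, stat, p


def silhouette_by_survival(embeddings: EmbeddingMatrix,
                           outcomes: SurvivalOutcome,
                           horizon: float = 5.0) -> float:
    """Mean silhouette of embeddings labelled by survival at ``horizon``.

    Label 1 = died within the horizon; label 0 = followed beyond it.
    Patients censored before the horizon are excluded (status unknown).
    Coincident points use the 0/0 -> 0 convention.
    """
    died = (outcomes.event == 1) & (outcomes.time <= horizon)
    known_alive = outcomes.time > horizon
    keep = died | known_alive
    labels = died[keep].astype(int)
    X = embeddings.values[keep]
    if len(np.unique(labels)) < 2 or min(np.bincount(labels)) < 2:
        raise UndefinedMetricError(
            "need >=2 patients in each survival class within the horizon")
    D = cdist(X, X)
    s = np.empty(len(labels))
    for i in range(len(labels)):
        same = labels == labels[i]
        same[i] = False
        a = D[i, same].mean() if same.any() else 0.0
        b = D[i, ~same & (np.arange(len(labels)) != i)].mean()
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def paired_fold_ttest(scores_a: np.ndarray, scores_b: np.ndarray,
                      ) -> tuple[float, float]:
    """One-sided paired t-test of b > a on per-fold scores."""
    a, b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("need equal-length paired scores, n >= 2")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() > 0:
            return np.inf, 0.0
        if d.mean() < 0:
            return -np.inf, 1.0
        return 0.0, 1.0
    t = d.mean() / (sd / np.sqrt(d.size))
    p = float(stats.t.sf(t, df=d.size - 1))
    return float(t), p


@dataclass
class EvaluationReport:
    """Bundle of the statistics the stack reports for one risk vector."""

    c_index: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    strata_logrank: tuple[float, float] | None = None
    km_curves: dict | None = None
    silhouette: float | None = None
    seeds: dict = field(default_factory=dict)
    n_patients: int = 0

    def to_dict(self) -> dict:
        out = {"c_index": self.c_index, "ci_low": self.ci_low,
               "ci_high": self.ci_high, "n_bootstrap": self.n_bootstrap,
               "n_patients": self.n_patients, "seeds": self.seeds}
        if self.strata_logrank is not None:
            out["logrank_statistic"], out["logrank_p"] = self.strata_logrank
        if self.silhouette is not None:
            out["silhouette"] = self.silhouette
        return out


def evaluate_risks(risks: np.ndarray, outcomes: SurvivalOutcome,
                   n_boot: int = 1000, seed: int = 0,
                   embeddings: EmbeddingMatrix | None = None,
                   horizon: float = 5.0) -> EvaluationReport:
    """Full evaluation of one risk vector: c-index + CI, stratification,
    and (optionally) embedding silhouette by survival status."""
    point, lo, hi = bootstrap_ci(risks, outcomes, n_boot=n_boot, seed=seed)
    try:
        _, curves, stat, p = median_split_logrank(risks, outcomes)
        strata = (stat, p)
    except (UndefinedMetricError, ValidationError):
        curves, strata = None, None
    sil = None
    if embeddings is not None:
        try:
            sil = silhouette_by_survival(embeddings, outcomes, horizon)
        except UndefinedMetricError:
            sil = None
    return EvaluationReport(c_index=point, ci_low=lo, ci_high=hi,
                            n_bootstrap=n_boot, strata_logrank=strata,
                            km_curves=curves, silhouette=sil,
                            seeds={"bootstrap": seed},
                            n_patients=len(outcomes))
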