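# contrasurv

Contrastive multimodal Cox survival modelling for cohorts that combine
histopathology, somatic mutations, and clinical data — the setting of
grade 2/3 (lower-grade) glioma, where prognosis depends jointly on
molecular markers, patient characteristics, and tissue morphology.

## Who this is for

Researchers who have, per patient: a binary patient × gene mutation
matrix (CSV or MAF), a mixed-type clinical table, per-slide tile
embeddings (HDF5; from any tile encoder — a deterministic stub encoder
is included for images), and right-censored survival outcomes — and who
want a leakage-safe, cross-validated estimate of how well the fused
modalities rank survival, plus the standard downstream statistics.

## The model

Every prediction path ends in a scalar risk h(x) trained with the Cox
negative log partial likelihood (Breslow ties):

    L(θ) = −(1/N_event) Σ_{i: event} [ h_θ(x_i) − log Σ_{j: T_j ≥ T_i} e^{h_θ(x_j)} ]

Training has three stages:

1. **Unimodal Cox pretraining** — a hierarchical MLP encoder for the
   non-image features (separate mutation and clinical branches, shared
   layers) and a gated-attention pooler over tile embeddings for the
   image side, each with a linear risk readout.
2. **Contrastive alignment** — both encoders and two projection heads
   minimise `InfoNCE + λ · Cox`: the patient-matched cross-modal
   projection pair is the positive in a softmax over the batch
   (temperature 0.1, λ = 1, symmetric), pulling the two modalities into
   a shared space while preserving survival signal.
3. **Fused risk head** — encoders frozen, a feed-forward head on the
   concatenated *pre-projection* embeddings trained with the Cox loss.

Evaluation: Harrell's c-index with percentile-bootstrap CIs and paired
bootstrap model comparison, median-split Kaplan–Meier curves with the
log-rank test, silhouette scores of the fused embeddings by 5-year
survival status (paired t-test across folds), rank-averaged fold
ensembles, and a zero-shot vs 20 %/10-epoch fine-tune protocol for
external cohorts. Interpretation: lasso selection then OLS with Wald
t-tests on the non-image features (p-values labelled post-selection).

A synthetic multimodal cohort generator with a known proportional-
hazards ground truth (exponential baseline, calibrated independent
censoring, latent image risk classes realised as embedding clusters)
makes the entire pipeline testable without any data download.

## Worked example

```python
from contrasurv import MultimodalCoxModel, TrainingConfig
from contrasurv.simulate import strong_signal_config, generate_cohort

cohort = generate_cohort(strong_signal_config(500, seed=7))
model = MultimodalCoxModel(cohort, training=TrainingConfig(seed=1))
results = model.fit(k=5, seed=2, n_boot=1000)
print(results.summary())
```

```
Contrastive multimodal Cox survival model
=========================================================
patients:   500   events: 168 (33.6%)   folds: 5   stage 2: on
---------------------------------------------------------
modality      c-index             95% CI  fold mean
image           0.681 [  0.636,   0.723]      0.665
nonimage        0.735 [  0.695,   0.773]      0.743
fused           0.788 [  0.751,   0.821]      0.802
---------------------------------------------------------
median-split log-rank: chi2(1) = 115.66, p = 5.64e-27
=========================================================
```

The cohort carries half its hazard signal in the image clusters and half
in the tabular features (its generating predictor ranks survival at
c ≈ 0.84, the information ceiling). Out-of-fold, each single modality
reaches c ≈ 0.67–0.74; fusing their pre-projection embeddings lifts
concordance to 0.79, and the median risk split separates survival
sharply (log-rank p ≈ 10⁻²⁷). Contrastive alignment tightens the joint
representation:

```python
sil = results.silhouette_change()
# silhouette pre -> post: 0.119 -> 0.139 (p = 0.023)
```

i.e. clustering of validation embeddings by 5-year survival status
improves after stage 2. `results.importance()` then attributes the fused
risk to individual features — here it recovers the planted causal genes
with the correct signs (G0001 protective −0.90, G0000 hazardous +0.84, …).

A CLI mirrors the library for shell use:
`contrasurv simulate|embed|preprocess|train|evaluate|adapt|interpret|run`
(see `contrasurv --help`).

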