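# Methods

## The model

`contrasurv` estimates patient-level survival risk for cohorts that carry
three kinds of data per patient: a binary somatic-mutation profile, a
clinical/demographic table, and a set of histopathology tile embeddings
(one vector per 224x224 tissue patch). The model is a proportional-hazards
deep survival network: every prediction path ends in a scalar risk score
h(x) trained with the Cox negative log partial likelihood

    L(h) = -(1/N_event) * sum_{i: event} [ h_i - log sum_{j: T_j >= T_i} exp(h_j) ],

with Breslow handling of tied event times (tied events share one risk
set). Risk scores are therefore identified only up to an additive
constant; all downstream statistics (concordance, median splits,
ensembling) use only their ordering.

Training proceeds in three stages:

1. **Unimodal pretraining.** The non-image encoder (separate MLP branches
   for mutations and clinical features, concatenated into shared layers)
   and the image aggregator (gated attention pooling over tile
   embeddings) are each trained with the Cox loss on a linear risk
   readout of their own embedding.
2. **Contrastive alignment.** Both encoders plus two projection heads are
   trained with `InfoNCE + lambda * Cox`. InfoNCE treats the
   patient-matched (image, non-image) projection pair as the positive in
   a softmax over the batch, symmetrised over both retrieval directions
   (temperature 0.1, lambda 1.0 by default, in-batch negatives only).
   The Cox term reads a throwaway linear head on the concatenated
   pre-projection embeddings; that head is discarded after this stage.
   This is a design choice forced by an open question: a combined
   objective needs *some* risk path before the fusion head exists, and a
   disposable linear readout is the minimal one.
3. **Fusion.** Encoders are frozen; a feed-forward head on the
   concatenated **pre-projection** embeddings (not the unit-normalised
   projections) is trained with the Cox loss.

The tile aggregator is gated attention pooling (Ilse-style multiple-
instance pooling: `score_t = w^T(tanh(V x_t) * sigmoid(U x_t))`, softmax
over tiles, weighted sum of linearly transformed tiles). It is
permutation-invariant in tile order and replaces a transformer slide
aggregator, which is out of scope at desk scale. Likewise, the real
pathology foundation model is replaced by a pluggable embedding
interface: embeddings can come from the deterministic stub encoder
(16x16 downsample -> seeded Gaussian projection -> tanh) or from any
external HDF5 of per-patient tile matrices.

All networks run on a small reverse-mode autodiff engine over numpy
(float64). This keeps the dependency surface to the scientific Python
stack and makes the gradient-check tests (autodiff vs central finite
differences, 1e-4 relative tolerance with an absolute floor for
exactly-zero gradients such as the Cox loss's shift direction) decisive.

## Preprocessing

Mutation columns with zero prevalence are dropped; remaining genes are
screened by single-covariate Cox Wald tests at alpha = 0.05. The
screener is a vectorised Newton-Raphson solver across genes (Breslow
ties); it matches scikit-survival's Breslow Cox coefficients to 1e-6 in
the tests and exists because screening runs inside every CV fold and the
calibration tests sweep thousands of null genes. Clinical columns are
one-hot encoded (categorical; an explicit "missing" level when NAs are
seen at fit time) or mean-imputed and z-scored (continuous, sample SD
with denominator n-1, so `[1,2,3] -> [-1,0,1]`). All statistics live in
a `PreprocessState` fitted exactly once on training patients; transforms
never refit, unseen categories map to all-zero indicators, and genes
missing from an external cohort's panel are zero-filled (the realistic
deployment case where sequencing panels differ).

Screening and preprocessing are fitted **inside each CV training fold**.
A whole-cohort screen before splitting would leak outcome information
into validation folds; in-fold fitting is the leakage-safe reading and
is asserted by instrumentation tests (every id seen during training is
disjoint from that fold's validation ids).

## Evaluation stack

* **Harrell's c-index**: pair (i,j) comparable when `T_i < T_j` and i had
  the event; tied risks count 0.5; equal-time both-event pairs are
  excluded. Verified against brute-force pair enumeration.
* **Bootstrap**: percentile intervals over patient resamples (default
  1000 replicates); paired model comparison applies the same resample to
  both risk vectors and reports a two-sided add-one-corrected p-value.
* **Risk stratification**: split at the median risk (ties go low), KM
  curves per group (via lifelines), two-group log-rank statistic from
  the hypergeometric O-E/V form, chi-square(1) p-value.
* **Representation quality**: mean silhouette of validation-fold fused
  pre-projection embeddings labelled by 5-year survival status. Patients
  censored before 5 years have unknown status and are excluded —
  the only label-faithful choice. Coincident points use the 0/0 -> 0
  convention. Per-fold silhouettes before vs after the contrastive stage
  are compared with a one-sided paired t-test (direction: alignment
  improves clustering).
* **Ensembling**: each fold's final model scores all patients; scores
  are rank-standardised before averaging because Cox risks are
  shift/scale-free and raw averages across models are meaningless.

## Feature importance

Lasso (penalty chosen by 5-fold CV prediction error over a 50-point
log-spaced grid spanning 4 decades below the all-zero penalty) selects
non-image features; OLS on the selected set provides coefficients, 95%
Wald intervals and two-sided t-tests. The default response is the fused
model's out-of-fold risk score, so the table explains the *model*.
These p-values are post-selection and nominal — selecting and testing on
the same data is anti-conservative — and the output is labelled
accordingly.

## Synthetic cohorts

The generator emulates the shape of a lower-grade-glioma registry
cohort: 498 patients, ~24% deaths, age ~ N(43.0, 13.4^2), sex and
three-level histology, 150 binary mutation columns with prevalences
drawn from (0.05, 0.40), and tile-embedding sets. Event times are
exponential proportional hazards (`rate = 0.05 * exp(lp)`, time unit
years); censoring is independent exponential with its rate solved by
root-finding so the *expected* event fraction hits the target — the
realised fraction is then within a couple of points at n >= 500.
Uniform jitter of 1e-9 breaks ties so concordance pairs are
unambiguous.

The image modality carries signal through a discrete latent risk class
(3 classes by default): tiles are unit-variance Gaussians around class
centroids placed `cluster_separation` apart (scaled basis vectors), and
the class effect enters the linear predictor. `image_signal_weight` w
scales the image-class effects by w and all tabular effects by 1-w, and
the recorded `true_coefficients` reproduce `true_linear_predictor`
exactly — the ground truth the recovery tests lean on.

Two named presets define the benchmark conditions used by the tests and
the acceptance script, chosen once:

* **strong-signal** (`strong_signal_config`): n=500, ~35% events, ten
  causal genes at log-hazard +/-2.0, image classes at -2.5/0/+2.5,
  w=0.5. The generating predictor itself ranks survival at c ~ 0.84,
  leaving headroom for a cross-validated model to clear c = 0.75.
* **domain shift**: the same conditions with the first causal gene's
  prevalence forced to 0.23 in the source cohort and 0.02 in the
  external cohort — a high-effect binary marker whose frequency shifts
  drastically between populations, the analogue of an IDH-mutation
  frequency shift between registries.

What the generator does **not** emulate: real histology texture (tiles
are Gaussian blobs, so image signal is easier to pool than in real
slides), correlated mutation co-occurrence, informative censoring,
non-proportional hazards, and site/batch effects. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
its orderings (fused >= unimodal; alignment improves clustering) emerge
when the assumed signal structure is present — not that comparable
c-indices would be reached on real cohorts.

## Numerical and design choices

* Optimiser: Adam, lr 1e-3, batch 32, 30 epochs per stage; batches are
  event-stratified so each has at least one event where arithmetically
  possible (the Cox loss is undefined on event-free batches, which are
  skipped with a warning).
* Regularisation: dropout 0.25 and L2 weight decay 1e-2 by default, with
  early stopping on the validation stage loss (patience 5). Defaults are
  sized for desk-scale cohorts of a few hundred patients, where the
  unregularised networks memorise the training risk order within ~30
  epochs.
* Default widths: mutation branch (128, 64), clinical branch (32, 32),
  shared (64), both embedding dims 64, projection dim 32, fusion
  (64, 32), attention dim 32 — all config-exposed.
* Initialisation: seeded uniform fan-in scaling; every forward pass at
  inference is a pure function of (inputs, parameters). All randomness
  descends from one root seed expanded into named sub-seeds.
* Losses are log-sum-exp stabilised. Zero-vector projection rows are
  replaced by a deterministic unit basis vector (logged). A zero-input
  gene panel (empty selection) degrades gracefully to a clinical-only
  non-image branch.
* Domain adaptation fine-tunes the non-image encoder, tile aggregator
  and fusion head on `round(0.2 n)` event-stratified external patients
  for 10 epochs (tile embeddings themselves are fixed inputs). The
  adapted model is compared with zero-shot scoring on the shared 80%
  complement, which removes split-to-split sampling noise from the
  paired comparison; the zero-shot report on the full cohort is also
  produced.

## Problem sizes in the shipped experiments

The test suite and `scripts/acceptance.py` run the pipeline at the
strong-signal conditions (n=500, 5 folds) with the default 30-epoch
stages and early stopping; multi-seed ordering checks use five seeds
(eight for domain adaptation), bootstrap coverage uses 500 replicates of
n=300 cohorts with 200-resample intervals, and screening calibration
uses 2000 null genes at n=400. These sizes were chosen as the smallest
at which the stochastic checks are statistically meaningful.

## Known limitations

* Stage 2's risk path (the throwaway linear readout) is one of several
  defensible constructions; alternatives (e.g. training the fusion head
  jointly in stage 2) are not implemented.
* The naive post-selection inference in the importance table is reported
  for fidelity with common practice, not because it is statistically
  sound; selective-inference corrections are out of scope.
* The c-index bootstrap treats patients as exchangeable; no stratified
  or cluster bootstrap.
* No Efron tie handling, time-dependent covariates, or competing risks.
* The stub tile encoder preserves coarse intensity structure only; it is
  a stand-in interface, not a model of histology.
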