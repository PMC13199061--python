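"""Three-stage training pipeline, cross-validation, ensembling, and the
external-cohort domain-adaptation protocol.

Stage 1 trains each modality independently with the Cox partial
likelihood on a linear risk readout of that modality's embedding. Stage 2
aligns the two modalities with the combined InfoNCE + lambda * Cox
objective (the Cox term reads a throwaway linear head on the concatenated
pre-projection embeddings, discarded afterwards). Stage 3 freezes the
encoders and trains the fused risk head on concatenated pre-projection
embeddings with the Cox loss again.

Cross-validation uses event-stratified folds fixed once and reused by all
stages; screening and clinical preprocessing are fitted inside each
training fold so validation patients never leak into any fitted
statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import encoders as enc
from . import preprocess as pp
from .autodiff import Parameter, Tensor
from .data import Cohort, EmbeddingMatrix, SurvivalOutcome, ValidationError
from .encoders import EncoderConfig, TrainedModel
from .evaluation import bootstrap_ci, concordance_index
from .objectives import (ConfigurationError, ContrastiveConfig,
                         cox_partial_nll, stage2_combined_loss)

logger = logging.getLogger(__name__)

__all__ = ["FoldSplit", "TrainingConfig", "CVResult", "make_folds",
           "train_stage", "cross_validate", "ensemble_risk",
           "domain_adapt_evaluate", "prepare_cohort", "PreparedData"]

STAGE_ORDER = ("stage1_image", "stage1_nonimage", "stage2_contrastive",
               "stage3_fused")


# --------------------------------------------------------------------------
# folds
# --------------------------------------------------------------------------

@dataclass
class FoldSplit:
    k: int
    assignments: np.ndarray  # fold index per patient
    seed: int
    stratified_on: str = "event"

    def train_val(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        val = np.where(self.assignments == fold)[0]
        train = np.where(self.assignments != fold)[0]
        return train, val


def make_folds(outcomes: SurvivalOutcome, k: int, seed: int) -> FoldSplit:
    """Event-stratified fold assignment: shuffle within each event stratum,
    then deal round-robin, so fold sizes and per-fold event counts differ
    by at most one."""
    n = len(outcomes)
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if k > n:
        raise ConfigurationError("more folds than patients")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=int)
    offset = 0
    for stratum in (1, 0):
        idx = np.where(outcomes.event == stratum)[0]
        rng.shuffle(idx)
        assignments[idx] = (np.arange(idx.size) + offset) % k
        offset += idx.size
    return FoldSplit(k=k, assignments=assignments, seed=seed)


# --------------------------------------------------------------------------
# training configuration and prepared numeric views
# --------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    epochs: dict = field(default_factory=lambda: {
        "stage1_image": 30, "stage1_nonimage": 30,
        "stage2_contrastive": 30, "stage3_fused": 30})
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    contrastive: ContrastiveConfig = field(default_factory=ContrastiveConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    seed: int = 0
    early_stopping_patience: int | None = 5

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ConfigurationError("batch_size must be >= 2")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if any(v < 0 for v in self.epochs.values()):
            raise ConfigurationError("epoch counts must be nonnegative")


@dataclass
class PreparedData:
    """Numeric, id-aligned view of a cohort after fold-local preprocessing."""

    patient_ids: list[str]
    mutation_X: np.ndarray
    clinical_X: np.ndarray
    tile_embeddings: dict[str, np.ndarray]
    outcomes: SurvivalOutcome

    def __len__(self) -> int:
        return len(self.patient_ids)

    def subset(self, idx: np.ndarray) -> "PreparedData":
        ids = [self.patient_ids[i] for i in idx]
        return PreparedData(ids, self.mutation_X[idx], self.clinical_X[idx],
                            {p: self.tile_embeddings[p] for p in ids},
                            self.outcomes.subset(idx))


def prepare_cohort(cohort: Cohort, schema: dict[str, str],
                   state: pp.PreprocessState | None = None,
                   alpha: float = 0.05,
                   ) -> tuple[PreparedData, pp.PreprocessState]:
    """Screen mutations and encode clinical features.

    With ``state`` None everything is fitted on ``cohort`` (training);
    otherwise the fitted state is applied unchanged (validation/external),
    zero-filling genes the cohort lacks.
    """
    if state is None:
        selected, pvals = pp.screen_mutations(cohort.mutation_matrix,
                                              cohort.outcomes, alpha=alpha)
        fm, state = pp.build_feature_matrix(cohort.clinical_table, schema)
        state.selected_genes = selected
        state.screening_pvalues = {g: float(p) for g, p in pvals.items()}
    else:
        fm, _ = pp.build_feature_matrix(cohort.clinical_table, schema,
                                        state=state)
    mut = pp.transform_mutations(cohort.mutation_matrix, state.selected_genes)
    return PreparedData(cohort.patient_ids, mut.to_numpy(float), fm.values,
                        dict(cohort.tile_embeddings), cohort.outcomes), state


# --------------------------------------------------------------------------
# optimizer and batching
# --------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mh = self.m[i] / (1 - b1**self.t)
            vh = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _event_stratified_batches(outcomes: SurvivalOutcome, batch_size: int,
                              rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled batches with events dealt round-robin so every batch has at
    least one event where arithmetically possible."""
    ev = np.where(outcomes.event == 1)[0]
    cs = np.where(outcomes.event == 0)[0]
    rng.shuffle(ev)
    rng.shuffle(cs)
    n_batches = max(1, len(outcomes) // batch_size)
    batches: list[list[int]] = [[] for _ in range(n_batches)]
    for i, idx in enumerate(ev):
        batches[i % n_batches].append(idx)
    for i, idx in enumerate(cs):
        batches[i % n_batches].append(idx)
    out = []
    for b in batches:
        arr = np.array(b)
        rng.shuffle(arr)
        out.append(arr)
    return out


# --------------------------------------------------------------------------
# stage forward passes
# --------------------------------------------------------------------------

def _image_embed_batch(model: TrainedModel, data: PreparedData,
                       idx: np.ndarray) -> Tensor:
    agg = model.components["aggregator"]
    rows = [agg(Tensor(data.tile_embeddings[data.patient_ids[i]])).reshape(1, -1)
            for i in idx]
    from .autodiff import concat
    return concat(rows, axis=0)


def _nonimage_embed_batch(model: TrainedModel, data: PreparedData,
                          idx: np.ndarray,
                          rng: np.random.Generator | None = None) -> Tensor:
    return model.components["nonimage"](Tensor(data.mutation_X[idx]),
                                        Tensor(data.clinical_X[idx]), rng)


def _stage_loss(stage: str, model: TrainedModel, data: PreparedData,
                idx: np.ndarray, config: TrainingConfig,
                rng: np.random.Generator | None) -> Tensor:
    from .autodiff import concat
    sub_out = data.outcomes.subset(idx)
    if stage == "stage1_nonimage":
        emb = _nonimage_embed_batch(model, data, idx, rng)
        risks = model.components["risk_nonimage"](emb)
        return cox_partial_nll(risks, sub_out)
    if stage == "stage1_image":
        emb = _image_embed_batch(model, data, idx)
        risks = model.components["risk_image"](emb)
        return cox_partial_nll(risks, sub_out)
    if stage == "stage2_contrastive":
        img = _image_embed_batch(model, data, idx)
        non = _nonimage_embed_batch(model, data, idx, rng)
        p_img = model.components["proj_image"](img)
        p_non = model.components["proj_nonimage"](non)
        fused = concat([img, non], axis=1)
        risks = model.components["risk_stage2"](fused)
        return stage2_combined_loss(p_img, p_non, risks, sub_out,
                                    config.contrastive)
    if stage == "stage3_fused":
        img = _image_embed_batch(model, data, idx)
        non = _nonimage_embed_batch(model, data, idx)
        fused = concat([img.detach(), non.detach()], axis=1)
        risks = model.components["fusion"](fused, rng)
        return cox_partial_nll(risks, sub_out)
    raise ConfigurationError(f"unknown stage {stage!r}")


_STAGE_PARAMS = {
    "stage1_nonimage": ["nonimage", "risk_nonimage"],
    "stage1_image": ["aggregator", "risk_image"],
    "stage2_contrastive": ["nonimage", "aggregator", "proj_image",
                           "proj_nonimage", "risk_stage2"],
    "stage3_fused": ["fusion"],
}

_STAGE_PRIOR = {
    "stage1_nonimage": (),
    "stage1_image": (),
    "stage2_contrastive": ("stage1_image", "stage1_nonimage"),
    "stage3_fused": ("stage2_contrastive",),
}


def train_stage(stage: str, train_data: PreparedData, config: TrainingConfig,
                prior: TrainedModel | None = None,
                val_data: PreparedData | None = None) -> TrainedModel:
    """Mini-batch gradient training of one pipeline stage.

    ``prior`` carries the parameters from earlier stages; stage 2 requires
    both stage-1 models (one TrainedModel whose provenance has passed
    through both), stage 3 requires the stage-2 model. With zero epochs
    the prior parameters are returned unchanged (provenance advanced).
    """
    if stage not in _STAGE_PARAMS:
        raise ConfigurationError(f"unknown stage {stage!r}")
    required = _STAGE_PRIOR[stage]
    if required and prior is None:
        raise ValidationError(f"{stage} requires a prior model "
                              f"(after {required})")
    if prior is None:
        model = TrainedModel(config=config.encoder,
                             n_mutation=train_data.mutation_X.shape[1],
                             n_clinical=train_data.clinical_X.shape[1],
                             tile_dim=next(iter(
                                 train_data.tile_embeddings.values())).shape[1],
                             seed=config.seed)
    else:
        model = prior.copy()
    history = dict(getattr(prior, "history", {})) if prior is not None else {}
    seen = set(history.get("seen_ids", []))
    seen.update(train_data.patient_ids)
    history["seen_ids"] = sorted(seen)

    params = model.parameters(_STAGE_PARAMS[stage])
    opt = Adam(params, lr=config.learning_rate,
               weight_decay=config.encoder.weight_decay)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, STAGE_ORDER.index(stage)]))
    n_epochs = config.epochs.get(stage, 0)
    losses: list[float] = []
    best_val, best_state, patience_left = np.inf, None, None
    if config.early_stopping_patience and val_data is not None:
        patience_left = config.early_stopping_patience

    for epoch in range(n_epochs):
        epoch_losses = []
        for batch in _event_stratified_batches(train_data.outcomes,
                                               config.batch_size, rng):
            if train_data.outcomes.event[batch].sum() == 0:
                logger.warning("skipping event-free batch in %s", stage)
                continue
            opt.zero_grad()
            loss = _stage_loss(stage, model, train_data, batch, config, rng)
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        # deterministic full-training-set loss at the epoch boundary
        full = _stage_loss(stage, model, train_data,
                           np.arange(len(train_data)), config, None).item()
        losses.append(full)
        logger.info("%s epoch %d loss %.5f (batch mean %.5f)", stage, epoch,
                    full, float(np.mean(epoch_losses)) if epoch_losses
                    else np.nan)
        if patience_left is not None:
            val_idx = np.arange(len(val_data))
            val_loss = _stage_loss(stage, model, val_data, val_idx, config,
                                   None).item()
            if val_loss < best_val - 1e-9:
                best_val, best_state = val_loss, model.copy()
                patience_left = config.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    logger.info("%s early stop at epoch %d", stage, epoch)
                    break
    if best_state is not None:
        model = best_state
    history.setdefault("losses", {})[stage] = losses
    model.history = history
    return model.with_stage(stage)


# --------------------------------------------------------------------------
# inference helpers
# --------------------------------------------------------------------------

def embed_all(model: TrainedModel, data: PreparedData) -> dict[str, EmbeddingMatrix]:
    """Pre-projection embeddings of both modalities, inference mode."""
    img = enc.encode_image(data.tile_embeddings, data.patient_ids, model)
    non = enc.encode_nonimage(data.mutation_X, data.clinical_X, model,
                              data.patient_ids)
    return {"image": img, "nonimage": non}


def score_modalities(model: TrainedModel, data: PreparedData) -> pd.DataFrame:
    """Per-patient risk scores from each path (image, nonimage, fused)."""
    embs = embed_all(model, data)
    risks = {
        "image": model.components["risk_image"](
            Tensor(embs["image"].values)).data,
        "nonimage": model.components["risk_nonimage"](
            Tensor(embs["nonimage"].values)).data,
        "fused": enc.predict_risk_fused(embs["image"], embs["nonimage"], model),
    }
    return pd.DataFrame(risks, index=data.patient_ids)


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

@dataclass
class CVResult:
    folds: FoldSplit
    fold_models: list[TrainedModel]
    fold_states: list[pp.PreprocessState]
    val_risks: pd.DataFrame          # patients x modality, id-indexed
    fold_c_indices: pd.DataFrame     # folds x modality
    fold_embeddings: list[dict]      # per fold: {"pre": ..., "post": ...}
    fold_alignment: pd.DataFrame | None = None  # matched-pair cosine pre/post


def matched_cosine(model: TrainedModel, data: PreparedData) -> float:
    """Mean cosine similarity of patient-matched cross-modal projections."""
    embs = embed_all(model, data)
    p_img = enc.project_contrastive(embs["image"], model, "image").values
    p_non = enc.project_contrastive(embs["nonimage"], model, "nonimage").values
    return float(np.mean(np.sum(p_img * p_non, axis=1)))


def cross_validate(cohort: Cohort, config: TrainingConfig, folds: FoldSplit,
                   schema: dict[str, str], alpha: float = 0.05,
                   use_stage2: bool = True) -> CVResult:
    """Leakage-safe k-fold pipeline run.

    Preprocessing (screening + clinical encoding) is fitted on each fold's
    training patients only; stages 1 -> (2) -> 3 share the fold split.
    ``use_stage2=False`` skips contrastive alignment (the non-contrastive
    fusion ablation).
    """
    if len(folds.assignments) != len(cohort):
        raise ValidationError("fold split does not cover the cohort")
    fold_models, fold_states, fold_embs = [], [], []
    risk_frames, cidx_rows, align_rows = [], [], []
    for fold in range(folds.k):
        train_idx, val_idx = folds.train_val(fold)
        train_cohort = cohort.subset(train_idx)
        val_cohort = cohort.subset(val_idx)
        train_data, state = prepare_cohort(train_cohort, schema, alpha=alpha)
        val_data, _ = prepare_cohort(val_cohort, schema, state=state)

        fold_cfg = TrainingConfig(
            epochs=dict(config.epochs), batch_size=config.batch_size,
            learning_rate=config.learning_rate, optimizer=config.optimizer,
            contrastive=config.contrastive, encoder=config.encoder,
            seed=int(np.random.SeedSequence(
                [config.seed, fold]).generate_state(1)[0] % (2**31)),
            early_stopping_patience=config.early_stopping_patience)

        model = train_stage("stage1_image", train_data, fold_cfg,
                            val_data=val_data)
        model = train_stage("stage1_nonimage", train_data, fold_cfg,
                            prior=model, val_data=val_data)
        pre_embs = embed_all(model, val_data)
        pre_fused = EmbeddingMatrix(
            val_data.patient_ids,
            np.hstack([pre_embs["image"].values, pre_embs["nonimage"].values]))
        cos_pre = matched_cosine(model, val_data)
        if use_stage2:
            model = train_stage("stage2_contrastive", train_data, fold_cfg,
                                prior=model, val_data=val_data)
        model = train_stage("stage3_fused", train_data, fold_cfg, prior=model,
                            val_data=val_data)
        post_embs = embed_all(model, val_data)
        post_fused = EmbeddingMatrix(
            val_data.patient_ids,
            np.hstack([post_embs["image"].values,
                       post_embs["nonimage"].values]))

        scores = score_modalities(model, val_data)
        risk_frames.append(scores)
        row = {}
        for modality in scores.columns:
            try:
                row[modality] = concordance_index(
                    scores[modality].to_numpy(), val_data.outcomes)
            except Exception:
                row[modality] = np.nan
        cidx_rows.append(row)
        fold_models.append(model)
        fold_states.append(state)
        fold_embs.append({"pre": pre_fused, "post": post_fused})
        align_rows.append({"cos_pre": cos_pre,
                           "cos_post": matched_cosine(model, val_data)})
        logger.info("fold %d c-indices: %s", fold, row)
    return CVResult(folds=folds, fold_models=fold_models,
                    fold_states=fold_states,
                    val_risks=pd.concat(risk_frames),
                    fold_c_indices=pd.DataFrame(cidx_rows),
                    fold_embeddings=fold_embs,
                    fold_alignment=pd.DataFrame(align_rows))


def ensemble_risk(cv: CVResult, cohort: Cohort, schema: dict[str, str],
                  modality: str = "fused") -> pd.Series:
    """Average of rank-standardised per-fold-model scores for all patients.

    Cox risks are shift/scale-free, so raw score averaging across models
    is meaningless; ranks preserve each model's ordering.
    """
    if not cv.fold_models:
        raise ValidationError("empty CVResult")
    ranked = []
    for model, state in zip(cv.fold_models, cv.fold_states):
        data, _ = prepare_cohort(cohort, schema, state=state)
        scores = score_modalities(model, data)[modality].to_numpy()
        ranked.append(rankdata(scores) / (len(scores) + 1.0))
    return pd.Series(np.mean(ranked, axis=0), index=cohort.patient_ids,
                     name=f"ensemble_{modality}")


def train_full(cohort: Cohort, config: TrainingConfig, schema: dict[str, str],
               alpha: float = 0.05, use_stage2: bool = True,
               ) -> tuple[TrainedModel, pp.PreprocessState]:
    """Train all stages on one cohort (no held-out split); returns the
    stage-3 model and the fitted preprocessing state."""
    data, state = prepare_cohort(cohort, schema, alpha=alpha)
    model = train_stage("stage1_image", data, config)
    model = train_stage("stage1_nonimage", data, config, prior=model)
    if use_stage2:
        model = train_stage("stage2_contrastive", data, config, prior=model)
    model = train_stage("stage3_fused", data, config, prior=model)
    return model, state


# --------------------------------------------------------------------------
# domain adaptation
# --------------------------------------------------------------------------

def domain_adapt_evaluate(model: TrainedModel, state: pp.PreprocessState,
                          external_cohort: Cohort, schema: dict[str, str],
                          fraction: float = 0.2, epochs: int = 10,
                          seed: int = 0, n_boot: int = 1000,
                          learning_rate: float = 1e-3, batch_size: int = 16,
                          ) -> tuple[dict, dict]:
    """Zero-shot vs small-fraction fine-tuned evaluation on an external cohort.

    The external cohort is preprocessed with the TRAINING cohort's fitted
    state (absent genes zero-filled). Zero-shot: frozen parameters on the
    full cohort. Adapted: fine-tune the prediction path (non-image
    encoder, tile aggregator, fusion head) on an event-stratified
    ``round(fraction * n)`` subset for ``epochs`` epochs, then evaluate on
    the complement. Returns (zero_shot_report, adapted_report) dicts.
    """
    if not 0 < fraction < 1:
        raise ConfigurationError("fraction must be in (0,1)")
    data, _ = prepare_cohort(external_cohort, schema, state=state)
    n = len(data)

    def report(m: TrainedModel, idx: np.ndarray, tag: str) -> dict:
        sub = data.subset(idx)
        risks = score_modalities(m, sub)["fused"].to_numpy()
        point, lo, hi = bootstrap_ci(risks, sub.outcomes, n_boot=n_boot,
                                     seed=seed)
        return {"tag": tag, "c_index": point, "ci_low": lo, "ci_high": hi,
                "n": int(len(sub)), "risks": pd.Series(risks,
                                                       index=sub.patient_ids)}

    zero_shot = report(model, np.arange(n), "zero_shot")

    # event-stratified adaptation split
    rng = np.random.default_rng(seed)
    n_adapt = int(round(fraction * n))
    ev = np.where(data.outcomes.event == 1)[0]
    cs = np.where(data.outcomes.event == 0)[0]
    rng.shuffle(ev)
    rng.shuffle(cs)
    n_ev = int(round(n_adapt * len(ev) / n))
    n_ev = min(max(n_ev, 1 if len(ev) else 0), len(ev))
    adapt_idx = np.concatenate([ev[:n_ev], cs[:n_adapt - n_ev]])
    eval_idx = np.setdiff1d(np.arange(n), adapt_idx)
    if data.outcomes.event[adapt_idx].sum() == 0:
        raise ValidationError("adaptation split has zero events; "
                              "use another seed or fraction")

    adapted_model = model.copy()
    if epochs > 0:
        adapt_data = data.subset(adapt_idx)
        params = adapted_model.parameters(["nonimage", "aggregator", "fusion"])
        opt = Adam(params, lr=learning_rate,
                   weight_decay=model.config.weight_decay)
        train_rng = np.random.default_rng(seed + 1)
        from .autodiff import concat
        for _ in range(epochs):
            for batch in _event_stratified_batches(adapt_data.outcomes,
                                                   min(batch_size,
                                                       len(adapt_data)),
                                                   train_rng):
                if adapt_data.outcomes.event[batch].sum() == 0:
                    continue
                opt.zero_grad()
                img = _image_embed_batch(adapted_model, adapt_data, batch)
                non = _nonimage_embed_batch(adapted_model, adapt_data, batch)
                fused = concat([img, non], axis=1)
                risks = adapted_model.components["fusion"](fused)
                loss = cox_partial_nll(risks, adapt_data.outcomes.subset(batch))
                loss.backward()
                opt.step()
    adapted = report(adapted_model, eval_idx, "adapted")
    adapted["n_adapt"] = int(len(adapt_idx))
    # zero-shot restricted to the same evaluation subset: the paired
    # comparison free of split-to-split sampling noise
    eval_sub = data.subset(eval_idx)
    adapted["zero_shot_on_eval_c_index"] = concordance_index(
        score_modalities(model, eval_sub)["fused"].to_numpy(),
        eval_sub.outcomes)
    return zero_shot, adapted
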