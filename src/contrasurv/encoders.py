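"""Model family: hierarchical non-image encoder, gated attention tile
aggregator, contrastive projection heads, and the fused risk head.

All networks are small fully connected stacks with rectified-linear
activations, built on the package's autodiff engine. The tile aggregator
is gated attention pooling (two score branches, multiplicative gate,
softmax over tiles): a permutation-invariant multiple-instance pooler
standing in for a transformer slide aggregator. Contrastive projection
heads end in row-wise unit normalisation; the fused risk head consumes
the concatenated PRE-projection embeddings of both modalities and emits
one scalar risk per patient (higher = worse).

Parameters are initialised with seeded uniform fan-in scaling so every
forward pass is reproducible; dropout is active only when a training
RNG is supplied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .data import EmbeddingMatrix, ValidationError
from .objectives import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = ["EncoderConfig", "TrainedModel", "encode_nonimage",
           "aggregate_tiles", "encode_image", "project_contrastive",
           "predict_risk_fused"]

STAGES = ("init", "stage1_image", "stage1_nonimage", "stage2_contrastive",
          "stage3_fused")


@dataclass
class EncoderConfig:
    mutation_hidden_sizes: tuple[int, ...] = (128, 64)
    clinical_hidden_sizes: tuple[int, ...] = (32, 32)
    shared_hidden_sizes: tuple[int, ...] = (64,)
    aggregator_attention_dim: int = 32
    image_embed_dim: int = 64
    nonimage_embed_dim: int = 64
    projection_dim: int = 32
    fusion_hidden_sizes: tuple[int, ...] = (64, 32)
    dropout_rate: float = 0.25
    weight_decay: float = 1e-2
    activation: str = "relu"

    def __post_init__(self) -> None:
        sizes = (*self.mutation_hidden_sizes, *self.clinical_hidden_sizes,
                 *self.shared_hidden_sizes, *self.fusion_hidden_sizes,
                 self.aggregator_attention_dim, self.image_embed_dim,
                 self.nonimage_embed_dim, self.projection_dim)
        if any(s < 1 for s in sizes):
            raise ConfigurationError("all layer sizes must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must be in [0,1)")
        if self.weight_decay < 0:
            raise ConfigurationError("weight_decay must be nonnegative")


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------

class Linear:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(max(in_dim, 1))  # in_dim 0 = empty gene panel
        self.W = Parameter(rng.uniform(-bound, bound, size=(in_dim, out_dim)))
        self.b = Parameter(rng.uniform(-bound, bound, size=out_dim))
        self.in_dim, self.out_dim = in_dim, out_dim

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


def _dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or rate <= 0:
        return x
    mask = (rng.uniform(size=x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


class MLP:
    """Stack of Linear+ReLU(+dropout) layers; ReLU omitted after the last
    layer when ``final_activation`` is False."""

    def __init__(self, in_dim: int, sizes: tuple[int, ...],
                 rng: np.random.Generator, dropout: float = 0.0,
                 final_activation: bool = True):
        self.layers: list[Linear] = []
        self.dropout = dropout
        self.final_activation = final_activation
        prev = in_dim
        for s in sizes:
            self.layers.append(Linear(prev, s, rng))
            prev = s
        self.out_dim = prev

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None
                 ) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            last = i == len(self.layers) - 1
            if not last or self.final_activation:
                x = ad.relu(x)
                x = _dropout(x, self.dropout, rng)
        return x

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]


class NonImageEncoder:
    """Separate mutation and clinical branches, then shared layers."""

    def __init__(self, n_mutation: int, n_clinical: int, cfg: EncoderConfig,
                 rng: np.random.Generator):
        self.mutation = MLP(n_mutation, cfg.mutation_hidden_sizes, rng,
                            cfg.dropout_rate)
        self.clinical = MLP(n_clinical, cfg.clinical_hidden_sizes, rng,
                            cfg.dropout_rate)
        self.shared = MLP(self.mutation.out_dim + self.clinical.out_dim,
                          (*cfg.shared_hidden_sizes, cfg.nonimage_embed_dim),
                          rng, cfg.dropout_rate, final_activation=False)
        self.n_mutation, self.n_clinical = n_mutation, n_clinical

    def __call__(self, mut: Tensor, clin: Tensor,
                 rng: np.random.Generator | None = None) -> Tensor:
        if mut.shape[1] != self.n_mutation:
            raise ValidationError(
                f"mutation branch expects {self.n_mutation} features, "
                f"got {mut.shape[1]}")
        if clin.shape[1] != self.n_clinical:
            raise ValidationError(
                f"clinical branch expects {self.n_clinical} features, "
                f"got {clin.shape[1]}")
        hm = self.mutation(mut, rng)
        hc = self.clinical(clin, rng)
        return self.shared(ad.concat([hm, hc], axis=1), rng)

    def parameters(self) -> list[Parameter]:
        return (self.mutation.parameters() + self.clinical.parameters()
                + self.shared.parameters())


class GatedAttentionAggregator:
    """Permutation-invariant pooling of a variable-size tile set.

    score_t = w^T (tanh(V x_t) * sigmoid(U x_t)); weights = softmax over
    tiles; output = sum_t weight_t * (H x_t).
    """

    def __init__(self, tile_dim: int, cfg: EncoderConfig,
                 rng: np.random.Generator):
        a = cfg.aggregator_attention_dim
        self.V = Linear(tile_dim, a, rng)
        self.U = Linear(tile_dim, a, rng)
        self.w = Linear(a, 1, rng)
        self.H = Linear(tile_dim, cfg.image_embed_dim, rng)
        self.tile_dim = tile_dim

    def attention_weights(self, tiles: Tensor) -> Tensor:
        scores = self.w(ad.tanh(self.V(tiles)) * ad.sigmoid(self.U(tiles)))
        s = scores.reshape(scores.shape[0])
        shift = float(s.data.max())
        e = ad.exp(s - shift)
        return e / e.sum()

    def __call__(self, tiles: Tensor) -> Tensor:
        if tiles.ndim != 2 or tiles.shape[0] < 1:
            raise ValidationError("tile set must be a nonempty tiles x dim matrix")
        if tiles.shape[1] != self.tile_dim:
            raise ValidationError(
                f"aggregator expects tile dim {self.tile_dim}, "
                f"got {tiles.shape[1]}")
        weights = self.attention_weights(tiles)
        return weights @ self.H(tiles)  # (image_embed_dim,)

    def parameters(self) -> list[Parameter]:
        return (self.V.parameters() + self.U.parameters()
                + self.w.parameters() + self.H.parameters())


class ProjectionHead:
    def __init__(self, in_dim: int, cfg: EncoderConfig,
                 rng: np.random.Generator):
        self.mlp = MLP(in_dim, (2 * cfg.projection_dim, cfg.projection_dim),
                       rng, dropout=0.0, final_activation=False)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.mlp(x)
        norms_sq = (h * h).sum(axis=1, keepdims=True)
        zero_rows = np.where(norms_sq.data[:, 0] <= 1e-24)[0]
        if zero_rows.size:
            logger.warning("zero projection rows replaced by unit basis: %s",
                           zero_rows[:5].tolist())
            basis = np.zeros_like(h.data)
            basis[zero_rows, 0] = 1.0
            h = h + Tensor(basis)
            norms_sq = (h * h).sum(axis=1, keepdims=True)
        return h / (norms_sq ** 0.5)

    def parameters(self) -> list[Parameter]:
        return self.mlp.parameters()


class LinearRisk:
    """Scalar readout used for stage-1 and the throwaway stage-2 Cox path."""

    def __init__(self, in_dim: int, rng: np.random.Generator):
        self.lin = Linear(in_dim, 1, rng)

    def __call__(self, x: Tensor, rng=None) -> Tensor:
        return self.lin(x).reshape(x.shape[0])

    def parameters(self) -> list[Parameter]:
        return self.lin.parameters()


class FusionHead:
    def __init__(self, in_dim: int, cfg: EncoderConfig,
                 rng: np.random.Generator):
        self.mlp = MLP(in_dim, (*cfg.fusion_hidden_sizes, 1), rng,
                       cfg.dropout_rate, final_activation=False)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None
                 ) -> Tensor:
        return self.mlp(x, rng).reshape(x.shape[0])

    def parameters(self) -> list[Parameter]:
        return self.mlp.parameters()


# --------------------------------------------------------------------------
# full model container
# --------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """Parameter state for all sub-networks plus training provenance."""

    config: EncoderConfig
    n_mutation: int
    n_clinical: int
    tile_dim: int
    seed: int = 0
    stage_provenance: str = "init"
    components: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage_provenance not in STAGES:
            raise ValidationError(f"unknown stage {self.stage_provenance!r}")
        if not self.components:
            rng = np.random.default_rng(self.seed)
            cfg = self.config
            self.components = {
                "nonimage": NonImageEncoder(self.n_mutation, self.n_clinical,
                                            cfg, rng),
                "aggregator": GatedAttentionAggregator(self.tile_dim, cfg, rng),
                "proj_image": ProjectionHead(cfg.image_embed_dim, cfg, rng),
                "proj_nonimage": ProjectionHead(cfg.nonimage_embed_dim, cfg,
                                                rng),
                "risk_image": LinearRisk(cfg.image_embed_dim, rng),
                "risk_nonimage": LinearRisk(cfg.nonimage_embed_dim, rng),
                "risk_stage2": LinearRisk(
                    cfg.image_embed_dim + cfg.nonimage_embed_dim, rng),
                "fusion": FusionHead(
                    cfg.image_embed_dim + cfg.nonimage_embed_dim, cfg, rng),
            }

    def parameters(self, names: list[str] | None = None) -> list[Parameter]:
        names = names or list(self.components)
        return [p for n in names for p in self.components[n].parameters()]

    def with_stage(self, stage: str) -> "TrainedModel":
        self.stage_provenance = stage
        return self

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """One binary checkpoint (.npz) plus a JSON sidecar."""
        path = Path(path)
        arrays = {}
        for cname, comp in self.components.items():
            for i, p in enumerate(comp.parameters()):
                arrays[f"{cname}.{i}"] = p.data
        np.savez(path, **arrays)
        sidecar = {"config": asdict(self.config), "seed": self.seed,
                   "stage_provenance": self.stage_provenance,
                   "n_mutation": self.n_mutation,
                   "n_clinical": self.n_clinical, "tile_dim": self.tile_dim}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        cfg_dict = sidecar["config"]
        for k, v in cfg_dict.items():
            if isinstance(v, list):
                cfg_dict[k] = tuple(v)
        model = cls(config=EncoderConfig(**cfg_dict),
                    n_mutation=sidecar["n_mutation"],
                    n_clinical=sidecar["n_clinical"],
                    tile_dim=sidecar["tile_dim"], seed=sidecar["seed"],
                    stage_provenance=sidecar["stage_provenance"])
        with np.load(path if path.suffix == ".npz" else str(path)) as data:
            for cname, comp in model.components.items():
                for i, p in enumerate(comp.parameters()):
                    p.data = np.array(data[f"{cname}.{i}"])
        return model

    def copy(self) -> "TrainedModel":
        clone = TrainedModel(config=self.config, n_mutation=self.n_mutation,
                             n_clinical=self.n_clinical, tile_dim=self.tile_dim,
                             seed=self.seed,
                             stage_provenance=self.stage_provenance)
        for cname in self.components:
            for p_new, p_old in zip(clone.components[cname].parameters(),
                                    self.components[cname].parameters()):
                p_new.data = p_old.data.copy()
        return clone


# --------------------------------------------------------------------------
# functional interface
# --------------------------------------------------------------------------

def encode_nonimage(mutation_features: np.ndarray, clinical_features: np.ndarray,
                    model: TrainedModel,
                    patient_ids: list[str] | None = None) -> EmbeddingMatrix:
    """Deterministic inference pass of the non-image encoder."""
    out = model.components["nonimage"](Tensor(mutation_features),
                                       Tensor(clinical_features))
    ids = patient_ids or [str(i) for i in range(out.shape[0])]
    return EmbeddingMatrix(ids, out.data)


def aggregate_tiles(tile_embeddings: np.ndarray,
                    model: TrainedModel) -> np.ndarray:
    """Pool one patient's tiles x dim matrix to a slide-level embedding."""
    return model.components["aggregator"](Tensor(tile_embeddings)).data


def encode_image(tile_embeddings: dict[str, np.ndarray],
                 patient_ids: list[str],
                 model: TrainedModel) -> EmbeddingMatrix:
    rows = [aggregate_tiles(tile_embeddings[p], model) for p in patient_ids]
    return EmbeddingMatrix(list(patient_ids), np.vstack(rows))


def project_contrastive(embedding: EmbeddingMatrix, model: TrainedModel,
                        which: str) -> EmbeddingMatrix:
    """Apply a modality projection head; rows come back unit-norm."""
    if which not in ("image", "nonimage"):
        raise ValidationError("which must be 'image' or 'nonimage'")
    head = model.components[f"proj_{which}"]
    out = head(Tensor(embedding.values))
    return EmbeddingMatrix(embedding.patient_ids, out.data)


def predict_risk_fused(image_embeddings: EmbeddingMatrix,
                       nonimage_embeddings: EmbeddingMatrix,
                       model: TrainedModel) -> np.ndarray:
    """Scalar fused risk from concatenated pre-projection embeddings."""
    if image_embeddings.patient_ids != nonimage_embeddings.patient_ids:
        raise ValidationError("modality embeddings have misaligned patient ids")
    fused = np.hstack([image_embeddings.values, nonimage_embeddings.values])
    return model.components["fusion"](Tensor(fused)).data
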