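"""Training objectives: Cox partial likelihood, cross-modal InfoNCE, and
their weighted combination.

The Cox loss is the negative log partial likelihood averaged over observed
events,

    L(h) = -(1/N_event) * sum_{i: event_i=1} [ h_i - log sum_{j in R(T_i)} exp(h_j) ],

with the risk set R(T_i) = {j : T_j >= T_i} (Breslow handling: tied event
times share one risk set). InfoNCE treats each patient's matched
cross-modal projection pair as the positive class in a softmax over the
batch; the combined stage-2 objective is InfoNCE + lambda * Cox.

All losses accept either plain numpy arrays (returning a float) or
:class:`~contrasurv.autodiff.Tensor` inputs (returning a Tensor on the
tape, so gradients flow to encoder parameters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data import SurvivalOutcome, ValidationError

__all__ = ["ContrastiveConfig", "cox_partial_nll", "info_nce_loss",
           "stage2_combined_loss"]


class ConfigurationError(ValueError):
    pass


@dataclass
class ContrastiveConfig:
    """Stage-2 objective settings.

    temperature : softmax temperature of the InfoNCE similarity logits.
    lambda_weight : weight of the Cox term in the combined loss.
    symmetric : average the image->non-image and non-image->image directions.
    """

    temperature: float = 0.1
    lambda_weight: float = 1.0
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be positive")
        if self.lambda_weight < 0:
            raise ConfigurationError("lambda_weight must be nonnegative")


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=float)), False


def cox_partial_nll(risks, outcomes: SurvivalOutcome):
    """Breslow negative log partial likelihood, averaged over events.

    Stabilised with log-sum-exp; differentiable with respect to ``risks``
    when given a Tensor. Raises if no event is observed (the average is
    undefined) or if any risk is non-finite.
    """
    h, was_tensor = _as_tensor(risks)
    if h.ndim != 1 or h.shape[0] != len(outcomes):
        raise ValidationError("risks must be a vector aligned with outcomes")
    if np.any(~np.isfinite(h.data)):
        raise ValidationError("non-finite risk score")
    event_idx = np.where(outcomes.event == 1)[0]
    if event_idx.size == 0:
        raise ValidationError("Cox partial likelihood undefined with zero events")

    # risk-set membership: row per event patient i, column j in R(T_i)
    t = outcomes.time
    member = (t[None, :] >= t[event_idx, None]).astype(float)

    shift = float(h.data.max())
    exp_h = ad.exp(h - shift)
    log_risk_sets = ad.log(Tensor(member) @ exp_h) + shift  # (n_event,)
    terms = h[event_idx] - log_risk_sets
    loss = -terms.mean()
    return loss if was_tensor else float(loss.data)


def info_nce_loss(proj_image, proj_nonimage, config: ContrastiveConfig):
    """Cross-modal InfoNCE over in-batch negatives.

    Rows must be unit-norm projections; non-unit rows are renormalised with
    a warning. With ``symmetric`` the two retrieval directions are averaged.
    """
    a, tensor_a = _as_tensor(proj_image)
    b, tensor_b = _as_tensor(proj_nonimage)
    was_tensor = tensor_a or tensor_b
    if a.ndim != 2 or b.ndim != 2 or a.shape != b.shape:
        raise ValidationError("projections must be equal-shape batch x dim matrices")
    n = a.shape[0]
    if n == 0:
        raise ValidationError("empty batch")

    for name, m in (("image", a), ("nonimage", b)):
        norms = np.linalg.norm(m.data, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            warnings.warn(f"{name} projections not unit-norm; renormalising")
            m.data = m.data / np.maximum(norms, 1e-12)[:, None]

    sims = (a @ b.T) * (1.0 / config.temperature)  # (n, n)
    diag = np.arange(n)

    def row_ce(s: Tensor) -> Tensor:
        shift = s.data.max(axis=1, keepdims=True)
        lse = ad.log(ad.exp(s - shift).sum(axis=1)) + Tensor(shift[:, 0])
        return (lse - s[diag, diag]).mean()

    loss = row_ce(sims)
    if config.symmetric:
        loss = (loss + row_ce(sims.T)) * 0.5
    return loss if was_tensor else float(loss.data)


def stage2_combined_loss(proj_image, proj_nonimage, risks,
                         outcomes: SurvivalOutcome,
                         config: ContrastiveConfig):
    """InfoNCE + lambda * Cox negative log partial likelihood."""
    if config.lambda_weight < 0:
        raise ConfigurationError("lambda_weight must be nonnegative")
    nce = info_nce_loss(proj_image, proj_nonimage, config)
    cox = cox_partial_nll(risks, outcomes)
    if isinstance(nce, Tensor) or isinstance(cox, Tensor):
        nce = nce if isinstance(nce, Tensor) else Tensor(nce)
        cox = cox if isinstance(cox, Tensor) else Tensor(cox)
        return nce + cox * config.lambda_weight
    return nce + config.lambda_weight * cox
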