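"""Composite objective and the seeded full-batch training loop.

The objective combines the binary cross-entropy of predicted pair scores
against known labels with KL divergences pulling both variational posteriors
toward the standard normal prior:

    L = L_pred + beta_vae * KL(q(Z|X) || N(0,I)) + beta_gvae * KL(q(Z~|G~) || N(0,I))

Each KL term is summed over latent dimensions and averaged over nodes so the
beta weights are dataset-size independent. ``kl_sign="subtract"`` flips the
KL contribution for comparison with the unregularized reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor
from .io import MDAGraph
from .model import (
    LatentGaussian,
    ModelState,
    forward_t,
    gcn_propagation_matrix,
    init_state,
    neighbor_mean_matrix,
    _score_logits_t,
)

__all__ = [
    "LossBreakdown",
    "TrainConfig",
    "TrainingDivergedError",
    "kl_gaussian",
    "bce_loss",
    "total_loss",
    "train",
]

logger = logging.getLogger(__name__)

_CLAMP = 1e-12


@dataclass
class LossBreakdown:
    """One evaluation of the composite objective, component by component."""

    pred_loss: float
    kl_vae: float
    kl_gvae: float
    total: float
    beta_vae: float
    beta_gvae: float


@dataclass
class TrainConfig:
    """Hyperparameters of the full-batch training loop.

    Defaults: Adam at learning rate 1e-2 for 300 epochs with KL weights of
    1e-3 and latent sampling on. ``seed`` fixes every source of randomness
    (initialization and the per-epoch reparameterization draws).
    """

    epochs: int = 300
    lr: float = 1e-2
    optimizer: str = "adam"
    beta_vae: float = 1e-3
    beta_gvae: float = 1e-3
    kl_sign: str = "penalize"
    sample_latent: bool = True
    seed: int = 0
    patience: int | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.kl_sign not in ("penalize", "subtract"):
            raise ValueError("kl_sign must be 'penalize' or 'subtract'")


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite, with the offending epoch."""

    def __init__(self, epoch: int, breakdown: LossBreakdown):
        super().__init__(
            f"non-finite loss at epoch {epoch}: pred={breakdown.pred_loss}, "
            f"kl_vae={breakdown.kl_vae}, kl_gvae={breakdown.kl_gvae}"
        )
        self.epoch = epoch
        self.breakdown = breakdown


# ---------------------------------------------------------------------------
# losses (public numeric forms)
# ---------------------------------------------------------------------------

def kl_gaussian(q: LatentGaussian | tuple) -> float:
    """KL(q || N(0, I)) summed over latent dimensions, averaged over nodes.

    Per node: ``0.5 * sum_i (var_i + mean_i^2 - log var_i - 1)``.
    """
    if isinstance(q, LatentGaussian):
        mean, var = q.mean, q.var
    else:
        mean, var = (np.asarray(x, dtype=float) for x in q)
    if not (var > 0).all():
        raise ValueError("variance must be strictly positive")
    mean = np.atleast_2d(mean)
    var = np.atleast_2d(var)
    per_node = 0.5 * (var + mean**2 - np.log(var) - 1.0).sum(axis=1)
    return float(per_node.mean())


def bce_loss(scores, labels) -> float:
    """Mean binary cross-entropy of scores in (0, 1) against 0/1 labels.

    Scores outside the open interval are clamped ``1e-12`` from the boundary
    (and the clamping logged) so the loss stays finite.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0 or 1")
    if ((s <= 0) | (s >= 1)).any():
        logger.warning("bce_loss: %d score(s) clamped to the open interval (0, 1)",
                       int(((s <= 0) | (s >= 1)).sum()))
    s = np.clip(s, _CLAMP, 1.0 - _CLAMP)
    return float(np.mean(-(y * np.log(s) + (1.0 - y) * np.log(1.0 - s))))


def total_loss(
    pred: float,
    kl_vae: float,
    kl_gvae: float,
    beta_vae: float = 1e-3,
    beta_gvae: float = 1e-3,
    kl_sign: str = "penalize",
) -> LossBreakdown:
    """Combine the components; the default penalized form adds the KL terms."""
    sign = 1.0 if kl_sign == "penalize" else -1.0
    total = pred + sign * (beta_vae * kl_vae + beta_gvae * kl_gvae)
    return LossBreakdown(pred, kl_vae, kl_gvae, total, beta_vae, beta_gvae)


# ---------------------------------------------------------------------------
# tensor-space pieces
# ---------------------------------------------------------------------------

def _kl_t(mean: Tensor, logvar: Tensor) -> Tensor:
    return ((logvar.exp() + mean * mean - logvar - 1.0).sum(axis=1) * 0.5).mean()


def _bce_from_logits_t(logits: Tensor, y: np.ndarray) -> Tensor:
    # softplus(x) - y*x == -[y log s + (1-y) log(1-s)] for s = sigmoid(x)
    return (logits.softplus() - logits * Tensor(y)).mean()


def loss_fn(
    state: ModelState,
    X: Tensor,
    nmean: np.ndarray | None,
    ahat: np.ndarray | None,
    pair_nodes: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    eps_vae: np.ndarray | None = None,
    eps_gvae: np.ndarray | None = None,
) -> tuple[Tensor, LossBreakdown]:
    """One full forward evaluation of the composite objective."""
    out = forward_t(state, X, nmean, ahat, eps_vae=eps_vae, eps_gvae=eps_gvae)
    logits = _score_logits_t(state, out["fused"], pair_nodes)
    pred = _bce_from_logits_t(logits, y)
    zero = Tensor(0.0)
    kl_vae = _kl_t(*out["vae"]) if "vae" in out else zero
    kl_gvae = _kl_t(*out["gvae"]) if "gvae" in out else zero
    sign = 1.0 if cfg.kl_sign == "penalize" else -1.0
    total = pred + (kl_vae * (sign * cfg.beta_vae)) + (kl_gvae * (sign * cfg.beta_gvae))
    breakdown = total_loss(
        float(pred.data),
        float(kl_vae.data),
        float(kl_gvae.data),
        cfg.beta_vae,
        cfg.beta_gvae,
        cfg.kl_sign,
    )
    return total, breakdown


def _pair_nodes(pairs, m: int, node_count: int) -> np.ndarray:
    nodes = np.asarray(pairs, dtype=np.intp).reshape(-1, 2).copy()
    # accept (microbe index, disease index) matrix coordinates
    nodes[:, 1] += m
    if ((nodes[:, 0] < 0) | (nodes[:, 0] >= m)).any() or (
        (nodes[:, 1] < m) | (nodes[:, 1] >= node_count)
    ).any():
        raise IndexError("training pair index out of range")
    return nodes


def train(
    G_train: MDAGraph,
    pairs,
    labels,
    cfg: TrainConfig | None = None,
    *,
    variant: str = "full",
    hidden_dim: int = 64,
    latent_dim: int = 64,
    predictor_hidden: int = 64,
    sage_layers: int = 2,
    tied_sage: bool = False,
    init: ModelState | None = None,
) -> tuple[ModelState, list[LossBreakdown]]:
    """Full-batch gradient training of all parameters.

    Deterministic for a fixed config and seed: initialization and the
    per-epoch latent draws come from generators spawned off ``cfg.seed``.
    Returns the trained state and the per-epoch loss history.
    """
    cfg = cfg or TrainConfig()
    y = np.asarray(labels, dtype=float).reshape(-1, 1)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0 or 1")
    pair_nodes = _pair_nodes(pairs, G_train.m, G_train.node_count)
    if pair_nodes.shape[0] != y.shape[0]:
        raise ValueError("pairs and labels must have equal length")
    if pair_nodes.shape[0] == 0:
        raise ValueError("at least one training pair is required")

    init_seq, sample_seq = np.random.SeedSequence(cfg.seed).spawn(2)
    state = init or init_state(
        d_in=G_train.features.shape[1],
        variant=variant,
        hidden_dim=hidden_dim,
        latent_dim=latent_dim,
        predictor_hidden=predictor_hidden,
        sage_layers=sage_layers,
        tied_sage=tied_sage,
        seed=init_seq.generate_state(1)[0] % (2**31),
    )
    sample_rng = np.random.default_rng(sample_seq)

    use_sage = state.config["variant"] in ("full", "sage_only")
    use_vae = state.config["variant"] in ("full", "dva_only")
    use_gvae = state.config["variant"] in ("full", "dva_only", "gva_only")
    nmean = neighbor_mean_matrix(G_train) if use_sage else None
    ahat = gcn_propagation_matrix(G_train) if use_gvae else None
    X = Tensor(G_train.features)
    latent_shape = (G_train.node_count, state.config["latent_dim"])

    if cfg.optimizer.lower() != "adam":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    opt = Adam(dict.fromkeys(state.parameters()), lr=cfg.lr)  # dedupe tied tensors

    history: list[LossBreakdown] = []
    best = np.inf
    stale = 0
    for epoch in range(cfg.epochs):
        eps_vae = eps_gvae = None
        if cfg.sample_latent:
            if use_vae:
                eps_vae = sample_rng.standard_normal(latent_shape)
            if use_gvae:
                eps_gvae = sample_rng.standard_normal(latent_shape)
        opt.zero_grad()
        total, breakdown = loss_fn(
            state, X, nmean, ahat, pair_nodes, y, cfg, eps_vae, eps_gvae
        )
        if not np.isfinite(breakdown.total):
            raise TrainingDivergedError(epoch, breakdown)
        total.backward()
        opt.step()
        history.append(breakdown)
        if cfg.patience is not None:
            if breakdown.total < best - 1e-12:
                best, stale = breakdown.total, 0
            else:
                stale += 1
                if stale > cfg.patience:
                    break
    return state, history
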