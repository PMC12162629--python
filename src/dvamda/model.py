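"""The DVAMDA forward model and its scikit-learn style estimator.

Architecture, applied to the bipartite association graph G = <V, E, X>:

1. A GraphSAGE encoder with mean neighborhood aggregation produces mid-level
   node embeddings ``X~`` (per layer: ``h_v = sigma(W_agg . mean_{u in N(v)}
   h_u + W_self . h_v + b)``; ReLU on hidden layers, identity on the last).
2. A feature-space VAE encodes the raw node features X into a diagonal
   Gaussian posterior (single linear layer for the mean; linear layer +
   normalization layer, exponentiated, for the variance).
3. A graph VAE (GVAE) encodes ``X~`` with a single symmetric-normalized
   graph-convolution layer per path (``D^{-1/2}(A+I)D^{-1/2}`` propagation).
4. The latent samples Z (VAE), Z~ (GVAE) and X~ are concatenated column-wise
   into fused node features ``X^``.
5. A pair scorer takes the Hadamard product of a microbe row and a disease
   row of ``X^`` and maps it through a small MLP with a terminal sigmoid to
   an association score ``s_md`` in (0, 1).

Ablation variants reduce this pipeline: ``sage_only`` scores on ``X~`` alone,
``dva_only`` drops the SAGE encoder (both VAEs read X, the GVAE propagating
on the observed graph), ``gva_only`` keeps just the graph VAE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .autodiff import Tensor, cat
from .io import AssociationMatrix, MDAGraph, build_graph
from .similarity import association_features

__all__ = [
    "VARIANTS",
    "LatentGaussian",
    "ModelState",
    "DVAMDA",
    "neighbor_mean_matrix",
    "gcn_propagation_matrix",
    "sage_encode",
    "vae_encode",
    "gvae_encode",
    "reparameterize",
    "fuse",
    "score_pairs",
]

VARIANTS = ("full", "sage_only", "dva_only", "gva_only")

_CHECKPOINT_VERSION = 1


@dataclass
class LatentGaussian:
    """Per-node diagonal Gaussian posterior (mean and strictly positive var)."""

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if self.mean.shape != self.var.shape:
            raise ValueError("mean and variance must have the same shape")
        if not np.isfinite(self.mean).all():
            raise ValueError("posterior mean must be finite")
        if not (self.var > 0).all():
            raise ValueError("posterior variance must be strictly positive")


# ---------------------------------------------------------------------------
# graph propagation matrices
# ---------------------------------------------------------------------------

def neighbor_mean_matrix(G: MDAGraph) -> np.ndarray:
    """Row-normalized adjacency: row v averages over N(v); zero row if isolated."""
    a = G.adjacency()
    deg = a.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        nmean = np.where(deg > 0, a / np.where(deg > 0, deg, 1.0), 0.0)
    return nmean


def gcn_propagation_matrix(G: MDAGraph) -> np.ndarray:
    """Symmetric-normalized propagation ``D^{-1/2} (A + I) D^{-1/2}``."""
    a = G.adjacency() + np.eye(G.node_count)
    d_inv_sqrt = 1.0 / np.sqrt(a.sum(axis=1))
    return a * np.outer(d_inv_sqrt, d_inv_sqrt)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

class ModelState:
    """All trainable weights plus the architecture hyperparameters.

    Parameters are a flat name -> Tensor mapping; ``config`` records the
    architecture (variant, layer widths, tying, seed) so a checkpoint is
    self-describing.
    """

    def __init__(self, params: dict[str, Tensor], config: dict):
        self.params = params
        self.config = dict(config)

    def __getitem__(self, name: str) -> Tensor:
        return self.params[name]

    def parameters(self) -> list[Tensor]:
        # dict preserves insertion order, so the optimizer sees a stable order
        return list(self.params.values())

    def save(self, path) -> None:
        payload = {
            "version": _CHECKPOINT_VERSION,
            "config": self.config,
            "params": {k: v.data.tolist() for k, v in self.params.items()},
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle)

    @classmethod
    def load(cls, path) -> "ModelState":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        if payload.get("version") != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {payload.get('version')}")
        params = {
            k: Tensor(np.asarray(v, dtype=float), requires_grad=True)
            for k, v in payload["params"].items()
        }
        state = cls(params, payload["config"])
        state._retie()
        return state

    def _retie(self) -> None:
        # tied SAGE weights are stored once; restore aliased references
        if self.config.get("tied_sage"):
            for layer in range(self.config["sage_layers"]):
                self.params[f"sage{layer}_Wagg"] = self.params[f"sage{layer}_Wself"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)), requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def _ones(*shape) -> Tensor:
    return Tensor(np.ones(shape), requires_grad=True)


def init_state(
    d_in: int,
    variant: str = "full",
    hidden_dim: int = 64,
    latent_dim: int = 64,
    predictor_hidden: int = 64,
    sage_layers: int = 2,
    tied_sage: bool = False,
    seed: int = 0,
) -> ModelState:
    """Seeded Glorot-uniform initialization of every weight the variant uses."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    rng = np.random.default_rng(seed)
    params: dict[str, Tensor] = {}

    use_sage = variant in ("full", "sage_only")
    use_vae = variant in ("full", "dva_only")
    use_gvae = variant in ("full", "dva_only", "gva_only")

    if use_sage:
        width = d_in
        for layer in range(sage_layers):
            params[f"sage{layer}_Wself"] = _glorot(rng, width, hidden_dim)
            params[f"sage{layer}_Wagg"] = (
                params[f"sage{layer}_Wself"] if tied_sage else _glorot(rng, width, hidden_dim)
            )
            params[f"sage{layer}_b"] = _zeros(1, hidden_dim)
            width = hidden_dim

    if use_vae:
        params["vae_Wmu"] = _glorot(rng, d_in, latent_dim)
        params["vae_bmu"] = _zeros(1, latent_dim)
        params["vae_Wvar"] = _glorot(rng, d_in, latent_dim)
        params["vae_bvar"] = _zeros(1, latent_dim)
        params["vae_gamma"] = _ones(1, latent_dim)
        params["vae_beta"] = _zeros(1, latent_dim)

    if use_gvae:
        gvae_in = hidden_dim if variant == "full" else d_in
        params["gvae_Wmu"] = _glorot(rng, gvae_in, latent_dim)
        params["gvae_bmu"] = _zeros(1, latent_dim)
        params["gvae_Wvar"] = _glorot(rng, gvae_in, latent_dim)
        params["gvae_bvar"] = _zeros(1, latent_dim)
        params["gvae_gamma"] = _ones(1, latent_dim)
        params["gvae_beta"] = _zeros(1, latent_dim)

    fused_dim = {
        "full": 2 * latent_dim + hidden_dim,
        "sage_only": hidden_dim,
        "dva_only": 2 * latent_dim,
        "gva_only": latent_dim,
    }[variant]
    params["pred_W1"] = _glorot(rng, fused_dim, predictor_hidden)
    params["pred_b1"] = _zeros(1, predictor_hidden)
    params["pred_W2"] = _glorot(rng, predictor_hidden, 1)
    params["pred_b2"] = _zeros(1, 1)

    config = {
        "variant": variant,
        "d_in": d_in,
        "hidden_dim": hidden_dim,
        "latent_dim": latent_dim,
        "predictor_hidden": predictor_hidden,
        "sage_layers": sage_layers,
        "tied_sage": bool(tied_sage),
        "fused_dim": fused_dim,
        "seed": int(seed),
    }
    if tied_sage and use_sage:
        # single storage, aliased use; serialization writes both names once each
        pass
    return ModelState(params, config)


# ---------------------------------------------------------------------------
# tensor-space forward pieces (shared by training and the public wrappers)
# ---------------------------------------------------------------------------

def _standardize(h: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Feature-wise standardization over nodes with a learned affine."""
    mu = h.mean(axis=0, keepdims=True)
    centered = h - mu
    var = (centered * centered).mean(axis=0, keepdims=True)
    return centered * (var + eps) ** -0.5 * gamma + beta


def _sage_t(state: ModelState, X: Tensor, nmean: np.ndarray) -> Tensor:
    n_layers = state.config["sage_layers"]
    prop = Tensor(nmean)
    h = X
    for layer in range(n_layers):
        agg = prop @ h
        pre = agg @ state[f"sage{layer}_Wagg"] + h @ state[f"sage{layer}_Wself"]
        pre = pre + state[f"sage{layer}_b"]
        h = pre.relu() if layer < n_layers - 1 else pre
    return h


def _vae_t(state: ModelState, X: Tensor) -> tuple[Tensor, Tensor]:
    mean = X @ state["vae_Wmu"] + state["vae_bmu"]
    logvar = _standardize(
        X @ state["vae_Wvar"] + state["vae_bvar"], state["vae_gamma"], state["vae_beta"]
    )
    return mean, logvar


def _gvae_t(state: ModelState, H: Tensor, ahat: np.ndarray) -> tuple[Tensor, Tensor]:
    prop = Tensor(ahat)
    mean = prop @ (H @ state["gvae_Wmu"]) + state["gvae_bmu"]
    pre = prop @ (H @ state["gvae_Wvar"]) + state["gvae_bvar"]
    logvar = _standardize(pre, state["gvae_gamma"], state["gvae_beta"])
    return mean, logvar


def _sample_t(mean: Tensor, logvar: Tensor, eps: np.ndarray | None) -> Tensor:
    if eps is None:
        return mean
    return mean + (logvar * 0.5).exp() * Tensor(eps)


def _score_logits_t(state: ModelState, fused: Tensor, pair_nodes: np.ndarray) -> Tensor:
    zhat = fused.rows(pair_nodes[:, 0]) * fused.rows(pair_nodes[:, 1])
    hidden = (zhat @ state["pred_W1"] + state["pred_b1"]).relu()
    return hidden @ state["pred_W2"] + state["pred_b2"]


def forward_t(
    state: ModelState,
    X: Tensor,
    nmean: np.ndarray | None,
    ahat: np.ndarray | None,
    eps_vae: np.ndarray | None = None,
    eps_gvae: np.ndarray | None = None,
) -> dict:
    """Run the variant's full forward pass in tensor space.

    Returns a dict with whichever of ``Xt`` (SAGE output), ``vae``/``gvae``
    (mean, log-variance pairs), ``Z``/``Zt`` (latent samples or means) and
    ``fused`` the variant produces. Passing ``eps_* = None`` uses posterior
    means (deterministic evaluation mode).
    """
    variant = state.config["variant"]
    out: dict = {}
    blocks: list[Tensor] = []

    if variant in ("full", "sage_only"):
        out["Xt"] = _sage_t(state, X, nmean)

    if variant in ("full", "dva_only"):
        mean, logvar = _vae_t(state, X)
        out["vae"] = (mean, logvar)
        out["Z"] = _sample_t(mean, logvar, eps_vae)
        blocks.append(out["Z"])

    if variant in ("full", "dva_only", "gva_only"):
        gvae_input = out["Xt"] if variant == "full" else X
        mean, logvar = _gvae_t(state, gvae_input, ahat)
        out["gvae"] = (mean, logvar)
        out["Zt"] = _sample_t(mean, logvar, eps_gvae)
        blocks.append(out["Zt"])

    if variant in ("full", "sage_only"):
        blocks.append(out["Xt"])

    out["fused"] = blocks[0] if len(blocks) == 1 else cat(blocks, axis=1)
    return out


# ---------------------------------------------------------------------------
# public functional wrappers
# ---------------------------------------------------------------------------

def sage_encode(G: MDAGraph, state: ModelState) -> np.ndarray:
    """GraphSAGE mean-aggregation encoding of the graph's node features."""
    d_in = state.config["d_in"]
    if G.features.shape[1] != d_in:
        raise ValueError(
            f"feature width {G.features.shape[1]} does not match encoder input {d_in}"
        )
    return _sage_t(state, Tensor(G.features), neighbor_mean_matrix(G)).data


def vae_encode(X: np.ndarray, state: ModelState) -> LatentGaussian:
    """Feature-space VAE posterior: affine mean, exp(normalized affine) variance."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != state["vae_Wmu"].shape[0]:
        raise ValueError(
            f"feature width {X.shape[1]} does not match encoder input "
            f"{state['vae_Wmu'].shape[0]}"
        )
    mean, logvar = _vae_t(state, Tensor(X))
    return LatentGaussian(mean.data, np.exp(logvar.data))


def gvae_encode(G_tilde: MDAGraph, state: ModelState) -> LatentGaussian:
    """Graph-VAE posterior from one symmetric-normalized graph convolution."""
    if G_tilde.features.shape[1] != state["gvae_Wmu"].shape[0]:
        raise ValueError(
            f"feature width {G_tilde.features.shape[1]} does not match encoder "
            f"input {state['gvae_Wmu'].shape[0]}"
        )
    mean, logvar = _gvae_t(
        state, Tensor(G_tilde.features), gcn_propagation_matrix(G_tilde)
    )
    return LatentGaussian(mean.data, np.exp(logvar.data))


def reparameterize(
    q: LatentGaussian, rng: np.random.Generator | None = None, mode: str = "eval"
) -> np.ndarray:
    """Draw ``Z = mean + sqrt(var) * eps`` in train mode; return the mean in eval."""
    if mode == "eval":
        return q.mean.copy()
    if mode != "train":
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    if rng is None:
        raise ValueError("train-mode sampling requires a random generator")
    eps = rng.standard_normal(q.mean.shape)
    return q.mean + np.sqrt(q.var) * eps


def fuse(Z=None, Z_tilde=None, X_tilde=None) -> np.ndarray:
    """Column-wise concatenation ``[Z | Z~ | X~]``; absent blocks are skipped."""
    blocks = [np.asarray(b, dtype=float) for b in (Z, Z_tilde, X_tilde) if b is not None]
    blocks = [b for b in blocks if b.shape[1] > 0]
    if not blocks:
        raise ValueError("at least one non-empty block is required")
    rows = {b.shape[0] for b in blocks}
    if len(rows) != 1:
        raise ValueError(f"blocks have mismatched row counts: {rows}")
    return np.concatenate(blocks, axis=1)


def score_pairs(fused: np.ndarray, pairs, state: ModelState, m: int) -> np.ndarray:
    """Score (microbe node, disease node) pairs through Hadamard product + MLP."""
    fused = np.asarray(fused, dtype=float)
    pair_nodes = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
    for u, v in pair_nodes:
        if not (0 <= u < m <= v < fused.shape[0]):
            raise IndexError(
                f"pair ({u}, {v}) invalid: need microbe node < {m} <= disease node "
                f"< {fused.shape[0]}"
            )
    logits = _score_logits_t(state, Tensor(fused), pair_nodes)
    return Tensor(logits.data).sigmoid().data.ravel()


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class DVAMDA(BaseEstimator):
    """Microbe-disease association predictor with dual variational autoencoders.

    A transductive bipartite link predictor: ``fit`` takes a binary
    association matrix (rows = microbes, columns = diseases), derives kernel
    similarity node features, trains the GraphSAGE + dual-VAE + Hadamard-MLP
    pipeline full-batch on labeled pairs, and caches fused node embeddings
    for scoring.

    Parameters
    ----------
    variant:
        ``"full"`` or one of the ablations ``"sage_only"``, ``"dva_only"``,
        ``"gva_only"``.
    hidden_dim, latent_dim, predictor_hidden, sage_layers, tied_sage:
        Architecture sizes; ``tied_sage`` shares the self and aggregate
        weight matrices within each SAGE layer.
    sk_kernel:
        Sigmoid kernel flavor for feature construction (``"logistic"`` or
        ``"tanh"``).
    epochs, lr, beta_vae, beta_gvae, kl_sign, sample_latent:
        Training-loop controls; ``kl_sign="penalize"`` adds the beta-weighted
        KL terms to the objective, ``"subtract"`` reproduces the alternative
        sign convention. ``sample_latent=False`` trains on posterior means.
    random_state:
        Seeds parameter initialization, latent sampling and default negative
        sampling.

    Attributes
    ----------
    state_ : ModelState
        Trained weights and architecture config.
    history_ : list of LossBreakdown
        Per-epoch loss components.
    embeddings_ : ndarray of shape (m+n, fused_dim)
        Evaluation-mode fused node features ``X^``.
    graph_ : MDAGraph
        The (possibly masked) training graph.
    """

    def __init__(
        self,
        variant: str = "full",
        hidden_dim: int = 64,
        latent_dim: int = 64,
        predictor_hidden: int = 64,
        sage_layers: int = 2,
        tied_sage: bool = False,
        sk_kernel: str = "logistic",
        epochs: int = 300,
        lr: float = 1e-2,
        beta_vae: float = 1e-3,
        beta_gvae: float = 1e-3,
        kl_sign: str = "penalize",
        sample_latent: bool = True,
        random_state: int = 0,
    ):
        self.variant = variant
        self.hidden_dim = hidden_dim
        self.latent_dim = latent_dim
        self.predictor_hidden = predictor_hidden
        self.sage_layers = sage_layers
        self.tied_sage = tied_sage
        self.sk_kernel = sk_kernel
        self.epochs = epochs
        self.lr = lr
        self.beta_vae = beta_vae
        self.beta_gvae = beta_gvae
        self.kl_sign = kl_sign
        self.sample_latent = sample_latent
        self.random_state = random_state

    def _as_matrix(self, A) -> AssociationMatrix:
        if isinstance(A, AssociationMatrix):
            return A
        return AssociationMatrix(np.asarray(A))

    def fit(self, A, pairs=None, labels=None, *, graph_matrix=None):
        """Train on an association matrix.

        Parameters
        ----------
        A:
            AssociationMatrix (or binary array); node features are computed
            from it.
        pairs, labels:
            Training supervision as (microbe index, disease index) pairs with
            0/1 labels. Defaults to all positives of ``A`` plus an equal
            number of uniformly sampled unknown pairs.
        graph_matrix:
            Optional binary matrix defining the message-passing edge set
            (defaults to ``A``); pass a masked copy of ``A`` to hide held-out
            positives from propagation while keeping features fixed.
        """
        from .evaluation import sample_negatives
        from .training import TrainConfig, train

        A = self._as_matrix(A)
        X = association_features(A, sk_kernel=self.sk_kernel)
        if graph_matrix is None:
            graph_source = A
        else:
            graph_vals = (
                graph_matrix.values
                if isinstance(graph_matrix, AssociationMatrix)
                else np.asarray(graph_matrix)
            )
            graph_source = AssociationMatrix(
                graph_vals, list(A.microbe_names), list(A.disease_names)
            )
        G = build_graph(graph_source, X)

        if pairs is None:
            positives = A.positives()
            if not positives:
                raise ValueError("association matrix has no positives to train on")
            negatives = sample_negatives(A, len(positives), seed=self.random_state)
            pairs = positives + negatives
            labels = [1] * len(positives) + [0] * len(negatives)
        if labels is None:
            raise ValueError("labels are required when pairs are given")

        cfg = TrainConfig(
            epochs=self.epochs,
            lr=self.lr,
            beta_vae=self.beta_vae,
            beta_gvae=self.beta_gvae,
            kl_sign=self.kl_sign,
            sample_latent=self.sample_latent,
            seed=self.random_state,
        )
        state, history = train(
            G,
            pairs,
            labels,
            cfg,
            variant=self.variant,
            hidden_dim=self.hidden_dim,
            latent_dim=self.latent_dim,
            predictor_hidden=self.predictor_hidden,
            sage_layers=self.sage_layers,
            tied_sage=self.tied_sage,
        )
        self.state_ = state
        self.history_ = history
        self.graph_ = G
        self.m_, self.n_ = A.m, A.n
        self.microbe_names_ = list(A.microbe_names)
        self.disease_names_ = list(A.disease_names)
        out = forward_t(
            state,
            Tensor(G.features),
            neighbor_mean_matrix(G),
            gcn_propagation_matrix(G),
        )
        self.embeddings_ = out["fused"].data
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "state_"):
            raise RuntimeError("this DVAMDA instance is not fitted yet")

    def predict_proba(self, pairs) -> np.ndarray:
        """Association scores in (0, 1) for (microbe index, disease index) pairs."""
        self._check_fitted()
        pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
        node_pairs = np.column_stack([pairs[:, 0], self.m_ + pairs[:, 1]])
        return score_pairs(self.embeddings_, node_pairs, self.state_, self.m_)

    def predict(self, pairs, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(pairs) >= threshold).astype(int)

    def score_matrix(self) -> np.ndarray:
        """Scores for every microbe-disease pair, shape (m, n)."""
        self._check_fitted()
        grid = [(i, j) for i in range(self.m_) for j in range(self.n_)]
        return self.predict_proba(grid).reshape(self.m_, self.n_)
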