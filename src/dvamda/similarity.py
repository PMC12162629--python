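"""Kernel similarities over interaction profiles and node feature assembly.

Each microbe's interaction profile is its row of the association matrix and
each disease's profile is its column. Three kernels are computed per entity
set — the Gaussian interaction profile (GIP) kernel, cosine similarity, and a
sigmoid kernel of the profile inner product — and fused by their elementwise
mean. The fused microbe similarity M (m x m) and disease similarity D (n x n)
are zero-padded to a common width d = max(m, n) and stacked row-wise into the
node feature matrix X of shape (m+n) x d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import expit
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .io import AssociationMatrix

__all__ = [
    "SimilarityMatrix",
    "gaussian_kernel",
    "cosine_similarity",
    "sigmoid_kernel",
    "fuse_similarities",
    "build_node_features",
    "association_features",
    "read_similarity_table",
    "write_similarity_table",
]


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity over one entity set (microbes or diseases)."""

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def size(self) -> int:
        return self.values.shape[0]


def _profiles(profiles) -> np.ndarray:
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("profiles must be a 2-D matrix with at least one row")
    return x


def gaussian_kernel(profiles) -> SimilarityMatrix:
    """Gaussian interaction profile kernel, ``exp(-gamma * ||x_i - x_j||^2)``.

    The bandwidth is data-driven: ``gamma = 1 / mean_k ||x_k||^2`` over the
    entity set, falling back to ``gamma = 1`` when every profile is zero.
    """
    x = _profiles(profiles)
    mean_sq_norm = float(np.mean((x**2).sum(axis=1)))
    gamma = 1.0 / mean_sq_norm if mean_sq_norm > 0 else 1.0
    sq_dist = cdist(x, x, metric="sqeuclidean")
    values = np.exp(-gamma * sq_dist)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix((values + values.T) / 2.0, "gaussian")


def cosine_similarity(profiles) -> SimilarityMatrix:
    """Cosine similarity of profiles; zero-norm rows get similarity 0.

    The diagonal is 1 for nonzero profiles and 0 for all-zero profiles.
    """
    x = _profiles(profiles)
    values = _sk_cosine(x)
    nonzero = (x != 0).any(axis=1)
    values[~nonzero, :] = 0.0
    values[:, ~nonzero] = 0.0
    np.fill_diagonal(values, nonzero.astype(float))
    values = np.clip(values, -1.0, 1.0)
    return SimilarityMatrix((values + values.T) / 2.0, "cosine")


def sigmoid_kernel(profiles, kernel: str = "logistic") -> SimilarityMatrix:
    """Sigmoid functional kernel of the profile inner product, in (0, 1).

    ``kernel="logistic"`` gives ``1 / (1 + exp(-<x_i, x_j>))``;
    ``kernel="tanh"`` the rescaled ``(tanh(<x_i, x_j>) + 1) / 2``.
    """
    x = _profiles(profiles)
    inner = x @ x.T
    if kernel == "logistic":
        values = expit(inner)
    elif kernel == "tanh":
        values = (np.tanh(inner) + 1.0) / 2.0
    else:
        raise ValueError(f"unknown sigmoid kernel {kernel!r}")
    return SimilarityMatrix((values + values.T) / 2.0, "sigmoid")


def fuse_similarities(
    gk: SimilarityMatrix, cs: SimilarityMatrix, sk: SimilarityMatrix
) -> SimilarityMatrix:
    """Average fusion: the elementwise mean ``(GK + CS + SK) / 3``."""
    shapes = {gk.values.shape, cs.values.shape, sk.values.shape}
    if len(shapes) != 1:
        raise ValueError(f"similarity matrices have mismatched shapes: {shapes}")
    return SimilarityMatrix((gk.values + cs.values + sk.values) / 3.0, "fused")


def build_node_features(M, D) -> np.ndarray:
    """Stack microbe and disease similarities into the node feature matrix X.

    The smaller block is right-padded with zero columns to d = max(m, n);
    X = [M; D+] has shape (m+n) x d with microbes in the first m rows.
    """
    m_vals = M.values if isinstance(M, SimilarityMatrix) else np.asarray(M, float)
    d_vals = D.values if isinstance(D, SimilarityMatrix) else np.asarray(D, float)
    if m_vals.shape[0] != m_vals.shape[1] or d_vals.shape[0] != d_vals.shape[1]:
        raise ValueError("similarity blocks must be square")
    m, n = m_vals.shape[0], d_vals.shape[0]
    d = max(m, n)
    top = np.pad(m_vals, ((0, 0), (0, d - m)))
    bottom = np.pad(d_vals, ((0, 0), (0, d - n)))
    return np.vstack([top, bottom])


def association_features(A, sk_kernel: str = "logistic") -> np.ndarray:
    """Full similarity pipeline from an association matrix to node features.

    Microbe profiles are the rows of A, disease profiles its columns; each
    entity set gets its three kernels (GIP bandwidth computed separately per
    set), average fusion, then zero-padded stacking.
    """
    values = A.values if isinstance(A, AssociationMatrix) else np.asarray(A, float)
    blocks = []
    for profiles in (values.astype(float), values.T.astype(float)):
        gk = gaussian_kernel(profiles)
        cs = cosine_similarity(profiles)
        sk = sigmoid_kernel(profiles, kernel=sk_kernel)
        blocks.append(fuse_similarities(gk, cs, sk))
    return build_node_features(blocks[0], blocks[1])


def write_similarity_table(sim: SimilarityMatrix, path, names=None) -> None:
    names = list(names) if names is not None else [str(i) for i in range(sim.size)]
    pd.DataFrame(sim.values, index=names, columns=names).to_csv(path, sep="\t")


def read_similarity_table(path, kind: str = "fused") -> SimilarityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(frame.to_numpy(dtype=float), kind)
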