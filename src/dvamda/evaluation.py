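"""Cross-validation protocol, metrics, and the case-study ranking.

Known associations are split into five non-overlapping folds; an equal number
of unknown (A = 0) pairs is sampled once per run and partitioned alongside
them, so training and test negatives never overlap. Within each fold the test
positives are removed from the message-passing graph and, by default, from
the kernel-similarity feature computation as well: interaction-profile
kernels computed from the full matrix encode the held-out cells and let a
flexible scorer reach far-above-chance AUC even on structureless data, so
the leak-free per-fold refit is the default (``refit_features=False``
reproduces the single up-front similarity computation). Metrics are AUC,
AUPR (average precision), and accuracy / precision / F1 at a 0.5 threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    roc_auc_score,
)

from .io import AssociationMatrix
from .model import DVAMDA

__all__ = [
    "MetricsReport",
    "CVResult",
    "make_folds",
    "sample_negatives",
    "compute_metrics",
    "cross_validate",
    "case_study_rank",
    "degree_product_scores",
]


@dataclass
class MetricsReport:
    """Scalar metrics for one evaluation; AUC/AUPR are NaN if one class is absent."""

    auc: float
    aupr: float
    acc: float
    pre: float
    f1: float
    threshold: float = 0.5

    def as_dict(self) -> dict:
        return {
            "AUC": self.auc,
            "AUPR": self.aupr,
            "ACC": self.acc,
            "PRE": self.pre,
            "F1": self.f1,
        }


@dataclass
class CVResult:
    """Per-fold and averaged metrics plus the run's control baselines."""

    fold_reports: list
    average: MetricsReport
    baseline_reports: list = field(default_factory=list)
    baseline_average: MetricsReport | None = None
    shuffled_average: MetricsReport | None = None
    fold_scores: list = field(default_factory=list)
    fold_labels: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.fold_reports] + [self.average.as_dict()]
        index = [str(i + 1) for i in range(len(self.fold_reports))] + ["Average"]
        frame = pd.DataFrame(rows, index=index)
        frame.index.name = "Index"
        return frame


def make_folds(positives, k: int = 5, seed: int = 0) -> list[list[tuple[int, int]]]:
    """Seeded shuffled partition into k folds whose sizes differ by at most 1."""
    positives = [tuple(p) for p in positives]
    if k > len(positives):
        raise ValueError(f"cannot make {k} folds from {len(positives)} positives")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    return [
        [positives[i] for i in chunk] for chunk in np.array_split(order, k)
    ]


def sample_negatives(
    A: AssociationMatrix, count: int, seed: int = 0, exclude=()
) -> list[tuple[int, int]]:
    """Uniform sample without replacement from the unknown (A = 0) cells."""
    exclude = {tuple(p) for p in exclude}
    zeros = [tuple(p) for p in np.argwhere(A.values == 0)]
    candidates = [p for p in zeros if p not in exclude]
    if count > len(candidates):
        raise ValueError(
            f"requested {count} negatives but only {len(candidates)} unknown cells"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=count, replace=False)
    return [candidates[i] for i in chosen]


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """AUC, AUPR (average precision) and thresholded ACC / PRE / F1.

    AUC is the probability a random positive outscores a random negative
    (ties count one half). With a single class present AUC and AUPR are
    reported as NaN rather than zero.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        auc = aupr = math.nan
    else:
        auc = float(roc_auc_score(labels, scores))
        aupr = float(average_precision_score(labels, scores))
    preds = (scores >= threshold).astype(int)
    acc = float(accuracy_score(labels, preds))
    pre = float(precision_score(labels, preds, zero_division=0))
    f1 = float(f1_score(labels, preds, zero_division=0))
    return MetricsReport(auc, aupr, acc, pre, f1, threshold)


def _average(reports: list[MetricsReport]) -> MetricsReport:
    return MetricsReport(
        float(np.mean([r.auc for r in reports])),
        float(np.mean([r.aupr for r in reports])),
        float(np.mean([r.acc for r in reports])),
        float(np.mean([r.pre for r in reports])),
        float(np.mean([r.f1 for r in reports])),
        reports[0].threshold,
    )


def degree_product_scores(A_train: np.ndarray, pairs) -> np.ndarray:
    """Baseline score proportional to deg(microbe) * deg(disease) in training."""
    A_train = np.asarray(A_train, dtype=float)
    row_deg = A_train.sum(axis=1)
    col_deg = A_train.sum(axis=0)
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    return row_deg[pairs[:, 0]] * col_deg[pairs[:, 1]]


def _fold_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence((seed, tag)).generate_state(1)[0] % (2**31))


def cross_validate(
    A: AssociationMatrix,
    k: int = 5,
    seed: int = 0,
    model_params: dict | None = None,
    refit_features: bool = True,
    edge_masking: bool = True,
    threshold: float = 0.5,
    with_controls: bool = True,
) -> CVResult:
    """k-fold cross-validation with balanced negative sampling.

    Per fold the model trains on the other folds' positives and negatives
    with the fold's test positives masked out of the message-passing graph
    (``edge_masking=False`` reproduces the naive leaky protocol). Alongside
    the model, a degree-product baseline and a shuffled-label control are
    scored on identical folds when ``with_controls`` is set.
    """
    model_params = dict(model_params or {})
    positives = A.positives()
    if not positives:
        raise ValueError("association matrix has no positives")
    pos_folds = make_folds(positives, k, seed=_fold_seed(seed, 0))
    negatives = sample_negatives(A, len(positives), seed=_fold_seed(seed, 1))
    neg_folds = [
        [tuple(p) for p in chunk]
        for chunk in np.array_split(np.asarray(negatives, dtype=int), k)
    ]

    reports, baseline_reports, shuffled_reports = [], [], []
    fold_scores, fold_labels = [], []
    for fold in range(k):
        test_pos, test_neg = pos_folds[fold], neg_folds[fold]
        train_pos = [p for f in range(k) if f != fold for p in pos_folds[f]]
        train_neg = [p for f in range(k) if f != fold for p in neg_folds[f]]
        train_pairs = train_pos + train_neg
        train_labels = [1] * len(train_pos) + [0] * len(train_neg)

        masked = A.values.copy()
        if edge_masking:
            for i, j in test_pos:
                masked[i, j] = 0

        params = dict(model_params)
        params.setdefault("random_state", _fold_seed(seed, 100 + fold))
        model = DVAMDA(**params)
        if refit_features:
            masked_A = AssociationMatrix(
                masked, list(A.microbe_names), list(A.disease_names)
            )
            model.fit(masked_A, train_pairs, train_labels)
        else:
            model.fit(A, train_pairs, train_labels, graph_matrix=masked)

        if edge_masking:
            for i, j in test_pos:
                assert not model.graph_.has_pair(i, j), "test positive leaked into training graph"

        test_pairs = list(test_pos) + list(test_neg)
        test_labels = np.array([1] * len(test_pos) + [0] * len(test_neg))
        scores = model.predict_proba(test_pairs)
        reports.append(compute_metrics(scores, test_labels, threshold))
        fold_scores.append(scores)
        fold_labels.append(test_labels)

        if with_controls:
            baseline = degree_product_scores(masked, test_pairs)
            baseline_reports.append(compute_metrics(baseline, test_labels, threshold))
            perm = np.random.default_rng(_fold_seed(seed, 200 + fold)).permutation(
                len(test_labels)
            )
            shuffled_reports.append(
                compute_metrics(scores, test_labels[perm], threshold)
            )

    return CVResult(
        fold_reports=reports,
        average=_average(reports),
        baseline_reports=baseline_reports,
        baseline_average=_average(baseline_reports) if baseline_reports else None,
        shuffled_average=_average(shuffled_reports) if shuffled_reports else None,
        fold_scores=fold_scores,
        fold_labels=fold_labels,
    )


def case_study_rank(
    A: AssociationMatrix,
    disease: str,
    model_params: dict | None = None,
    top_k: int = 10,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Leave-one-disease-out discovery ranking.

    Every known association of ``disease`` is removed from the training
    supervision and from the message-passing graph (node features stay
    computed from the full matrix, as in a discovery run over curated data);
    the trained model then scores all microbes against the disease. Returns
    the ``top_k`` (microbe name, score) pairs by descending score, ties
    broken by microbe index.
    """
    if disease not in A.disease_names:
        raise KeyError(f"unknown disease {disease!r}")
    j = A.disease_names.index(disease)

    masked = A.values.copy()
    masked[:, j] = 0
    train_pos = [tuple(p) for p in np.argwhere(masked == 1)]
    if not train_pos:
        raise ValueError("no training positives remain after excluding the disease")
    exclude = {(i, j) for i in range(A.m)}
    negatives = sample_negatives(
        AssociationMatrix(masked, list(A.microbe_names), list(A.disease_names)),
        len(train_pos),
        seed=_fold_seed(seed, 300),
        exclude=exclude,
    )
    pairs = train_pos + negatives
    labels = [1] * len(train_pos) + [0] * len(negatives)

    params = dict(model_params or {})
    params.setdefault("random_state", _fold_seed(seed, 301))
    model = DVAMDA(**params)
    model.fit(A, pairs, labels, graph_matrix=masked)
    assert model.graph_.degree(model.m_ + j) == 0, "held-out disease must be isolated"

    scores = model.predict_proba([(i, j) for i in range(A.m)])
    order = np.lexsort((np.arange(A.m), -scores))
    return [(A.microbe_names[i], float(scores[i])) for i in order[: min(top_k, A.m)]]
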