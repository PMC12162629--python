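"""Association tables and the bipartite microbe-disease graph.

The raw input is an edge list of (microbe, disease) name pairs, as exported by
curated association databases such as HMDAD or Disbiome. From it we build a
binary association matrix ``A`` (rows = microbes, columns = diseases) and an
undirected bipartite graph whose nodes are microbes followed by diseases.

Node indexing convention used everywhere in this package: microbes occupy
node indices ``0..m-1`` and diseases ``m..m+n-1``, matching the row order of
the node feature matrix.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "MDAGraph",
    "InputFormatError",
    "read_association_table",
    "build_graph",
    "mask_edges",
]

_HEADER_TOKENS = {"microbe", "microbes", "microbe_name", "disease", "diseases", "disease_name"}


class InputFormatError(ValueError):
    """Raised for malformed association tables; the message names the line."""


@dataclass
class AssociationMatrix:
    """Binary microbe-disease association matrix with name indices.

    Parameters
    ----------
    values:
        Binary matrix of shape ``(m, n)``; ``values[i, j] == 1`` records a
        known association between microbe ``i`` and disease ``j``.
    microbe_names, disease_names:
        Ordered unique labels for the rows and columns.
    """

    values: np.ndarray
    microbe_names: list[str] = field(default_factory=list)
    disease_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        m, n = self.values.shape
        if not self.microbe_names:
            self.microbe_names = [f"microbe_{i}" for i in range(m)]
        if not self.disease_names:
            self.disease_names = [f"disease_{j}" for j in range(n)]
        if len(self.microbe_names) != m or len(self.disease_names) != n:
            raise ValueError("name lists must match matrix shape")
        if len(set(self.microbe_names)) != m or len(set(self.disease_names)) != n:
            raise ValueError("duplicate entity names")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def density(self) -> float:
        return float(self.values.mean()) if self.values.size else 0.0

    def positives(self) -> list[tuple[int, int]]:
        """All (microbe index, disease index) pairs with a known association."""
        return [tuple(p) for p in np.argwhere(self.values == 1)]

    @classmethod
    def from_pairs(
        cls, pairs: list[tuple[str, str]]
    ) -> "AssociationMatrix":
        """Build from (microbe name, disease name) pairs, first-appearance order."""
        microbes: dict[str, int] = {}
        diseases: dict[str, int] = {}
        links: set[tuple[int, int]] = set()
        for microbe, disease in pairs:
            i = microbes.setdefault(microbe, len(microbes))
            j = diseases.setdefault(disease, len(diseases))
            links.add((i, j))
        values = np.zeros((len(microbes), len(diseases)), dtype=np.int8)
        for i, j in links:
            values[i, j] = 1
        return cls(values, list(microbes), list(diseases))

    def to_pairs(self) -> list[tuple[str, str]]:
        return [
            (self.microbe_names[i], self.disease_names[j])
            for i, j in self.positives()
        ]

    def write_pairs(self, path, delimiter: str = "\t") -> None:
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle, delimiter=delimiter)
            writer.writerow(["microbe", "disease"])
            writer.writerows(self.to_pairs())

    def write_table(self, path) -> None:
        """Dense TSV with row/column headers, for inspection."""
        frame = pd.DataFrame(self.values, index=self.microbe_names, columns=self.disease_names)
        frame.to_csv(path, sep="\t")


def read_association_table(path, delimiter: str | None = None) -> AssociationMatrix:
    """Read a two-column (microbe, disease) pair list into a binary matrix.

    Tab- or comma-delimited; ``#``-prefixed comment lines are ignored; an
    optional header line (fields named microbe/disease) is detected and
    skipped. Duplicate pairs collapse to a single association; name order is
    first-appearance order.
    """
    pairs: list[tuple[str, str]] = []
    first_data_line = True
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if delimiter is None:
                delimiter = "\t" if "\t" in line else ","
            fields = [f.strip() for f in line.split(delimiter)]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise InputFormatError(
                    f"line {lineno}: expected at least 2 delimited columns, got {line!r}"
                )
            if first_data_line and {fields[0].lower(), fields[1].lower()} & _HEADER_TOKENS:
                first_data_line = False
                continue
            first_data_line = False
            pairs.append((fields[0], fields[1]))
    if not pairs:
        raise InputFormatError(f"{path}: no association pairs found")
    return AssociationMatrix.from_pairs(pairs)


@dataclass(frozen=True)
class MDAGraph:
    """Undirected bipartite graph of observed associations plus node features.

    Edges are stored canonically as ``(u, v)`` with microbe node ``u < m`` and
    disease node ``m <= v < m + n``; the graph is simple, undirected and has
    no self-loops.
    """

    m: int
    n: int
    edges: frozenset
    features: np.ndarray

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if not (0 <= u < self.m <= v < self.m + self.n):
                raise ValueError(f"edge ({u}, {v}) does not cross the bipartition")
        if self.features.shape[0] != self.node_count:
            raise ValueError(
                f"feature matrix has {self.features.shape[0]} rows, "
                f"expected {self.node_count}"
            )

    @property
    def node_count(self) -> int:
        return self.m + self.n

    def degree(self, node: int) -> int:
        return sum(1 for u, v in self.edges if u == node or v == node)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric (m+n) x (m+n) adjacency matrix."""
        a = np.zeros((self.node_count, self.node_count))
        for u, v in self.edges:
            a[u, v] = a[v, u] = 1.0
        return a

    def has_pair(self, microbe: int, disease: int) -> bool:
        return (microbe, self.m + disease) in self.edges

    def with_features(self, features: np.ndarray) -> "MDAGraph":
        return MDAGraph(self.m, self.n, self.edges, features)


def build_graph(A: AssociationMatrix, X: np.ndarray) -> MDAGraph:
    """Build the bipartite graph: one undirected edge per ``A[i, j] == 1``.

    ``X`` holds node features, microbes first then diseases, so it must have
    ``m + n`` rows.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != A.m + A.n:
        raise ValueError(
            f"feature matrix must have m+n={A.m + A.n} rows, got {X.shape}"
        )
    edges = frozenset((int(i), A.m + int(j)) for i, j in np.argwhere(A.values == 1))
    return MDAGraph(A.m, A.n, edges, X)


def mask_edges(G: MDAGraph, held_out) -> MDAGraph:
    """Remove held-out (microbe index, disease index) pairs from the edge set.

    Features are left untouched and the input graph is not modified; use this
    to hide test positives from message passing during evaluation.
    """
    to_remove = set()
    for i, j in held_out:
        edge = (int(i), G.m + int(j))
        if edge not in G.edges:
            raise ValueError(f"held-out pair ({i}, {j}) is not an edge of the graph")
        to_remove.add(edge)
    return MDAGraph(G.m, G.n, G.edges - to_remove, G.features)
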