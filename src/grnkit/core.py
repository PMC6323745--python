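"""Shared data containers and small network utilities.

The containers are thin, validated wrappers around numpy arrays.  Gene
identifiers (not indices) are the external contract throughout the package;
integer indices are an internal detail tied to the order of ``gene_ids``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "WeightedNetwork",
    "BinaryNetwork",
    "EdgeTable",
    "standardize",
    "threshold_network",
    "degrees",
    "upper_triangle_pairs",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} identifier: {dup!r}")
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with row/column identifiers.

    ``values[j, i]`` is the expression of gene ``gene_ids[j]`` in sample
    ``sample_ids[i]``.  Values are real with no missing entries.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        p, n = self.values.shape
        if p < 2:
            raise ValueError(f"need at least 2 genes, got {p}")
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if len(self.gene_ids) != p or len(self.sample_ids) != n:
            raise ValueError("identifier lengths do not match matrix shape")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(map(str, df.index)), list(map(str, df.columns)))


def _symmetrize_exact(m: np.ndarray) -> np.ndarray:
    # (m + m.T) is bitwise symmetric because float addition commutes.
    return (m + m.T) / 2.0


@dataclass
class WeightedNetwork:
    """Symmetric gene-by-gene edge-strength matrix with zero diagonal."""

    strengths: np.ndarray
    gene_ids: list[str]
    method_tag: str = ""

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, dtype=float)
        p = len(self.gene_ids)
        if self.strengths.shape != (p, p):
            raise ValueError("strengths shape does not match gene_ids")
        if not np.array_equal(self.strengths, self.strengths.T):
            raise ValueError("strengths matrix must be exactly symmetric")
        if np.any(self.strengths.diagonal() != 0.0):
            raise ValueError("strengths diagonal must be zero")
        self.gene_ids = _check_unique(self.gene_ids, "gene")

    @classmethod
    def from_raw(cls, m: np.ndarray, gene_ids: Sequence[str], method_tag: str = "") -> "WeightedNetwork":
        """Build from a nearly-symmetric matrix: averages with the transpose
        (exactly symmetric in floating point) and zeroes the diagonal."""
        m = _symmetrize_exact(np.asarray(m, dtype=float))
        np.fill_diagonal(m, 0.0)
        return cls(m, list(gene_ids), method_tag)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected, unweighted network: a set of unordered index pairs.

    Pairs are stored with the smaller gene index first; no self-loops.
    """

    edges: frozenset[tuple[int, int]]
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(_check_unique(list(self.gene_ids), "gene")))
        p = len(self.gene_ids)
        norm = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on index {a}")
            if not (0 <= a < p and 0 <= b < p):
                raise ValueError(f"edge ({a},{b}) out of range for p={p}")
            norm.add((min(a, b), max(a, b)))
        object.__setattr__(self, "edges", frozenset(norm))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        p = self.n_genes
        a = np.zeros((p, p), dtype=bool)
        for i, j in self.edges:
            a[i, j] = a[j, i] = True
        return a

    def edge_id_pairs(self) -> list[tuple[str, str]]:
        return sorted((self.gene_ids[i], self.gene_ids[j]) for i, j in self.edges)


@dataclass
class EdgeTable:
    """Flat per-edge records: (gene_a, gene_b, strength, p_value, q_value).

    ``gene_a < gene_b`` lexicographically in every record; each unordered
    pair appears at most once.  Missing p/q values are NaN in memory and
    "NA" on disk.
    """

    records: pd.DataFrame

    COLUMNS = ("gene_a", "gene_b", "strength", "p_value", "q_value")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=list(self.COLUMNS)).copy()
        swap = df["gene_a"] > df["gene_b"]
        if swap.any():
            a = df.loc[swap, "gene_a"].copy()
            df.loc[swap, "gene_a"] = df.loc[swap, "gene_b"]
            df.loc[swap, "gene_b"] = a
        if df.duplicated(subset=["gene_a", "gene_b"]).any():
            raise ValueError("duplicate gene pair in edge table")
        for col in ("p_value", "q_value"):
            vals = df[col].to_numpy(dtype=float)
            ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
            if not ok.all():
                raise ValueError(f"{col} outside [0, 1]")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# operations


def standardize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale every gene row to mean 0, variance 1 (divisor n-1).

    Raises ``ValueError`` naming the first constant gene (zero variance),
    since downstream estimators divide by gene standard deviations.
    """
    mu = x.values.mean(axis=1, keepdims=True)
    sd = x.values.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0.0)
    if zero.size:
        raise ValueError(f"gene {x.gene_ids[zero[0]]!r} has zero variance; cannot standardize")
    return ExpressionMatrix((x.values - mu) / sd, list(x.gene_ids), list(x.sample_ids))


def is_standardized(x: ExpressionMatrix, tol: float = 1e-8) -> bool:
    mu = x.values.mean(axis=1)
    var = x.values.var(axis=1, ddof=1)
    return bool(np.all(np.abs(mu) < tol) and np.all(np.abs(var - 1.0) < 1e-6))


def threshold_network(w: WeightedNetwork, t: float) -> BinaryNetwork:
    """Edges are pairs with ``|strength| > t`` (strict)."""
    if t < 0:
        raise ValueError("threshold must be non-negative")
    iu, ju = np.triu_indices(w.n_genes, k=1)
    keep = np.abs(w.strengths[iu, ju]) > t
    edges = frozenset(zip(iu[keep].tolist(), ju[keep].tolist()))
    return BinaryNetwork(edges, tuple(w.gene_ids))


def degrees(b: BinaryNetwork) -> dict[str, int]:
    """Per-gene edge counts, keyed by gene identifier."""
    d = dict.fromkeys(b.gene_ids, 0)
    for i, j in b.edges:
        d[b.gene_ids[i]] += 1
        d[b.gene_ids[j]] += 1
    return d


def upper_triangle_pairs(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the p(p-1)/2 unordered pairs, j < h."""
    return np.triu_indices(p, k=1)


def edge_table_from_network(w: WeightedNetwork, threshold: float = 0.0) -> EdgeTable:
    """Flatten a weighted network into per-edge records (|strength| > threshold).

    p/q-values are absent (NaN); use the ensemble machinery for significance.
    """
    iu, ju = upper_triangle_pairs(w.n_genes)
    keep = np.abs(w.strengths[iu, ju]) > threshold
    rows = []
    for i, j in zip(iu[keep].tolist(), ju[keep].tolist()):
        a, b = sorted((w.gene_ids[i], w.gene_ids[j]))
        rows.append((a, b, w.strengths[i, j], np.nan, np.nan))
    df = pd.DataFrame(rows, columns=list(EdgeTable.COLUMNS))
    return EdgeTable(df)
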