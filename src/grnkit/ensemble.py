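"""Ensemble network aggregation with a permutation null.

Each inference method turns into a per-edge ranking (strongest edge =
rank 1, average ranks on ties); the consensus statistic for a pair is the
harmonic mean of its per-method ranks, which rewards edges that at least
one method ranks very highly.  Significance comes from a permutation
scheme: every gene's values are permuted independently across samples
(destroying gene-gene dependence while preserving marginals), the full
method ensemble is re-run, and the pooled harmonic-mean ranks over all
pairs and permutations form the empirical null.  An observed pair's
p-value is the add-one left-tail quantile of its harmonic-mean rank in
that null, and Benjamini-Hochberg adjustment over all p(p-1)/2 pairs
yields per-edge q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .core import EdgeTable, ExpressionMatrix, WeightedNetwork
from .likelihood import bayesian_glasso, glasso, glasso_sf
from .mutual_info import pcacmi
from .pcor import neighborhood_selection, shrinkage_pcor, space

__all__ = [
    "RankMatrix",
    "NullDistribution",
    "MethodSpec",
    "make_method",
    "default_ensemble",
    "edge_ranks",
    "ena_aggregate",
    "permutation_null",
    "edge_pvalues",
    "ena",
    "ena_score_network",
]

logger = logging.getLogger(__name__)

DEFAULT_PERMUTATIONS = 100


@dataclass
class RankMatrix:
    """Per-pair ranks (or their harmonic-mean aggregate) over unordered pairs."""

    ranks: np.ndarray
    gene_ids: list[str]
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)
        p = len(self.gene_ids)
        if self.ranks.shape != (p, p):
            raise ValueError("rank matrix shape must match gene_ids")

    def upper_values(self) -> np.ndarray:
        iu, ju = np.triu_indices(len(self.gene_ids), k=1)
        return self.ranks[iu, ju]


@dataclass
class NullDistribution:
    """Pooled harmonic-mean ranks over all pairs and permutations."""

    values: np.ndarray
    m_permutations: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float).ravel())


@dataclass(frozen=True)
class MethodSpec:
    """A named, parameter-bound inference method for ensembling."""

    name: str
    runner: Callable[[ExpressionMatrix], WeightedNetwork]


def _runner(name: str, params: dict) -> Callable[[ExpressionMatrix], WeightedNetwork]:
    if name == "shrinkage":
        return lambda x: shrinkage_pcor(x)
    if name == "ns":
        lam = params.get("lam", 0.1)
        return lambda x: neighborhood_selection(x, lam)
    if name == "space":
        lam = params.get("lam", 0.1)
        return lambda x: space(x, lam, outer_iters=params.get("outer_iters", 3))
    if name == "glasso":
        rho = params.get("rho", 0.1)
        return lambda x: glasso(x, rho)
    if name == "glasso_sf":
        rho = params.get("rho", 0.1)
        return lambda x: glasso_sf(x, rho, reweight_iters=params.get("reweight_iters", 5))
    if name == "pcacmi":
        return lambda x: pcacmi(
            x, alpha=params.get("alpha", 0.03), max_order=params.get("max_order", 2)
        ).to_network()
    if name == "bglasso":
        return lambda x: bayesian_glasso(
            x,
            lam=params.get("lam", 1.0),
            iterations=params.get("iterations", 5000),
            burn_in=params.get("burn_in", 1000),
            thinning=params.get("thinning", 2),
            seed=params.get("seed", 0),
        )
    raise ValueError(f"unknown method {name!r}; available: {sorted(AVAILABLE_METHODS)}")


AVAILABLE_METHODS = {"shrinkage", "ns", "space", "glasso", "glasso_sf", "pcacmi", "bglasso"}


def make_method(name: str, **params) -> MethodSpec:
    """Bind a method name and its tuning parameters into a MethodSpec."""
    return MethodSpec(name, _runner(name, params))


def default_ensemble(**overrides) -> list[MethodSpec]:
    """The six-method ensemble used in the simulation studies:
    NS, GLASSO, GLASSO-SF, PCACMI, SPACE and BayesianGLASSO.

    ``overrides`` maps method name -> parameter dict.
    """
    names = ["ns", "glasso", "glasso_sf", "pcacmi", "space", "bglasso"]
    return [make_method(n, **overrides.get(n, {})) for n in names]


# ---------------------------------------------------------------------------
# ranking and aggregation


def edge_ranks(w: WeightedNetwork) -> RankMatrix:
    """Rank pairs by |strength|, strongest first; ties get average ranks."""
    p = w.n_genes
    iu, ju = np.triu_indices(p, k=1)
    vals = np.abs(w.strengths[iu, ju])
    r = rankdata(-vals, method="average")
    ranks = np.zeros((p, p))
    ranks[iu, ju] = r
    ranks[ju, iu] = r
    return RankMatrix(ranks, list(w.gene_ids), w.method_tag)


def ena_aggregate(rank_matrices: Sequence[RankMatrix]) -> RankMatrix:
    """Harmonic mean of per-method ranks: K / sum_k 1/rank_k per pair."""
    if len(rank_matrices) < 2:
        raise ValueError("need at least two rank matrices to aggregate")
    gene_ids = rank_matrices[0].gene_ids
    for rm in rank_matrices[1:]:
        if rm.gene_ids != gene_ids:
            raise ValueError("rank matrices cover different gene sets")
    k = len(rank_matrices)
    inv_sum = np.zeros_like(rank_matrices[0].ranks)
    for rm in rank_matrices:
        inv_sum += 1.0 / rm.ranks if np.all(rm.ranks > 0) else 1.0 / np.maximum(rm.ranks, 1e-300)
    agg = k / inv_sum
    np.fill_diagonal(agg, 0.0)
    return RankMatrix(agg, list(gene_ids), "ena")


def _ena_ranks(x: ExpressionMatrix, methods: Sequence[MethodSpec]) -> RankMatrix:
    mats = [edge_ranks(spec.runner(x)) for spec in methods]
    return ena_aggregate(mats)


def ena_score_network(x: ExpressionMatrix, methods: Sequence[MethodSpec] | None = None) -> WeightedNetwork:
    """Consensus edge scores: negated harmonic-mean rank (higher = stronger)."""
    methods = list(methods) if methods is not None else default_ensemble()
    agg = _ena_ranks(x, methods)
    n_pairs = len(agg.gene_ids) * (len(agg.gene_ids) - 1) / 2
    strengths = (n_pairs + 1.0) - agg.ranks  # positive, decreasing in rank
    np.fill_diagonal(strengths, 0.0)
    return WeightedNetwork.from_raw(strengths, agg.gene_ids, "ena")


# ---------------------------------------------------------------------------
# permutation null and p-values


def _permute_genes(x: ExpressionMatrix, rng: np.random.Generator) -> ExpressionMatrix:
    vals = x.values.copy()
    for j in range(vals.shape[0]):
        vals[j] = vals[j, rng.permutation(vals.shape[1])]
    return ExpressionMatrix(vals, list(x.gene_ids), list(x.sample_ids))


def permutation_null(
    x: ExpressionMatrix,
    methods: Sequence[MethodSpec] | None = None,
    m_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> NullDistribution:
    """Pooled harmonic-mean ranks from ``m_permutations`` permuted datasets.

    Methods run on permuted data with the same tuning parameters as on the
    observed data, so observed and null statistics are exchangeable under
    the no-dependence hypothesis.  A method failure on any permuted dataset
    aborts with the method named.
    """
    if m_permutations < 1:
        raise ValueError("m_permutations must be >= 1")
    methods = list(methods) if methods is not None else default_ensemble()
    rng = np.random.default_rng(seed)
    pooled: list[np.ndarray] = []
    for m in range(m_permutations):
        xp = _permute_genes(x, rng)
        mats = []
        for spec in methods:
            try:
                mats.append(edge_ranks(spec.runner(xp)))
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise RuntimeError(
                    f"method {spec.name!r} failed on permuted dataset {m + 1}: {exc}"
                ) from exc
        pooled.append(ena_aggregate(mats).upper_values())
    return NullDistribution(np.concatenate(pooled), m_permutations, seed)


def edge_pvalues(observed: RankMatrix, null: NullDistribution) -> EdgeTable:
    """Left-tail empirical p-values of observed harmonic-mean ranks, with BH.

    Small harmonic-mean rank = consistently strong edge, so
    ``p = (1 + #{null <= r}) / (1 + |null|)``; the add-one keeps p > 0 at
    finite permutation counts.  q-values are Benjamini-Hochberg over all
    p(p-1)/2 pairs.
    """
    if null.values.size == 0:
        raise ValueError("empty null distribution")
    p = len(observed.gene_ids)
    iu, ju = np.triu_indices(p, k=1)
    r_obs = observed.ranks[iu, ju]
    counts = np.searchsorted(null.values, r_obs, side="right")
    pvals = (1.0 + counts) / (1.0 + null.values.size)
    pvals = np.minimum(pvals, 1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    gene_ids = observed.gene_ids
    rows = []
    for k, (j, h) in enumerate(zip(iu.tolist(), ju.tolist())):
        a, b = sorted((gene_ids[j], gene_ids[h]))
        rows.append((a, b, r_obs[k], pvals[k], qvals[k]))
    df = pd.DataFrame(rows, columns=list(EdgeTable.COLUMNS))
    return EdgeTable(df)


def ena(
    x: ExpressionMatrix,
    methods: Sequence[MethodSpec] | None = None,
    m_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> EdgeTable:
    """Full ensemble analysis: consensus ranks, permutation null, p/q-values.

    The returned table's ``strength`` column holds the harmonic-mean rank
    (small = strong, consistent edge).
    """
    methods = list(methods) if methods is not None else default_ensemble()
    observed = _ena_ranks(x, methods)
    null = permutation_null(x, methods, m_permutations, seed)
    return edge_pvalues(observed, null)
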