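"""Information-theoretic inference: path consistency on conditional MI.

Under a Gaussian model, (conditional) mutual information between genes j
and h given a conditioning set C has the closed form

    MI(j; h | C) = 1/2 * log( det R_{jC} * det R_{hC}
                              / (det R_C * det R_{jhC}) )        [nats]

with R the correlation matrix and ``det R_{}`` of the empty set equal to 1;
unconditionally this is -1/2 * log(1 - r_jh^2).  The path-consistency
algorithm starts from the pairwise-MI graph and, at increasing conditioning
order L, deletes an edge only if even the most supportive size-L subset of
the pair's common neighbors yields CMI below the threshold alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core import ExpressionMatrix, WeightedNetwork

__all__ = ["MIResult", "gaussian_mi", "pcacmi", "DEFAULT_ALPHA"]

#: MI deletion threshold (nats); the published default for this algorithm
DEFAULT_ALPHA = 0.03


@dataclass
class MIResult:
    """Final (conditional) MI score retained per pair.

    ``entropy_scores[j, h]`` is the last MI/CMI value computed for the pair:
    pairs deleted at some order carry the score that fell below ``alpha``,
    surviving pairs the maximal CMI of the highest order that examined them.
    """

    entropy_scores: np.ndarray
    final_order: int
    alpha: float
    gene_ids: list[str]

    def to_network(self) -> WeightedNetwork:
        return WeightedNetwork.from_raw(self.entropy_scores, self.gene_ids, "pcacmi")

    def binary_edges(self) -> set[tuple[int, int]]:
        """Edges whose retained score clears alpha (the inferred structure)."""
        p = self.entropy_scores.shape[0]
        iu, ju = np.triu_indices(p, k=1)
        keep = self.entropy_scores[iu, ju] >= self.alpha
        return set(zip(iu[keep].tolist(), ju[keep].tolist()))


class _CorrelationMI:
    """Closed-form Gaussian MI over a fixed correlation matrix, with a
    log-determinant cache keyed by the (sorted) index subset."""

    def __init__(self, r: np.ndarray):
        self.r = r
        self._cache: dict[tuple[int, ...], float] = {(): 0.0}

    def logdet(self, subset: tuple[int, ...]) -> float:
        val = self._cache.get(subset)
        if val is None:
            sub = self.r[np.ix_(subset, subset)]
            sign, val = np.linalg.slogdet(sub)
            if sign <= 0:
                raise np.linalg.LinAlgError(
                    f"conditioning correlation submatrix {subset} is singular or not PD"
                )
            self._cache[subset] = val
        return val

    def mi(self, j: int, h: int, cond: tuple[int, ...]) -> float:
        cond = tuple(sorted(cond))
        jc = tuple(sorted((j,) + cond))
        hc = tuple(sorted((h,) + cond))
        jhc = tuple(sorted((j, h) + cond))
        val = 0.5 * (self.logdet(jc) + self.logdet(hc) - self.logdet(cond) - self.logdet(jhc))
        return max(val, 0.0)


def _correlation(x: ExpressionMatrix) -> np.ndarray:
    r = np.corrcoef(x.values)
    np.fill_diagonal(r, 1.0)
    return r


def gaussian_mi(x: ExpressionMatrix, j: int, h: int, cond: set[int] | None = None) -> float:
    """Gaussian (conditional) mutual information between genes j and h, in nats."""
    if j == h:
        raise ValueError("j and h must differ")
    cond_t = tuple(sorted(cond or ()))
    if j in cond_t or h in cond_t:
        raise ValueError("conditioning set must exclude j and h")
    return _CorrelationMI(_correlation(x)).mi(j, h, cond_t)


def pcacmi(x: ExpressionMatrix, alpha: float = DEFAULT_ALPHA, max_order: int = 2) -> MIResult:
    """Path-consistency pruning on conditional mutual information.

    Order 0 computes pairwise MI and deletes pairs below ``alpha``.  At
    order L >= 1, each surviving pair is tested against every size-L subset
    of its common neighbors in the current graph; the pair keeps the
    *maximal* CMI and is deleted only if that maximum is below ``alpha``.
    Deletions within an order are simultaneous.  The loop stops when no
    pair has enough common neighbors for the next order, or at
    ``max_order``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    p = x.n_genes
    calc = _CorrelationMI(_correlation(x))

    scores = np.zeros((p, p))
    adj: list[set[int]] = [set() for _ in range(p)]
    iu, ju = np.triu_indices(p, k=1)
    for j, h in zip(iu.tolist(), ju.tolist()):
        mi0 = calc.mi(j, h, ())
        scores[j, h] = scores[h, j] = mi0
        if mi0 >= alpha:
            adj[j].add(h)
            adj[h].add(j)

    final_order = 0
    for order in range(1, max_order + 1):
        any_tested = False
        deletions: list[tuple[int, int]] = []
        pairs = [(j, h) for j in range(p) for h in adj[j] if h > j]
        for j, h in pairs:
            common = sorted((adj[j] & adj[h]) - {j, h})
            if len(common) < order:
                continue
            any_tested = True
            best = max(calc.mi(j, h, subset) for subset in combinations(common, order))
            scores[j, h] = scores[h, j] = best
            if best < alpha:
                deletions.append((j, h))
        if not any_tested:
            break
        final_order = order
        for j, h in deletions:
            adj[j].discard(h)
            adj[h].discard(j)

    return MIResult(scores, final_order, alpha, list(x.gene_ids))
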