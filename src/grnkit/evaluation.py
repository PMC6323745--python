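"""ROC/AUC evaluation of inferred networks against simulated truth.

Different method families are swept the way their output allows, mirroring
the standard benchmarking protocol for these estimators:

* score methods (shrinkage partial correlation, Bayesian graphical lasso,
  the ensemble consensus) emit one continuous strength per pair and are
  swept over score thresholds;
* mutual-information methods are swept over the entropy threshold on their
  final retained scores (the pruning threshold alpha only shapes the
  structure-search stage);
* penalized methods (NS, SPACE, GLASSO, GLASSO-SF) are swept over their
  tuning parameter, one (FPR, TPR) point per grid value, with (0,0) and
  (1,1) appended.

AUC is always the trapezoidal integral of the points sorted by FPR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import BinaryNetwork, ExpressionMatrix, WeightedNetwork, standardize
from .ensemble import MethodSpec, default_ensemble, ena_score_network
from .likelihood import bayesian_glasso, glasso_path, glasso_sf_path
from .mutual_info import pcacmi
from .pcor import LassoPath, default_penalty_grid, ns_path, shrinkage_pcor, space_path
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "RocCurve",
    "roc_from_scores",
    "roc_from_path",
    "BenchmarkMethod",
    "default_benchmark_methods",
    "run_benchmark",
    "benchmark_grid",
]

logger = logging.getLogger(__name__)


@dataclass
class RocCurve:
    points: np.ndarray  # (k, 2) array of (fpr, tpr), sorted by fpr
    auc: float
    method_tag: str
    sweep_kind: str  # score_threshold | tuning_parameter | entropy_threshold

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if np.any(np.diff(self.points[:, 0]) < 0):
            raise ValueError("points must be sorted by FPR")


def _truth_labels(truth: BinaryNetwork) -> np.ndarray:
    p = truth.n_genes
    iu, ju = np.triu_indices(p, k=1)
    adj = truth.adjacency()
    return adj[iu, ju]


def _check_truth(truth: BinaryNetwork) -> None:
    n_pairs = truth.n_genes * (truth.n_genes - 1) // 2
    if truth.n_edges == 0 or truth.n_edges == n_pairs:
        raise ValueError("truth network must be neither empty nor complete")


def _finish(points: list[tuple[float, float]], tag: str, kind: str) -> RocCurve:
    pts = np.array(sorted(set(points)))
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return RocCurve(pts, auc, tag, kind)


def roc_from_scores(scores: WeightedNetwork, truth: BinaryNetwork, sweep_kind: str = "score_threshold") -> RocCurve:
    """Threshold sweep over all distinct |score| values."""
    if list(scores.gene_ids) != list(truth.gene_ids):
        raise ValueError("scores and truth cover different gene sets")
    _check_truth(truth)
    labels = _truth_labels(truth)
    p = truth.n_genes
    iu, ju = np.triu_indices(p, k=1)
    s = np.abs(scores.strengths[iu, ju])
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    l_sorted = labels[order]
    tp = np.cumsum(l_sorted)
    fp = np.cumsum(~l_sorted)
    # one operating point after each distinct score value (edge iff |s| > t)
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    cut = np.concatenate([distinct, [s.size - 1]])
    points = [(0.0, 0.0)] + [(fp[c] / n_neg, tp[c] / n_pos) for c in cut] + [(1.0, 1.0)]
    return _finish(points, scores.method_tag, sweep_kind)


def roc_from_path(path: LassoPath, truth: BinaryNetwork) -> RocCurve:
    """One (FPR, TPR) point per penalty value, from the nonzero support."""
    if not path.networks:
        raise ValueError("empty path")
    if list(path.networks[0].gene_ids) != list(truth.gene_ids):
        raise ValueError("path and truth cover different gene sets")
    _check_truth(truth)
    labels = _truth_labels(truth)
    p = truth.n_genes
    iu, ju = np.triu_indices(p, k=1)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    points = [(0.0, 0.0), (1.0, 1.0)]
    for net in path.networks:
        sel = np.abs(net.strengths[iu, ju]) > 0
        tp = int((sel & labels).sum())
        fp = int((sel & ~labels).sum())
        points.append((fp / n_neg, tp / n_pos))
    tag = path.networks[0].method_tag
    return _finish(points, tag, "tuning_parameter")


# ---------------------------------------------------------------------------
# benchmark harness


@dataclass(frozen=True)
class BenchmarkMethod:
    """One benchmark entry: a tag plus how its ROC curve is built."""

    tag: str
    kind: str  # "score" | "path" | "entropy"
    runner: Callable[[ExpressionMatrix], WeightedNetwork | LassoPath]


def default_benchmark_methods(
    grid_points: int = 20,
    bglasso_iterations: int = 5000,
    bglasso_burn_in: int = 1000,
    sf_reweight_iters: int = 5,
    space_outer_iters: int = 2,
    ensemble: Sequence[MethodSpec] | None = None,
    include_ena: bool = True,
) -> list[BenchmarkMethod]:
    """The seven estimators plus the ensemble consensus, with their sweep kinds."""

    def grid(x: ExpressionMatrix) -> np.ndarray:
        return default_penalty_grid(x, n_points=grid_points)

    methods = [
        BenchmarkMethod("shrinkage", "score", shrinkage_pcor),
        BenchmarkMethod("ns", "path", lambda x: ns_path(x, grid(x))),
        BenchmarkMethod("glasso", "path", lambda x: glasso_path(x, grid(x))),
        BenchmarkMethod(
            "glasso_sf", "path", lambda x: glasso_sf_path(x, grid(x), reweight_iters=sf_reweight_iters)
        ),
        BenchmarkMethod("space", "path", lambda x: space_path(x, grid(x), outer_iters=space_outer_iters)),
        BenchmarkMethod("pcacmi", "entropy", lambda x: pcacmi(x).to_network()),
        BenchmarkMethod(
            "bglasso",
            "score",
            lambda x: bayesian_glasso(x, iterations=bglasso_iterations, burn_in=bglasso_burn_in),
        ),
    ]
    if include_ena:
        ens = list(ensemble) if ensemble is not None else default_ensemble(
            bglasso={"iterations": bglasso_iterations, "burn_in": bglasso_burn_in},
            glasso_sf={"reweight_iters": sf_reweight_iters},
            space={"outer_iters": space_outer_iters},
        )
        methods.append(BenchmarkMethod("ena", "score", lambda x: ena_score_network(x, ens)))
    return methods


def _roc_for(method: BenchmarkMethod, x: ExpressionMatrix, truth: BinaryNetwork) -> float:
    out = method.runner(x)
    if method.kind == "path":
        assert isinstance(out, LassoPath)
        return roc_from_path(out, truth).auc
    assert isinstance(out, WeightedNetwork)
    kind = "entropy_threshold" if method.kind == "entropy" else "score_threshold"
    return roc_from_scores(out, truth, kind).auc


def run_benchmark(
    config: SimulationConfig,
    methods: Sequence[BenchmarkMethod] | None = None,
    replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ``replicates`` datasets under ``config`` and score each method.

    Per-replicate seeds depend only on ``seed`` and the replicate index, so
    running the same seed at two noise levels or sample sizes evaluates the
    methods on paired structures.  Method failures are recorded as NaN AUC
    with the error message, not raised.

    Returns a table with columns (method_tag, replicate, p, n, epsilon, auc,
    error).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    methods = list(methods) if methods is not None else default_benchmark_methods()
    rows = []
    for rep in range(replicates):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2 ** 31))
        cfg = SimulationConfig(config.p, config.n, config.epsilon, rep_seed, config.attachment)
        ps, x = simulate_dataset(cfg)
        xs = standardize(x)
        for method in methods:
            try:
                auc = _roc_for(method, xs, ps.structure)
                err = ""
            except Exception as exc:  # noqa: BLE001 - benchmark cells record failures
                logger.warning("%s failed on replicate %d: %s", method.tag, rep, exc)
                auc, err = float("nan"), str(exc)
            rows.append((method.tag, rep, config.p, config.n, config.epsilon, auc, err))
    return pd.DataFrame(rows, columns=["method_tag", "replicate", "p", "n", "epsilon", "auc", "error"])


def benchmark_grid(
    p: int,
    sample_sizes: Sequence[int],
    noise_levels: Sequence[float],
    methods: Sequence[BenchmarkMethod] | None = None,
    replicates: int = 10,
    seed: int = 0,
    attachment: int = 2,
) -> pd.DataFrame:
    """Full study grid over sample sizes and noise levels, paired by seed."""
    tables = []
    for n in sample_sizes:
        for eps in noise_levels:
            cfg = SimulationConfig(p=p, n=int(n), epsilon=float(eps), seed=seed, attachment=attachment)
            tables.append(run_benchmark(cfg, methods, replicates, seed))
    return pd.concat(tables, ignore_index=True)
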