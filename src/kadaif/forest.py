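"""Isolation forests over ordination splits.

The estimator builds an ensemble of t random trees. Each internal node
draws a random multiset of psi features, renormalizes that subset to a
relative-abundance profile (compositional mode), ordinates it (PCoA on
Bray-Curtis distances by default, PCA for non-compositional omics),
picks one of the leading axes with probability proportional to the
variance it explains, and splits the node's samples at a uniform random
threshold along that axis. Samples that are easy to isolate — i.e. that
end up alone after few random splits — are anomalies.

Scores follow the isolation-forest convention: with E(d(x)) the average
isolation depth of sample x across trees and c(n) the expected path
length of an unsuccessful binary-search-tree lookup among n items,

    s(x) = 2 ** (-E(d(x)) / c(n)),      c(n) = 2 (H(n-1) - (n-1)/n),

so s is in (0, 1], anchored at 0.5 for an average sample, and larger for
anomalies. A single-feature baseline (classic isolation forest splits,
same depth bookkeeping and score) is provided for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .ordination import (
    ReducerArtifact,
    bray_curtis_matrix,
    draw_threshold_and_split,
    pca_reduce,
    pcoa,
    select_component,
    subsample_features,
)
from .table import FeatureTable

__all__ = [
    "KadaifParams",
    "TreeNode",
    "IsolationTree",
    "KadaifForest",
    "AnomalyScoreReport",
    "harmonic_number",
    "average_path_length",
    "anomaly_score",
    "build_tree",
    "build_forest",
    "build_baseline_forest",
    "isolation_depth",
    "score_samples",
    "baseline_isolation_forest",
]

_EULER_GAMMA = 0.5772156649015328606
# exact summation below this; series expansion above (agrees to << 1e-6)
_HARMONIC_EXACT_LIMIT = 100_000
_harmonic_cumsum = np.cumsum(1.0 / np.arange(1, 1025))


def harmonic_number(m: int) -> float:
    """H(m) = sum_{i=1..m} 1/i, by direct summation (memoized).

    Above a large cutoff the Euler-Maclaurin expansion
    ln m + gamma + 1/(2m) - 1/(12 m^2) is used; at the crossover the two
    agree far within 1e-6.
    """
    global _harmonic_cumsum
    m = int(m)
    if m < 1:
        raise ValueError(f"harmonic number requires m >= 1, got {m}")
    if m > _HARMONIC_EXACT_LIMIT:
        return math.log(m) + _EULER_GAMMA + 1.0 / (2 * m) - 1.0 / (12 * m * m)
    if m > _harmonic_cumsum.size:
        n0 = _harmonic_cumsum.size
        n1 = max(2 * n0, m)
        ext = _harmonic_cumsum[-1] + np.cumsum(1.0 / np.arange(n0 + 1, n1 + 1))
        _harmonic_cumsum = np.concatenate([_harmonic_cumsum, ext])
    return float(_harmonic_cumsum[m - 1])


def average_path_length(n: int) -> float:
    """c(n) = 2 (H(n-1) - (n-1)/n); c(0) = c(1) = 0 by convention."""
    n = int(n)
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    if n < 2:
        return 0.0
    return 2.0 * (harmonic_number(n - 1) - (n - 1) / n)


def anomaly_score(mean_depth: float, n: int) -> float:
    """s = 2 ** (-mean_depth / c(n)); strictly decreasing in mean_depth."""
    if n < 2:
        raise ValueError(f"anomaly score needs n >= 2 training samples, got {n}")
    if mean_depth < 0:
        raise ValueError(f"mean depth must be non-negative, got {mean_depth}")
    return float(2.0 ** (-mean_depth / average_path_length(n)))


@dataclass
class KadaifParams:
    """Algorithm knobs.

    t : number of trees in the forest.
    max_depth : maximal tree depth l; defaults to the number of samples.
    psi_fraction, psi_min : each node draws max(psi_min,
        round(psi_fraction * F)) features — about 1% with a floor of 10.
    with_replacement : feature subsampling with replacement (duplicates
        kept as separate columns).
    r : stop splitting once a node holds at most r samples.
    n_components : number of candidate ordination axes per node.
    pc_selection : "variance_weighted" | "uniform" | "first".
    reduction : "pcoa_braycurtis" | "pca".
    renormalize_nodes : row-renormalize node subsets; None resolves to
        True for pcoa_braycurtis (compositional pipeline) and False for
        pca (mean-centering on the given scale).
    flag_threshold : scores above this are flagged as anomalies.
    degenerate_retry_limit : fresh feature subsets tried after a
        degenerate split before giving up and making a leaf.
    seed : master seed; each tree gets an independent spawned substream,
        so serial and parallel builds agree bit-for-bit.
    n_jobs : worker processes for tree building (joblib).
    """

    t: int = 100
    max_depth: int | None = None
    psi_fraction: float = 0.01
    psi_min: int = 10
    with_replacement: bool = True
    r: int = 1
    n_components: int = 20
    pc_selection: str = "variance_weighted"
    reduction: str = "pcoa_braycurtis"
    renormalize_nodes: bool | None = None
    flag_threshold: float = 0.5
    degenerate_retry_limit: int = 3
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if not 0 < self.psi_fraction <= 1:
            raise ValueError("psi_fraction must be in (0, 1]")
        if self.psi_min < 1:
            raise ValueError("psi_min must be >= 1")
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.pc_selection not in ("variance_weighted", "uniform", "first"):
            raise ValueError(f"unknown pc_selection {self.pc_selection!r}")
        if self.reduction not in ("pcoa_braycurtis", "pca"):
            raise ValueError(f"unknown reduction {self.reduction!r}")
        if self.degenerate_retry_limit < 0:
            raise ValueError("degenerate_retry_limit must be >= 0")

    @property
    def renormalize_resolved(self) -> bool:
        if self.renormalize_nodes is None:
            return self.reduction == "pcoa_braycurtis"
        return self.renormalize_nodes


@dataclass
class TreeNode:
    """One node of an isolation tree (leaf or internal)."""

    depth: int
    members: np.ndarray | None = None  # leaf: training-sample indices
    feature_indices: np.ndarray | None = None  # internal: node's feature multiset
    artifact: ReducerArtifact | None = None  # internal (None for baseline splits)
    component_index: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.members is not None

    @property
    def size(self) -> int:
        return len(self.members) if self.is_leaf else 0


@dataclass
class IsolationTree:
    root: TreeNode
    n_train: int
    path_lengths: np.ndarray = field(repr=False)  # per training sample


@dataclass
class KadaifForest:
    trees: list[IsolationTree]
    n: int
    params: KadaifParams
    c_n: float
    method: str  # "kadaif" | "baseline_if"
    sample_ids: list[str]

    def mean_depths(self) -> np.ndarray:
        return np.mean([t.path_lengths for t in self.trees], axis=0)

    def scores(self) -> np.ndarray:
        return 2.0 ** (-self.mean_depths() / self.c_n)

    def report(self, threshold: float | None = None) -> "AnomalyScoreReport":
        thr = self.params.flag_threshold if threshold is None else threshold
        depths = self.mean_depths()
        scores = 2.0 ** (-depths / self.c_n)
        return AnomalyScoreReport(
            sample_ids=list(self.sample_ids),
            mean_depth=depths,
            score=scores,
            flagged=scores > thr,
            threshold=thr,
        )

    def score_new(self, table: FeatureTable) -> "AnomalyScoreReport":
        """Score samples that were not in the training set.

        Requires pca reduction (or the single-feature baseline): PCoA has
        no out-of-sample projection.
        """
        if self.method == "kadaif" and self.params.reduction != "pca":
            raise NotImplementedError(
                "out-of-sample scoring requires reduction='pca'; "
                "pcoa_braycurtis can only score the fitted samples"
            )
        renorm = self.params.renormalize_resolved
        depths = np.zeros(table.n_samples)
        for i, row in enumerate(table.values):
            total = 0.0
            for tree in self.trees:
                total += _traverse_depth(tree.root, row, renorm)
            depths[i] = total / len(self.trees)
        scores = 2.0 ** (-depths / self.c_n)
        thr = self.params.flag_threshold
        return AnomalyScoreReport(
            sample_ids=list(table.sample_ids),
            mean_depth=depths,
            score=scores,
            flagged=scores > thr,
            threshold=thr,
        )


@dataclass
class AnomalyScoreReport:
    sample_ids: list[str]
    mean_depth: np.ndarray
    score: np.ndarray
    flagged: np.ndarray
    threshold: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "mean_depth": self.mean_depth,
                "anomaly_score": self.score,
                "flagged": self.flagged,
            }
        )


def _kadaif_split(values: np.ndarray, params: KadaifParams, rng: np.random.Generator):
    """Attempt one ordination split of a node; None when degenerate."""
    n_features = values.shape[1]
    idx = subsample_features(n_features, params, rng)
    subset = values[:, idx]
    if params.renormalize_resolved:
        # inputs were validated non-negative at table level
        sums = subset.sum(axis=1, keepdims=True)
        good = sums > 0
        subset = np.divide(subset, sums, out=np.zeros_like(subset), where=good)
    if params.reduction == "pcoa_braycurtis":
        artifact = pcoa(bray_curtis_matrix(subset), params.n_components, validate=False)
    else:
        artifact = pca_reduce(subset, params.n_components)
    axis = select_component(artifact, params.pc_selection, rng)
    if axis is None:
        return None
    res = draw_threshold_and_split(artifact.coordinates[:, axis], rng)
    if res is None:
        return None
    threshold, left, right = res
    return idx, artifact, axis, threshold, left, right


def _baseline_split(values: np.ndarray, params: KadaifParams, rng: np.random.Generator):
    """Classic isolation-forest split: one random feature, uniform threshold."""
    j = int(rng.integers(0, values.shape[1]))
    col = values[:, j]
    res = draw_threshold_and_split(col, rng)
    if res is None:
        return None
    threshold, left, right = res
    return np.array([j]), None, None, threshold, left, right


_SPLITTERS = {"kadaif": _kadaif_split, "baseline_if": _baseline_split}


def _grow(values, indices, depth, max_depth, params, rng, splitter, sink):
    if depth >= max_depth or indices.size <= params.r:
        sink.append((indices, depth))
        return TreeNode(depth=depth, members=indices)
    node_values = values[indices]
    for _ in range(params.degenerate_retry_limit + 1):
        res = splitter(node_values, params, rng)
        if res is not None:
            break
    else:
        sink.append((indices, depth))
        return TreeNode(depth=depth, members=indices)
    feat, artifact, axis, threshold, left, right = res
    node = TreeNode(
        depth=depth,
        feature_indices=feat,
        artifact=artifact,
        component_index=axis,
        threshold=threshold,
    )
    node.left = _grow(values, indices[left], depth + 1, max_depth, params, rng, splitter, sink)
    node.right = _grow(values, indices[right], depth + 1, max_depth, params, rng, splitter, sink)
    return node


def build_tree(values: np.ndarray, depth: int, params: KadaifParams,
               rng: np.random.Generator, method: str = "kadaif") -> TreeNode:
    """Grow a (sub)tree on the given samples starting at ``depth``.

    Stops at a leaf when ``depth >= max_depth`` or the node holds at most
    ``r`` samples; degenerate splits (empty side or constant projection)
    are retried with fresh feature subsets before terminating.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 1:
        raise ValueError("build_tree requires a non-empty samples x features matrix")
    max_depth = params.max_depth if params.max_depth is not None else values.shape[0]
    sink: list = []
    return _grow(values, np.arange(values.shape[0]), depth, max_depth, params, rng,
                 _SPLITTERS[method], sink)


def _build_one_tree(values, params, seed_seq, method) -> IsolationTree:
    rng = np.random.Generator(np.random.PCG64(seed_seq))
    n = values.shape[0]
    max_depth = params.max_depth if params.max_depth is not None else n
    sink: list = []
    root = _grow(values, np.arange(n), 0, max_depth, params, rng, _SPLITTERS[method], sink)
    paths = np.zeros(n)
    for members, depth in sink:
        paths[members] = depth + average_path_length(members.size)
    return IsolationTree(root=root, n_train=n, path_lengths=paths)


def _as_table(X) -> FeatureTable:
    if isinstance(X, FeatureTable):
        return X
    X = np.asarray(X, dtype=float)
    return FeatureTable(
        [f"S{i}" for i in range(X.shape[0])],
        [f"F{j}" for j in range(X.shape[1])],
        X,
    )


def _fit(X, params: KadaifParams, method: str) -> KadaifForest:
    table = _as_table(X)
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples to build a forest")
    if table.n_features < 1:
        raise ValueError("need at least 1 feature")
    children = np.random.SeedSequence(params.seed).spawn(params.t)
    values = table.values
    if params.n_jobs != 1:
        trees = Parallel(n_jobs=params.n_jobs)(
            delayed(_build_one_tree)(values, params, ss, method) for ss in children
        )
    else:
        trees = [_build_one_tree(values, params, ss, method) for ss in children]
    return KadaifForest(
        trees=list(trees),
        n=table.n_samples,
        params=params,
        c_n=average_path_length(table.n_samples),
        method=method,
        sample_ids=list(table.sample_ids),
    )


def build_forest(X, params: KadaifParams | None = None) -> KadaifForest:
    """Fit a KADAIF forest of ``params.t`` trees on the full sample set."""
    return _fit(X, params or KadaifParams(), "kadaif")


def build_baseline_forest(X, params: KadaifParams | None = None) -> KadaifForest:
    """Fit the single-feature isolation-forest baseline with the same machinery."""
    return _fit(X, params or KadaifParams(), "baseline_if")


def isolation_depth(tree: IsolationTree, sample_index: int) -> float:
    """Path length of a training sample: leaf depth + c(leaf size)."""
    return float(tree.path_lengths[sample_index])


def _traverse_depth(node: TreeNode, row: np.ndarray, renorm: bool) -> float:
    while not node.is_leaf:
        sub = row[node.feature_indices]
        if node.artifact is None:  # baseline: single raw feature
            value = sub[0]
        else:
            if renorm:
                s = sub.sum()
                sub = sub / s if s > 0 else sub
            value = node.artifact.project(sub[None, :])[0, node.component_index]
        node = node.left if value <= node.threshold else node.right
    return node.depth + average_path_length(node.size)


def score_samples(X, params: KadaifParams | None = None, method: str = "kadaif",
                  threshold: float | None = None) -> AnomalyScoreReport:
    """Fit a forest and report per-sample mean depths, scores and flags."""
    if method not in _SPLITTERS:
        raise ValueError(f"unknown method {method!r}")
    forest = _fit(X, params or KadaifParams(), method)
    return forest.report(threshold)


def baseline_isolation_forest(X, params: KadaifParams | None = None,
                              threshold: float | None = None) -> AnomalyScoreReport:
    """Score with the classic single-feature isolation forest."""
    return score_samples(X, params, method="baseline_if", threshold=threshold)
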