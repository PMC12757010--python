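"""Per-node splitting machinery: feature subsampling, renormalization,
Bray-Curtis distances, PCoA/PCA ordination, component selection and
threshold partitioning.

These primitives run inside every internal node of every isolation tree,
so they are written lean (plain numpy, no intermediate containers). The
conventions for degenerate inputs matter:

* all-zero rows stay all-zero after renormalization;
* Bray-Curtis between two all-zero rows is 0 (indistinguishable), and
  between an all-zero and a non-zero row is 1;
* PCoA axes with non-positive eigenvalues are discarded (Bray-Curtis is
  non-Euclidean), and explained variance is computed over the positive
  eigenvalues only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReducerArtifact",
    "subsample_features",
    "renormalize",
    "bray_curtis_matrix",
    "pcoa",
    "pca_reduce",
    "select_component",
    "draw_threshold_and_split",
]

# eigenvalues / singular values below this (relative) level count as zero
_EIG_TOL = 1e-10


@dataclass
class ReducerArtifact:
    """Result of a node-level dimensionality reduction.

    For ``pcoa_braycurtis`` the artifact holds the node's sample embedding
    (coordinates); there is no out-of-sample projection. For ``pca`` it
    holds the feature means and loadings so new samples can be projected
    onto the same axes.
    """

    mode: str  # "pcoa_braycurtis" | "pca"
    coordinates: np.ndarray = field(repr=False)  # samples x k
    explained: np.ndarray = field(repr=False)  # k fractions, sum to 1
    means: np.ndarray | None = field(default=None, repr=False)  # pca only, (psi,)
    loadings: np.ndarray | None = field(default=None, repr=False)  # pca only, (psi, k)

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def project(self, rows: np.ndarray) -> np.ndarray:
        """Project new rows (n x psi, already subset) onto the retained axes."""
        if self.mode != "pca":
            raise NotImplementedError("out-of-sample projection requires pca mode")
        return (np.asarray(rows, dtype=float) - self.means) @ self.loadings


def subsample_features(n_features: int, params, rng: np.random.Generator) -> np.ndarray:
    """Draw the node's feature-index multiset.

    Draws ``psi = max(psi_min, round(psi_fraction * F))`` indices uniformly,
    with replacement by default (duplicates are kept: they re-weight the
    duplicated taxon in the node's distances). Without replacement psi is
    capped at F.
    """
    if n_features < 1:
        raise ValueError("need at least one feature")
    psi = max(params.psi_min, round(params.psi_fraction * n_features))
    if params.with_replacement:
        return rng.integers(0, n_features, size=psi)
    psi = min(psi, n_features)
    return rng.choice(n_features, size=psi, replace=False)


def renormalize(values: np.ndarray) -> np.ndarray:
    """Row-normalize a non-negative subset to relative abundances.

    Rows with positive sum are divided by their sum; all-zero rows are
    left all-zero. Idempotent and scale-invariant per row.
    """
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("negative entries in abundance subset")
    sums = values.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sums > 0, values / sums, 0.0)


def bray_curtis_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity, D[u,v] = 1 - 2*sum(min)/(sum_u+sum_v).

    Vectorized over the full matrix; fine for node-sized inputs. Two
    all-zero rows get distance 0; an all-zero vs a non-zero row gets 1.
    """
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("negative entries in abundance subset")
    sums = values.sum(axis=1)
    shared = np.minimum(values[:, None, :], values[None, :, :]).sum(axis=-1)
    denom = sums[:, None] + sums[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, 1.0 - 2.0 * shared / denom, 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def _sign_fix(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude loading positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def pcoa(distances: np.ndarray, n_axes: int, validate: bool = True) -> ReducerArtifact:
    """Principal Coordinates Analysis via Gower double-centering.

    B = -1/2 * J D^2 J with J the centering matrix; coordinates are the
    eigenvectors of B scaled by sqrt of the positive eigenvalues. At most
    ``min(n_axes, positive eigenvalues, n-1)`` axes are retained, sorted
    by decreasing eigenvalue; explained-variance fractions are relative
    to the sum of positive eigenvalues.
    """
    d = np.asarray(distances, dtype=float)
    if validate:
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if (d < 0).any():
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(d, d.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    d2 = d * d
    row = d2.mean(axis=1)
    b = -0.5 * (d2 - row[:, None] - row[None, :] + row.mean())
    eigvals, eigvecs = np.linalg.eigh(b)  # ascending
    eigvals = eigvals[::-1]
    eigvecs = eigvecs[:, ::-1]
    tol = _EIG_TOL * max(1.0, abs(eigvals[0]) if n else 1.0)
    pos = eigvals > tol
    eigvals = eigvals[pos]
    eigvecs = eigvecs[:, pos]
    k = min(n_axes, eigvals.size, max(n - 1, 0))
    total = eigvals.sum()
    explained = eigvals[:k] / total if total > 0 else np.zeros(0)
    coords = _sign_fix(eigvecs[:, :k]) * np.sqrt(eigvals[:k])
    return ReducerArtifact(mode="pcoa_braycurtis", coordinates=coords, explained=explained)


def pca_reduce(values: np.ndarray, n_axes: int) -> ReducerArtifact:
    """PCA of a node subset: per-feature mean-centering + SVD.

    Stores means and loadings so any new sample restricted to the same
    feature multiset can be projected onto the node's axes.
    """
    x = np.asarray(values, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("pca requires at least 2 samples")
    means = x.mean(axis=0)
    centered = x - means
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = _EIG_TOL * max(1.0, s[0] if s.size else 1.0)
    pos = s > tol
    s = s[pos]
    u = u[:, pos]
    vt = vt[pos]
    k = min(n_axes, s.size, x.shape[0] - 1)
    s, u, vt = s[:k], u[:, :k], vt[:k]
    # sign convention applied to loadings, propagated to scores
    lt = vt.T
    idx = np.argmax(np.abs(lt), axis=0) if lt.size else np.zeros(0, dtype=int)
    signs = np.sign(lt[idx, np.arange(lt.shape[1])]) if lt.size else np.ones(0)
    signs[signs == 0] = 1.0
    loadings = lt * signs
    coords = u * s * signs
    var = s**2
    explained = var / var.sum() if var.size and var.sum() > 0 else np.zeros(0)
    return ReducerArtifact(
        mode="pca", coordinates=coords, explained=explained, means=means, loadings=loadings
    )


def select_component(artifact: ReducerArtifact, mode: str, rng: np.random.Generator,
                     max_candidates: int = 20) -> int | None:
    """Choose the ordination axis used to split a node.

    ``variance_weighted`` draws from the first ``min(max_candidates,
    available)`` axes with probability proportional to explained
    variance; ``uniform`` is equiprobable over the same prefix; ``first``
    always returns axis 0. Returns None (degenerate-split signal) when
    the artifact retains no axes.
    """
    k = artifact.n_axes
    if k == 0:
        return None
    m = min(max_candidates, k)
    if mode == "first":
        return 0
    if mode == "uniform":
        return int(rng.integers(0, m))
    if mode == "variance_weighted":
        w = np.asarray(artifact.explained[:m], dtype=float)
        cum = np.cumsum(w)
        if cum[-1] <= 0:
            return None
        # inverse-CDF draw (faster than rng.choice for tiny prefixes)
        return int(np.searchsorted(cum, rng.random() * cum[-1], side="right").clip(0, m - 1))
    raise ValueError(f"unknown pc_selection mode {mode!r}")


def draw_threshold_and_split(projection: np.ndarray, rng: np.random.Generator):
    """Draw T ~ U(min, max) of the projection and partition by P <= T.

    Returns ``(T, left_indices, right_indices)`` or ``None`` when the
    split is degenerate (constant projection, or one side empty because
    T landed exactly on the maximum).
    """
    p = np.asarray(projection, dtype=float)
    if p.size < 2:
        raise ValueError("need at least 2 samples to split")
    lo, hi = p.min(), p.max()
    if lo == hi:
        return None
    t = rng.uniform(lo, hi)
    mask = p <= t
    left = np.flatnonzero(mask)
    right = np.flatnonzero(~mask)
    if left.size == 0 or right.size == 0:
        return None
    return t, left, right
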