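"""Node splitting machinery: subsampling, renormalization, Bray-Curtis,
PCoA/PCA, axis selection and threshold partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import chisquare

from kadaif import (
    KadaifParams,
    bray_curtis_matrix,
    draw_threshold_and_split,
    pca_reduce,
    pcoa,
    renormalize,
    select_component,
    subsample_features,
)
from kadaif.ordination import ReducerArtifact


# ---------------------------------------------------------------- subsampling
@pytest.mark.parametrize(
    "n_features, expected_psi",
    [(1000, 10), (500, 10), (3000, 30), (10, 10), (5, 10)],
)
def test_subsample_size_one_percent_with_floor(n_features, expected_psi, rng):
    idx = subsample_features(n_features, KadaifParams(), rng)
    assert len(idx) == expected_psi
    assert idx.min() >= 0 and idx.max() < n_features


def test_subsample_without_replacement_caps_at_feature_count(rng):
    params = KadaifParams(with_replacement=False)
    idx = subsample_features(5, params, rng)
    assert len(idx) == 5
    assert len(set(idx.tolist())) == 5


def test_subsample_with_replacement_allows_duplicates(rng):
    params = KadaifParams(psi_min=50)
    idx = subsample_features(10, params, rng)
    assert len(idx) == 50  # duplicates kept as separate columns


# -------------------------------------------------------------- renormalize
def test_renormalize_rows_and_zero_convention():
    out = renormalize(np.array([[2.0, 3.0, 5.0], [0.0, 0.0, 0.0]]))
    assert np.allclose(out[0], [0.2, 0.3, 0.5], atol=1e-12)
    assert np.all(out[1] == 0.0)


def test_renormalize_rejects_negative():
    with pytest.raises(ValueError):
        renormalize(np.array([[1.0, -0.5]]))


@given(
    row=st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=8),
    scale=st.floats(min_value=1e-6, max_value=1e6),
)
@settings(max_examples=100, deadline=None)
def test_renormalize_idempotent_and_scale_invariant(row, scale):
    row = np.array([row])
    once = renormalize(row)
    assert np.allclose(renormalize(once), once, atol=1e-12)
    assert np.allclose(renormalize(row * scale), once, atol=1e-9)
    if row.sum() > 0:
        assert once.sum() == pytest.approx(1.0, abs=1e-12)


# -------------------------------------------------------------- Bray-Curtis
@pytest.mark.parametrize(
    "u, v, expected",
    [
        ([1.0, 0.0], [0.0, 1.0], 1.0),
        ([0.3, 0.7], [0.3, 0.7], 0.0),
        ([0.5, 0.5], [0.25, 0.75], 0.25),
    ],
)
def test_bray_curtis_pairs(u, v, expected):
    d = bray_curtis_matrix(np.array([u, v]))
    assert d[0, 1] == pytest.approx(expected, abs=1e-12)
    assert d[1, 0] == d[0, 1]
    assert d[0, 0] == 0.0


def test_bray_curtis_zero_row_conventions():
    d = bray_curtis_matrix(np.array([[0.0, 0.0], [0.0, 0.0], [0.2, 0.8]]))
    assert d[0, 1] == 0.0  # two empty profiles are indistinguishable
    assert d[0, 2] == 1.0  # empty vs non-empty share nothing


def test_bray_curtis_matches_double_loop_and_scipy(rng):
    for _ in range(50):
        x = rng.gamma(0.5, size=(10, 8))
        x[rng.random((10, 8)) < 0.3] = 0.0
        d = bray_curtis_matrix(x)
        for u in range(10):
            for v in range(10):
                num = 2.0 * np.minimum(x[u], x[v]).sum()
                den = x[u].sum() + x[v].sum()
                oracle = 1.0 - num / den if den > 0 else 0.0
                assert d[u, v] == pytest.approx(oracle, abs=1e-12)
                if x[u].sum() > 0 and x[v].sum() > 0 and u != v:
                    assert d[u, v] == pytest.approx(
                        scipy_braycurtis(x[u], x[v]), abs=1e-12
                    )


# ---------------------------------------------------------------------- PCoA
def _pairwise(coords):
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def test_pcoa_reconstructs_euclidean_distances(rng):
    for _ in range(20):
        pts = rng.normal(size=(12, 4))
        d = _pairwise(pts)
        art = pcoa(d, n_axes=12)
        assert np.allclose(_pairwise(art.coordinates), d, atol=1e-9)
        assert np.all(np.diff(art.explained) <= 1e-12)  # non-increasing
        assert art.explained.sum() == pytest.approx(1.0, abs=1e-9)


def test_pcoa_collinear_points_give_single_axis():
    pts = np.array([[0.0], [1.0], [3.0]])
    d = _pairwise(pts)
    art = pcoa(d, n_axes=5)
    assert art.n_axes == 1
    assert np.allclose(_pairwise(art.coordinates), d, atol=1e-9)


def test_pcoa_identical_samples_degenerate():
    art = pcoa(np.zeros((4, 4)), n_axes=3)
    assert art.n_axes == 0


def test_pcoa_rejects_bad_matrices():
    with pytest.raises(ValueError):
        pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]), n_axes=2)  # asymmetric
    with pytest.raises(ValueError):
        pcoa(np.array([[0.0, -1.0], [-1.0, 0.0]]), n_axes=2)  # negative


def test_pcoa_agrees_with_skbio_on_braycurtis(rng):
    skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
    DistanceMatrix = pytest.importorskip("skbio").DistanceMatrix

    x = rng.dirichlet(np.full(12, 0.5), size=9)
    d = bray_curtis_matrix(x)
    ours = pcoa(d, n_axes=8)
    ref = skbio_pcoa(DistanceMatrix(d), number_of_dimensions=0)
    ref_eigs = np.asarray(ref.eigvals)
    ref_eigs = ref_eigs[ref_eigs > 1e-8]
    ours_eigs = (ours.coordinates**2).sum(axis=0)  # eigenvalues of the centered matrix
    assert np.allclose(np.sort(ours_eigs)[::-1], np.sort(ref_eigs)[::-1], atol=1e-8)
    ref_coords = np.asarray(ref.samples)[:, : ours.n_axes]
    assert np.allclose(_pairwise(ours.coordinates), _pairwise(ref_coords), atol=1e-6)


# ----------------------------------------------------------------------- PCA
def test_pca_rank_one_data_explains_everything(rng):
    direction = rng.normal(size=5)
    x = np.outer(rng.normal(size=20), direction) + 3.0
    art = pca_reduce(x, n_axes=5)
    assert art.explained[0] == pytest.approx(1.0, abs=1e-9)


def test_pca_projection_roundtrip(rng):
    x = rng.gamma(1.0, size=(15, 6))
    art = pca_reduce(x, n_axes=6)
    assert np.allclose(art.project(x), art.coordinates, atol=1e-9)


def test_pca_isotropic_cloud_splits_variance(rng):
    x = rng.normal(size=(10_000, 2))
    art = pca_reduce(x, n_axes=2)
    assert art.explained[0] == pytest.approx(0.5, abs=0.1)
    assert art.explained[1] == pytest.approx(0.5, abs=0.1)


def test_pca_requires_two_samples():
    with pytest.raises(ValueError):
        pca_reduce(np.ones((1, 4)), n_axes=2)


# ----------------------------------------------------------- axis selection
def _artifact(explained):
    explained = np.asarray(explained, dtype=float)
    coords = np.zeros((3, explained.size))
    return ReducerArtifact(mode="pcoa_braycurtis", coordinates=coords, explained=explained)


def test_select_component_forced_cases(rng):
    single = _artifact([1.0])
    for mode in ("variance_weighted", "uniform", "first"):
        assert select_component(single, mode, rng) == 0
    assert select_component(_artifact([0.5, 0.3, 0.2]), "first", rng) == 0
    empty = _artifact(np.zeros(0)).explained
    art = ReducerArtifact(mode="pcoa_braycurtis", coordinates=np.zeros((3, 0)), explained=empty)
    assert select_component(art, "variance_weighted", rng) is None


def test_select_component_variance_weighted_frequencies(rng):
    art = _artifact([0.8, 0.2])
    draws = np.array([select_component(art, "variance_weighted", rng) for _ in range(10_000)])
    freq0 = np.mean(draws == 0)
    assert freq0 == pytest.approx(0.8, abs=0.03)
    counts = np.bincount(draws, minlength=2)
    assert chisquare(counts, f_exp=[8000, 2000]).pvalue > 0.01


def test_select_component_uniform_over_prefix(rng):
    art = _artifact([0.9, 0.06, 0.04])
    draws = np.array([select_component(art, "uniform", rng) for _ in range(9000)])
    counts = np.bincount(draws, minlength=3)
    assert chisquare(counts).pvalue > 0.01


def test_select_component_prefix_capped_at_20(rng):
    art = _artifact(np.full(30, 1 / 30))
    draws = {select_component(art, "variance_weighted", rng) for _ in range(2000)}
    assert max(draws) <= 19


# ------------------------------------------------------------- partitioning
def test_split_two_points_always_separates(rng):
    res = draw_threshold_and_split(np.array([0.0, 10.0]), rng)
    t, left, right = res
    assert 0.0 <= t <= 10.0
    assert set(left.tolist()) | set(right.tolist()) == {0, 1}


def test_split_constant_projection_degenerate(rng):
    assert draw_threshold_and_split(np.full(5, 3.3), rng) is None


def test_split_exhaustive_and_exclusive(rng):
    for _ in range(200):
        p = rng.normal(size=rng.integers(2, 30))
        res = draw_threshold_and_split(p, rng)
        if res is None:
            continue
        t, left, right = res
        assert np.all(p[left] <= t) and np.all(p[right] > t)
        merged = np.sort(np.concatenate([left, right]))
        assert np.array_equal(merged, np.arange(p.size))


def test_split_requires_two_samples(rng):
    with pytest.raises(ValueError):
        draw_threshold_and_split(np.array([1.0]), rng)
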