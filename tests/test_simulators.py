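"""Synthetic community generator and the three anomaly-injection scenarios."""

import numpy as np
import pytest

from kadaif import (
    CommunitySpec,
    bray_curtis_matrix,
    build_contamination_pool,
    build_inflation_pool,
    build_mislabeling_pool,
    community_preset,
    contaminate_mixture,
    generate_communities,
    generate_dysbiosis_series,
    inflate_taxa,
)


# ---------------------------------------------------------------- generator
def test_generated_profiles_are_compositional():
    spec = CommunitySpec(n_taxa=50, seed=1)
    normal, anomalous = generate_communities(spec, 30, 10)
    assert np.allclose(normal.values.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(anomalous.values.sum(axis=1), 1.0, atol=1e-9)
    assert (normal.values >= 0).all() and (anomalous.values >= 0).all()


def test_generator_is_seed_deterministic():
    spec = CommunitySpec(n_taxa=40, seed=9)
    a1, b1 = generate_communities(spec, 10, 5)
    a2, b2 = generate_communities(spec, 10, 5)
    assert np.array_equal(a1.values, a2.values)
    assert np.array_equal(b1.values, b2.values)


def test_zero_sparsity_leaves_no_zeros():
    spec = CommunitySpec(n_taxa=30, sparsity=0.0, seed=2)
    normal, _ = generate_communities(spec, 20, 0)
    assert (normal.values > 0).all()


def test_identical_settings_give_same_group_distribution():
    """With no shift/dispersion the two groups are exchangeable draws
    (permutation test on the two-sample energy statistic)."""
    spec = CommunitySpec(n_taxa=60, anomaly_shift=1.0, anomaly_dispersion=1.0, seed=3)
    normal, anomalous = generate_communities(spec, 100, 100)
    x = np.vstack([normal.values, anomalous.values])
    d = bray_curtis_matrix(x)
    n = 100

    def energy(groups):
        a = np.flatnonzero(groups == 0)
        b = np.flatnonzero(groups == 1)
        between = d[np.ix_(a, b)].mean()
        within = 0.5 * (d[np.ix_(a, a)].mean() + d[np.ix_(b, b)].mean())
        return 2 * between - 2 * within

    labels = np.repeat([0, 1], n)
    observed = energy(labels)
    rng = np.random.default_rng(0)
    null = np.array([energy(rng.permutation(labels)) for _ in range(199)])
    p = (1 + np.sum(null >= observed)) / 200
    assert p > 0.01


def test_dispersion_inflates_within_group_spread():
    spec = CommunitySpec(n_taxa=60, sample_log_sd=0.4, sparsity=0.3,
                         anomaly_dispersion=3.0, seed=4)
    normal, anomalous = generate_communities(spec, 100, 100)
    within_normal = bray_curtis_matrix(normal.values)
    within_anom = bray_curtis_matrix(anomalous.values)
    iu = np.triu_indices(100, k=1)
    assert within_anom[iu].mean() > within_normal[iu].mean()


def test_disjoint_support_groups_share_no_taxa():
    spec = CommunitySpec(n_taxa=100, anomaly_support_fraction=0.2, seed=5)
    normal, anomalous = generate_communities(spec, 20, 20)
    normal_taxa = normal.values.sum(axis=0) > 0
    anom_taxa = anomalous.values.sum(axis=0) > 0
    assert not np.any(normal_taxa & anom_taxa)


def test_spec_validation():
    with pytest.raises(ValueError):
        CommunitySpec(sparsity=1.0)
    with pytest.raises(ValueError):
        CommunitySpec(anomaly_dispersion=0.5)
    with pytest.raises(ValueError):
        community_preset("nope")


# -------------------------------------------------------------- mislabeling
@pytest.mark.parametrize("fraction, expected", [(0.02, 1), (0.1, 5), (0.5, 25)])
def test_mislabeling_pool_counts(community_pair, fraction, expected, rng):
    normal, anomalous = community_pair
    pool = build_mislabeling_pool(normal, anomalous, fraction, 50, rng)
    assert pool.table.n_samples == 50
    assert pool.n_anomalous == expected
    assert len(pool.labels) == 50


def test_mislabeling_pool_requires_enough_sources(community_pair, rng):
    normal, anomalous = community_pair
    with pytest.raises(ValueError):
        build_mislabeling_pool(normal, anomalous, 0.5, 500, rng)


def test_mislabeling_pool_rows_come_from_sources(community_pair, rng):
    normal, anomalous = community_pair
    pool = build_mislabeling_pool(normal, anomalous, 0.1, 30, rng)
    source = {row.tobytes(): lab for rows, lab in
              ((normal.values, 0), (anomalous.values, 1)) for row in rows}
    for row, label in zip(pool.table.values, pool.labels):
        assert source[row.tobytes()] == label


# ------------------------------------------------------------ contamination
@pytest.mark.parametrize(
    "normal, anomalous, p, expected",
    [
        ([1.0, 0.0], [0.0, 1.0], 0.3, [0.7, 0.3]),
        ([0.6, 0.4], [0.1, 0.9], 0.0, [0.6, 0.4]),
        ([0.6, 0.4], [0.1, 0.9], 1.0, [0.1, 0.9]),
    ],
)
def test_contaminate_mixture_formula(normal, anomalous, p, expected):
    out = contaminate_mixture(np.array(normal), np.array(anomalous), p)
    assert np.allclose(out, expected, atol=1e-12)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


def test_contaminate_mixture_is_invertible():
    rng = np.random.default_rng(1)
    normal = rng.dirichlet(np.ones(10))
    anomalous = rng.dirichlet(np.ones(10))
    p = 0.35
    mixed = contaminate_mixture(normal, anomalous, p)
    recovered = (mixed - p * anomalous) / (1 - p)
    assert np.allclose(recovered, normal, atol=1e-12)


def test_contaminate_mixture_rejects_bad_level():
    with pytest.raises(ValueError):
        contaminate_mixture(np.array([1.0]), np.array([1.0]), 1.5)


@pytest.mark.parametrize("fraction, expected", [(0.04, 2), (0.1, 5), (0.3, 15)])
def test_contamination_pool_counts(community_pair, fraction, expected, rng):
    normal, anomalous = community_pair
    pool = build_contamination_pool(normal, anomalous, fraction, p=0.3,
                                    pool_size=50, rng=rng)
    assert pool.n_anomalous == expected
    assert pool.level == 0.3
    # uncontaminated members are untouched normal rows
    source = {row.tobytes() for row in normal.values}
    for row, label in zip(pool.table.values, pool.labels):
        if label == 0:
            assert row.tobytes() in source


# ---------------------------------------------------------------- inflation
@pytest.mark.parametrize("n_taxa, expected_m", [(1000, 10), (100, 5)])
def test_inflate_taxa_counts(n_taxa, expected_m, rng):
    profile = np.full(n_taxa, 1.0 / n_taxa)
    out = inflate_taxa(profile, factor=10.0, rng=rng)
    assert np.sum(~np.isclose(out, out.min())) == expected_m
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


def test_inflate_factor_one_is_identity(rng):
    profile = np.random.default_rng(0).dirichlet(np.ones(50))
    out = inflate_taxa(profile, factor=1.0, rng=rng)
    assert np.allclose(out, profile, atol=1e-12)


def test_inflate_rejects_deflation(rng):
    with pytest.raises(ValueError):
        inflate_taxa(np.ones(10) / 10, factor=0.5, rng=rng)


def test_inflation_pool_counts(community_pair, rng):
    normal, _ = community_pair
    pool = build_inflation_pool(normal, 0.1, factor=20.0, pool_size=40, rng=rng)
    assert pool.n_anomalous == 4
    assert np.allclose(pool.table.values.sum(axis=1), 1.0, atol=1e-9)


# -------------------------------------------------------------- time series
def test_dysbiosis_series_marks_shift_segment():
    spec = community_preset("even", seed=0, anomaly_dispersion=2.0)
    series, inside = generate_dysbiosis_series(spec, n_days=100, cadence=2,
                                               shift_start=40, shift_end=50)
    days = series.times
    assert np.array_equal(inside, (days >= 40) & (days <= 50))
    assert np.allclose(series.table.values.sum(axis=1), 1.0, atol=1e-9)
    assert len(series) == 50
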