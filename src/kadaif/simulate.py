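"""Synthetic compositional communities and anomaly-injection scenarios.

The generator emulates the properties of real taxon-abundance tables
that matter for anomaly detection — sparsity, compositionality, heavy
rank-abundance tails — with a zero-inflated log-normal model. Each
community draws a fixed per-taxon baseline log-abundance (the shared
community structure); each sample adds log-normal noise around that
baseline, zeroes each taxon with the sparsity probability, and is then
renormalized to relative abundances.

Anomalous samples come from the same generator with three optional
departures: a multiplicative shift on a fixed random taxon subset, a
variance inflation of the sample-level noise (the "Anna Karenina"
pattern — perturbed communities vary in many directions), and/or a
restriction of their support to a dedicated taxon subset disjoint from
the taxa the normal group uses.

Three injection scenarios produce labeled pools of (by default) 50
samples each:

* mislabeling — a few samples from the anomalous population slipped
  into an otherwise normal pool;
* mixture contamination — normal profiles blended with an anomalous
  profile at contamination level p: (1-p)*normal + p*anomalous;
* taxon inflation — a small random set of a sample's own taxa
  multiplied by a contamination factor and renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .table import FeatureTable

__all__ = [
    "CommunitySpec",
    "LabeledPool",
    "generate_communities",
    "build_mislabeling_pool",
    "contaminate_mixture",
    "build_contamination_pool",
    "inflate_taxa",
    "build_inflation_pool",
    "community_preset",
    "generate_dysbiosis_series",
]


def community_preset(name: str, seed: int = 0, **overrides) -> "CommunitySpec":
    """Named community configurations used by the benchmark scenarios.

    ``sparse`` — heavy-tailed, highly sparse gut-like community with a
    disjoint-support anomalous population (mislabeling experiments).
    ``tight`` — same rank-abundance curve but low between-sample noise,
    so contaminated profiles stand out (mixture-contamination
    experiments).
    ``even`` — small, even, low-noise community in which inflating a few
    taxa visibly distorts the composition (inflation experiments).
    """
    presets = {
        "sparse": dict(n_taxa=300, log_sd=2.0, sample_log_sd=0.7, sparsity=0.6,
                       anomaly_support_fraction=0.2),
        "tight": dict(n_taxa=300, log_sd=2.0, sample_log_sd=0.3, sparsity=0.3,
                      anomaly_support_fraction=0.2),
        "even": dict(n_taxa=100, log_sd=0.5, sample_log_sd=0.3, sparsity=0.2),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; options: {sorted(presets)}")
    kwargs = {**presets[name], "seed": seed, **overrides}
    return CommunitySpec(**kwargs)


@dataclass
class CommunitySpec:
    """Parameters of the zero-inflated log-normal community generator.

    n_taxa : community richness (feature count).
    log_mean, log_sd : location and spread of the per-taxon baseline
        log-abundances (log_sd = 2 gives the heavy-tailed rank-abundance
        curve typical of genus-level gut profiles).
    sample_log_sd : sd of the per-sample log-normal noise around the
        baseline (between-sample variability within a group).
    sparsity : probability a taxon is zeroed in a sample.
    anomaly_taxa_fraction : fraction of taxa receiving the multiplicative
        shift in the anomalous group (one fixed subset per community).
    anomaly_shift : multiplicative effect on that subset (1 = none).
    anomaly_dispersion : factor (>= 1) multiplying sample_log_sd in the
        anomalous group; > 1 emulates the elevated within-group
        variability of perturbed communities.
    anomaly_support_fraction : when set, anomalous samples live on a
        dedicated random subset of this fraction of taxa, disjoint from
        the taxa available to the normal group (a strong compositional
        shift).
    seed : generator seed used when no rng is passed explicitly.
    """

    n_taxa: int = 300
    log_mean: float = 0.0
    log_sd: float = 2.0
    sample_log_sd: float = 0.7
    sparsity: float = 0.6
    anomaly_taxa_fraction: float = 0.2
    anomaly_shift: float = 1.0
    anomaly_dispersion: float = 1.0
    anomaly_support_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must be in [0, 1)")
        if self.anomaly_dispersion < 1:
            raise ValueError("anomaly_dispersion must be >= 1")
        if not 0 < self.anomaly_taxa_fraction <= 1:
            raise ValueError("anomaly_taxa_fraction must be in (0, 1]")
        if self.anomaly_support_fraction is not None and not (
            0 < self.anomaly_support_fraction < 1
        ):
            raise ValueError("anomaly_support_fraction must be in (0, 1)")


@dataclass
class LabeledPool:
    """A simulated pool with ground-truth labels (1 = anomalous)."""

    table: FeatureTable
    labels: np.ndarray
    scenario: str
    fraction: float
    level: float | None = None  # contamination level p or inflation factor

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != self.table.n_samples:
            raise ValueError("labels must align with table rows")

    @property
    def n_anomalous(self) -> int:
        return int(self.labels.sum())


def _round_count(fraction: float, pool_size: int) -> int:
    # round-half-up with a floor of one anomalous sample
    return max(1, int(np.floor(fraction * pool_size + 0.5)))


def _draw_samples(baseline, log_sd, sparsity, n, rng, support=None):
    n_taxa = baseline.size
    x = np.exp(baseline + log_sd * rng.standard_normal((n, n_taxa)))
    x[rng.random((n, n_taxa)) < sparsity] = 0.0
    if support is not None:
        mask = np.zeros(n_taxa, dtype=bool)
        mask[support] = True
        x[:, ~mask] = 0.0
        # a sample must keep at least one taxon; resurrect the largest draw
        dead = x.sum(axis=1) == 0
        if dead.any():
            x[np.ix_(dead, mask)] = np.exp(
                baseline[mask] + log_sd * rng.standard_normal((int(dead.sum()), int(mask.sum())))
            )
    sums = x.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return x / sums


def generate_communities(
    spec: CommunitySpec,
    n_normal: int,
    n_anomalous: int,
    rng: np.random.Generator | None = None,
) -> tuple[FeatureTable, FeatureTable]:
    """Draw a normal and an anomalous sample group from one community.

    Both groups share the community's per-taxon baseline; the anomalous
    group applies the spec's shift/dispersion/support departures. All
    rows are compositional (sum to 1).
    """
    if n_normal < 0 or n_anomalous < 0:
        raise ValueError("group sizes must be non-negative")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    baseline = spec.log_mean + spec.log_sd * rng.standard_normal(spec.n_taxa)

    n_shift = max(1, round(spec.anomaly_taxa_fraction * spec.n_taxa))
    shift_taxa = rng.choice(spec.n_taxa, size=n_shift, replace=False)

    normal_support = None
    anomalous_support = None
    if spec.anomaly_support_fraction is not None:
        n_anom_taxa = max(1, round(spec.anomaly_support_fraction * spec.n_taxa))
        perm = rng.permutation(spec.n_taxa)
        anomalous_support = perm[:n_anom_taxa]
        normal_support = perm[n_anom_taxa:]

    normal = _draw_samples(
        baseline, spec.sample_log_sd, spec.sparsity, n_normal, rng, normal_support
    )

    anom_baseline = baseline.copy()
    anom_baseline[shift_taxa] += np.log(spec.anomaly_shift)
    anomalous = _draw_samples(
        anom_baseline,
        spec.sample_log_sd * spec.anomaly_dispersion,
        spec.sparsity,
        n_anomalous,
        rng,
        anomalous_support,
    )

    taxa = [f"taxon_{j}" for j in range(spec.n_taxa)]
    normal_table = FeatureTable([f"normal_{i}" for i in range(n_normal)], taxa, normal)
    anomalous_table = FeatureTable([f"anomalous_{i}" for i in range(n_anomalous)], taxa, anomalous)
    return normal_table, anomalous_table


def build_mislabeling_pool(
    normal: FeatureTable,
    anomalous: FeatureTable,
    fraction: float,
    pool_size: int = 50,
    rng: np.random.Generator | None = None,
) -> LabeledPool:
    """Pool of pool_size samples with round(fraction * pool_size) mislabeled.

    Anomalous members are drawn without replacement from the anomalous
    source, the rest from the normal source; row order is shuffled.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    if not 0 < fraction <= 0.5:
        raise ValueError("anomaly fraction must be in (0, 0.5]")
    k = _round_count(fraction, pool_size)
    n_norm = pool_size - k
    if anomalous.n_samples < k or normal.n_samples < n_norm:
        raise ValueError(
            f"insufficient source samples: need {k} anomalous (have {anomalous.n_samples}) "
            f"and {n_norm} normal (have {normal.n_samples})"
        )
    anom_idx = rng.choice(anomalous.n_samples, size=k, replace=False)
    norm_idx = rng.choice(normal.n_samples, size=n_norm, replace=False)
    values = np.vstack([normal.values[norm_idx], anomalous.values[anom_idx]])
    labels = np.concatenate([np.zeros(n_norm, dtype=int), np.ones(k, dtype=int)])
    order = rng.permutation(pool_size)
    ids = [f"pool_{i}" for i in range(pool_size)]
    table = FeatureTable(ids, list(normal.feature_ids), values[order])
    return LabeledPool(table=table, labels=labels[order], scenario="mislabeling",
                       fraction=fraction)


def contaminate_mixture(normal_profile: np.ndarray, anomalous_profile: np.ndarray,
                        p: float) -> np.ndarray:
    """Blend profiles at contamination level p: (1-p)*normal + p*anomalous."""
    if not 0 <= p <= 1:
        raise ValueError(f"contamination level must be in [0, 1], got {p}")
    normal_profile = np.asarray(normal_profile, dtype=float)
    anomalous_profile = np.asarray(anomalous_profile, dtype=float)
    return (1.0 - p) * normal_profile + p * anomalous_profile


def build_contamination_pool(
    normal: FeatureTable,
    anomalous: FeatureTable,
    fraction: float,
    p: float,
    pool_size: int = 50,
    rng: np.random.Generator | None = None,
) -> LabeledPool:
    """Pool of normal samples with a few blended with anomalous profiles.

    Every pool member comes from the normal source; round(fraction *
    pool_size) of them are mixed, each with its own independently drawn
    anomalous partner, at contamination level p.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    if not 0 < fraction <= 0.5:
        raise ValueError("contaminated fraction must be in (0, 0.5]")
    k = _round_count(fraction, pool_size)
    if normal.n_samples < pool_size:
        raise ValueError(
            f"insufficient normal samples: need {pool_size}, have {normal.n_samples}"
        )
    if anomalous.n_samples < 1:
        raise ValueError("need at least one anomalous source sample")
    idx = rng.choice(normal.n_samples, size=pool_size, replace=False)
    values = normal.values[idx].copy()
    contaminated = rng.choice(pool_size, size=k, replace=False)
    partners = rng.integers(0, anomalous.n_samples, size=k)
    for slot, partner in zip(contaminated, partners):
        values[slot] = contaminate_mixture(values[slot], anomalous.values[partner], p)
    labels = np.zeros(pool_size, dtype=int)
    labels[contaminated] = 1
    ids = [f"pool_{i}" for i in range(pool_size)]
    table = FeatureTable(ids, list(normal.feature_ids), values)
    return LabeledPool(table=table, labels=labels, scenario="contamination_mixture",
                       fraction=fraction, level=p)


def inflate_taxa(
    profile: np.ndarray,
    taxa_fraction: float = 0.01,
    min_taxa: int = 5,
    factor: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Multiply a random ~1% of taxa (at least min_taxa) by ``factor``.

    The profile is renormalized afterwards so it stays compositional.
    """
    if factor < 1:
        raise ValueError(f"inflation factor must be >= 1, got {factor}")
    rng = np.random.default_rng(0) if rng is None else rng
    profile = np.asarray(profile, dtype=float).copy()
    n_taxa = profile.size
    m = min(n_taxa, max(min_taxa, round(taxa_fraction * n_taxa)))
    chosen = rng.choice(n_taxa, size=m, replace=False)
    profile[chosen] *= factor
    total = profile.sum()
    return profile / total if total > 0 else profile


def build_inflation_pool(
    normal: FeatureTable,
    fraction: float,
    factor: float,
    pool_size: int = 50,
    taxa_fraction: float = 0.01,
    min_taxa: int = 5,
    rng: np.random.Generator | None = None,
) -> LabeledPool:
    """Pool of normal samples with a few taxon-inflated members."""
    rng = np.random.default_rng(0) if rng is None else rng
    if not 0 < fraction <= 0.5:
        raise ValueError("inflated fraction must be in (0, 0.5]")
    k = _round_count(fraction, pool_size)
    if normal.n_samples < pool_size:
        raise ValueError(
            f"insufficient normal samples: need {pool_size}, have {normal.n_samples}"
        )
    idx = rng.choice(normal.n_samples, size=pool_size, replace=False)
    values = normal.values[idx].copy()
    inflated = rng.choice(pool_size, size=k, replace=False)
    for slot in inflated:
        values[slot] = inflate_taxa(values[slot], taxa_fraction, min_taxa, factor, rng)
    labels = np.zeros(pool_size, dtype=int)
    labels[inflated] = 1
    ids = [f"pool_{i}" for i in range(pool_size)]
    table = FeatureTable(ids, list(normal.feature_ids), values)
    return LabeledPool(table=table, labels=labels, scenario="contamination_inflation",
                       fraction=fraction, level=factor)


def generate_dysbiosis_series(
    spec: CommunitySpec,
    n_days: int = 200,
    cadence: int = 2,
    shift_start: float = 80,
    shift_end: float = 90,
    rng: np.random.Generator | None = None,
):
    """Daily-style time series with a dysbiotic (dispersion-inflated) segment.

    Samples are drawn every ``cadence`` days from one community; samples
    whose day falls in [shift_start, shift_end] use the spec's anomalous
    departures (dispersion inflation and/or shift), emulating a
    transient perturbation such as a diarrhea episode. Returns a
    TimedSeries plus the boolean in-segment mask.
    """
    from .longitudinal import TimedSeries

    rng = np.random.default_rng(spec.seed) if rng is None else rng
    days = np.arange(0, n_days, cadence, dtype=float)
    inside = (days >= shift_start) & (days <= shift_end)
    # one community: normal rows for outside days, anomalous rows inside
    normal, anomalous = generate_communities(spec, int((~inside).sum()), int(inside.sum()), rng)
    values = np.empty((days.size, spec.n_taxa))
    values[~inside] = normal.values
    values[inside] = anomalous.values
    table = FeatureTable([f"day_{int(d):03d}" for d in days], list(normal.feature_ids), values)
    return TimedSeries(table=table, times=days), inside
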