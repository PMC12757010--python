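"""Canonical simulation experiments bundled with the package.

Each function builds its synthetic study population from a named
community preset, runs the detector(s), and returns the headline
numbers. These are the package's reference study conditions:

* mislabeling — sparse heavy-tailed community whose anomalous population
  lives on a disjoint 20% taxon support; pools of 50 with 2% anomalies,
  50 repetitions, 2500 pooled scores per method.
* mixture contamination — low-noise ("tight") community; 4% of each
  50-sample pool contaminated at level p over a grid of p, 20
  repetitions per level.
* taxon inflation — small, even, low-noise community; 4% of each pool
  has ~1% of taxa (minimum five) multiplied by a contamination factor,
  20 repetitions per factor.
* sliding-window dysbiosis — a 200-day series sampled every other day
  with a dispersion-inflated day-80..90 segment, scored against the
  preceding 60 days; detection = the peak 7-sample rolling average
  falling within days 75-95.
"""

from __future__ import annotations

import numpy as np

from .evaluate import ExperimentConfig, run_experiment
from .forest import KadaifParams
from .longitudinal import rolling_average, sliding_window_score
from .simulate import community_preset, generate_communities, generate_dysbiosis_series

__all__ = [
    "mislabeling_experiment",
    "mixture_experiment",
    "inflation_experiment",
    "dysbiosis_window_experiment",
]


def _sources(preset: str, seed: int, n_normal: int = 250, n_anomalous: int = 60):
    spec = community_preset(preset, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(17,)))
    return generate_communities(spec, n_normal, n_anomalous, rng)


def mislabeling_experiment(seed: int = 0, repetitions: int = 50, trees: int = 100,
                           fraction: float = 0.02, pool_size: int = 50):
    """Rare-mislabeling benchmark; returns {method: pooled AUC}."""
    config = ExperimentConfig(
        scenario="mislabeling",
        methods=("kadaif", "baseline_if"),
        repetitions=repetitions,
        pool_size=pool_size,
        fractions=(fraction,),
        seed=seed,
        params=KadaifParams(t=trees),
    )
    results = run_experiment(config, sources=_sources("sparse", seed))
    return {r.method: r.auc for r in results}


def mixture_experiment(seed: int = 0, repetitions: int = 20, trees: int = 100,
                       levels: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9),
                       fraction: float = 0.04, pool_size: int = 50):
    """Mixture-contamination benchmark; returns {p: pooled KADAIF AUC}."""
    config = ExperimentConfig(
        scenario="contamination_mixture",
        methods=("kadaif",),
        repetitions=repetitions,
        pool_size=pool_size,
        fractions=(fraction,),
        levels=levels,
        seed=seed,
        params=KadaifParams(t=trees),
    )
    results = run_experiment(config, sources=_sources("tight", seed))
    return {r.level: r.auc for r in results}


def inflation_experiment(seed: int = 0, repetitions: int = 20, trees: int = 100,
                         factors: tuple[float, ...] = (1.0, 20.0),
                         fraction: float = 0.04, pool_size: int = 50):
    """Taxon-inflation benchmark; returns {factor: pooled KADAIF AUC}."""
    config = ExperimentConfig(
        scenario="contamination_inflation",
        methods=("kadaif",),
        repetitions=repetitions,
        pool_size=pool_size,
        fractions=(fraction,),
        levels=factors,
        seed=seed,
        params=KadaifParams(t=trees),
    )
    results = run_experiment(config, sources=_sources("even", seed))
    return {r.level: r.auc for r in results}


def dysbiosis_window_experiment(seed: int = 0, trees: int = 25, n_days: int = 200,
                                cadence: int = 2, shift: tuple[float, float] = (80, 90),
                                dispersion: float = 4.0, window_days: float = 60.0,
                                min_history: int = 20, rolling_k: int = 7):
    """One sliding-window run on a series with a planted dysbiotic segment.

    Returns (peak_day, hit) where hit means the maximum rolling-average
    score landed within 5 days of the planted segment.
    """
    spec = community_preset("even", seed=seed, anomaly_dispersion=dispersion)
    series, _ = generate_dysbiosis_series(
        spec, n_days=n_days, cadence=cadence, shift_start=shift[0], shift_end=shift[1],
        rng=np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(23,))),
    )
    frame = sliding_window_score(series, window_days=window_days, min_history=min_history,
                                 params=KadaifParams(t=trees), seed=seed)
    roll = rolling_average(frame["score"].to_numpy(), k=rolling_k)
    peak_day = float(frame["time"].to_numpy()[int(np.nanargmax(roll))])
    hit = shift[0] - 5 <= peak_day <= shift[1] + 5
    return peak_day, bool(hit)
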