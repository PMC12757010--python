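"""Benchmarking harness: repeated scenario x method experiments with
pooled ROC-AUC evaluation.

For each grid cell (anomaly fraction x contamination level/factor) the
harness builds `repetitions` independent labeled pools, scores every
pool with the chosen detector, pools all scores with their ground-truth
labels (repetitions x pool_size points — 2500 at the defaults) and
computes a single AUC on the pooled vector. Per-repetition AUCs are kept
as diagnostics only. Pool construction is seeded independently of the
scoring method, so two methods run with the same seed are compared on
identical pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .forest import KadaifParams, score_samples
from .simulate import (
    CommunitySpec,
    build_contamination_pool,
    build_inflation_pool,
    build_mislabeling_pool,
    generate_communities,
)
from .table import FeatureTable

__all__ = ["ExperimentConfig", "RocResult", "roc_auc", "run_experiment",
           "results_frame", "score_distribution_summary"]

_SCENARIOS = ("mislabeling", "contamination_mixture", "contamination_inflation")
_METHODS = ("kadaif", "baseline_if")


def roc_auc(scores, labels) -> float:
    """ROC AUC: P(random anomalous score > random normal score), ties 1/2.

    Labels are binary with 1 = anomalous; both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(labels, scores))


@dataclass
class ExperimentConfig:
    """One benchmarking run over a scenario/fraction/level grid."""

    scenario: str = "mislabeling"
    methods: tuple[str, ...] = ("kadaif", "baseline_if")
    repetitions: int = 50
    pool_size: int = 50
    fractions: tuple[float, ...] = (0.02, 0.1, 0.3, 0.5)
    levels: tuple[float, ...] | None = None  # p grid or factor grid
    seed: int = 0
    params: KadaifParams | None = None

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for m in self.methods:
            if m not in _METHODS:
                raise ValueError(f"unknown method {m!r}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not self.fractions:
            raise ValueError("fraction grid must be non-empty")
        if self.levels is None:
            if self.scenario == "contamination_mixture":
                self.levels = (0.1, 0.2, 0.3, 0.4)
            elif self.scenario == "contamination_inflation":
                self.levels = (5.0, 20.0, 100.0)
            else:
                self.levels = (float("nan"),)
        if len(self.levels) == 0:
            raise ValueError("level grid must be non-empty")


@dataclass
class RocResult:
    """Pooled AUC for one (scenario, method, fraction, level) cell."""

    scenario: str
    method: str
    fraction: float
    level: float
    auc: float
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    per_repetition_auc: np.ndarray = field(repr=False)


def _build_pool(scenario, normal, anomalous, fraction, level, pool_size, rng):
    if scenario == "mislabeling":
        return build_mislabeling_pool(normal, anomalous, fraction, pool_size, rng)
    if scenario == "contamination_mixture":
        return build_contamination_pool(normal, anomalous, fraction, level, pool_size, rng)
    return build_inflation_pool(normal, fraction, level, pool_size=pool_size, rng=rng)


def run_experiment(
    config: ExperimentConfig,
    sources: tuple[FeatureTable, FeatureTable] | None = None,
    community: CommunitySpec | None = None,
) -> list[RocResult]:
    """Run the full grid and return one pooled RocResult per cell/method.

    ``sources`` supplies the (normal, anomalous) source tables; when
    omitted they are generated from ``community`` (or a default
    CommunitySpec) with a seed derived from the config seed. Pool
    construction is seeded by (cell, repetition) only, so every method
    sees identical pools — a paired comparison.
    """
    base_params = config.params or KadaifParams()
    if sources is None:
        spec = community or CommunitySpec()
        gen_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
        need_anom = config.pool_size  # enough to draw any fraction <= 0.5 w/o replacement
        normal, anomalous = generate_communities(spec, 4 * config.pool_size, need_anom, gen_rng)
    else:
        normal, anomalous = sources

    results: list[RocResult] = []
    for ci, fraction in enumerate(config.fractions):
        for li, level in enumerate(config.levels):
            pools = []
            for rep in range(config.repetitions):
                pool_rng = np.random.default_rng(
                    np.random.SeedSequence(config.seed, spawn_key=(1, ci, li, rep))
                )
                pools.append(
                    _build_pool(config.scenario, normal, anomalous, fraction, level,
                                config.pool_size, pool_rng)
                )
            for mi, method in enumerate(config.methods):
                all_scores, all_labels, rep_aucs = [], [], []
                for rep, pool in enumerate(pools):
                    seed = np.random.SeedSequence(
                        config.seed, spawn_key=(2, ci, li, mi, rep)
                    ).generate_state(1)[0] % (2**31)
                    params = _with_seed(base_params, int(seed))
                    report = score_samples(pool.table, params, method=method)
                    all_scores.append(report.score)
                    all_labels.append(pool.labels)
                    rep_aucs.append(roc_auc(report.score, pool.labels))
                scores = np.concatenate(all_scores)
                labels = np.concatenate(all_labels)
                results.append(
                    RocResult(
                        scenario=config.scenario,
                        method=method,
                        fraction=fraction,
                        level=level,
                        auc=roc_auc(scores, labels),
                        scores=scores,
                        labels=labels,
                        per_repetition_auc=np.array(rep_aucs),
                    )
                )
    return results


def _with_seed(params: KadaifParams, seed: int) -> KadaifParams:
    from dataclasses import replace

    return replace(params, seed=seed)


def results_frame(results: list[RocResult]) -> pd.DataFrame:
    """Long-format results table (one row per grid cell and method)."""
    return pd.DataFrame(
        {
            "scenario": [r.scenario for r in results],
            "method": [r.method for r in results],
            "fraction": [r.fraction for r in results],
            "level": [r.level for r in results],
            "auc": [r.auc for r in results],
            "repetitions": [len(r.per_repetition_auc) for r in results],
            "n_pooled": [len(r.scores) for r in results],
        }
    )


def score_distribution_summary(scores, labels, threshold: float = 0.5) -> pd.DataFrame:
    """Per-class score summaries plus the fraction flagged above threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rows = []
    for cls, name in ((0, "normal"), (1, "anomalous")):
        s = scores[labels == cls]
        if s.size == 0:
            continue
        rows.append(
            {
                "class": name,
                "n": s.size,
                "mean": s.mean(),
                "median": float(np.median(s)),
                "q25": float(np.quantile(s, 0.25)),
                "q75": float(np.quantile(s, 0.75)),
                "flagged_fraction": float((s > threshold).mean()),
            }
        )
    return pd.DataFrame(rows)
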