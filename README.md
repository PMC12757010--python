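# kadaif

Anomaly detection for sparse, high-dimensional, compositional abundance
tables — the kind produced by microbiome profiling, where conventional
outlier detectors struggle with compositionality, zero-inflation and
community-level dependencies between taxa.

`kadaif` implements KADAIF (K-dimensional Anomaly Detection using
Aggregated Isolation of Features), a generalization of Isolation Forest.
A classic isolation forest partitions samples with axis-parallel cuts on
single random features; on sparse taxon tables a single taxon is usually
uninformative. KADAIF instead draws a random multiset of ψ features at
every tree node (≈1% of the features, at least 10, with replacement),
renormalizes the subset into a proper relative-abundance profile,
ordinates it — PCoA on Bray–Curtis dissimilarities by default, PCA for
non-compositional omics — picks one of the leading axes with probability
proportional to its explained variance, and splits the node's samples at
a uniform random threshold T on that axis. Splitting on ordination axes
of feature subsets lets each cut reflect community-wide structure rather
than one noisy taxon.

Scoring follows the isolation-forest convention. With E(d(x)) the mean
depth at which sample x is isolated across t trees, and

    c(n) = 2 (H(n−1) − (n−1)/n)

the expected path length of an unsuccessful search in a binary search
tree over n items (H the harmonic number), the anomaly score is

    s(x) = 2^(−E(d(x)) / c(n)) ∈ (0, 1].

Easily isolated samples score near 1; an average sample scores 0.5.
Samples with s(x) > 0.5 are flagged as potential anomalies.

The package also ships everything needed to validate the detector on
synthetic data: a zero-inflated log-normal community generator, the
three anomaly-injection scenarios (mislabeling, mixture contamination at
level p where a contaminated profile is (1−p)·normal + p·anomalous, and
taxon inflation), a pooled ROC-AUC benchmarking harness, and a
sliding-window mode that scores each sample of a longitudinal series
against only the preceding 60 days — a real-time dysbiosis monitor.

## Worked example

```python
import numpy as np
from kadaif import (KadaifParams, build_mislabeling_pool, community_preset,
                    generate_communities, roc_auc, score_samples)

spec = community_preset("tight", seed=1)          # low-noise community
normal, anomalous = generate_communities(spec, 100, 20)
pool = build_mislabeling_pool(normal, anomalous, fraction=0.06,
                              pool_size=50, rng=np.random.default_rng(1))
report = score_samples(pool.table, KadaifParams(t=100, seed=1))
print(roc_auc(report.score, pool.labels))
```

Running `python examples/01_score_anomalies.py` (this scenario) prints:

```
sample          score   truly anomalous?
pool_1          0.622  FLAGGED  yes
pool_23         0.620  FLAGGED  yes
pool_9          0.615  FLAGGED  yes
pool_6          0.526  FLAGGED  no
...
pool ROC AUC vs ground truth: 1.000
```

The three planted anomalies (2% taxon-support shift, 3 of 50 samples)
receive the top scores — they were isolated after markedly fewer random
splits than the normal samples — and rank perfectly ahead of every
normal sample (AUC 1.0). The remaining examples cover the
mislabeling benchmark against the single-feature baseline
(`02_benchmark_mislabeling.py`), the contamination-level sweep
(`03_contamination_levels.py`) and sliding-window dysbiosis monitoring
(`04_sliding_window.py`).

A thin CLI wraps the same functionality:

```sh
kadaif score table.tsv -o scores.tsv --trees 100 --seed 7
kadaif simulate --scenario mislabeling --fraction 0.02 \
    --table-out pool.tsv --labels-out labels.tsv
kadaif benchmark --scenario mislabeling -o aucs.tsv
kadaif window table.tsv --manifest manifest.tsv -o trace.tsv
```

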