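# Methods

## The detector

KADAIF is an isolation-forest ensemble whose splits operate on
ordinations of random feature subsets. Each of `t` trees (default 100)
is grown on the full sample set. At a node holding m samples:

1. draw ψ = max(psi_min, round(psi_fraction · F)) feature indices
   uniformly, with replacement (defaults: 1% of the F features, at
   least 10); duplicate indices are kept as separate columns, so a
   doubly drawn taxon is doubly weighted in the node's distances;
2. renormalize every sample's restriction to those features into a
   relative-abundance profile (all-zero rows stay zero);
3. ordinate the subset — by default PCoA of the Bray–Curtis
   dissimilarity matrix; optionally PCA with per-feature mean centering;
4. pick one of the first min(20, available) axes with probability
   proportional to its explained variance (alternatives: uniform over
   the same prefix, or always the first axis);
5. draw a threshold T uniformly between the minimum and maximum of the
   samples' coordinates on that axis and split into {P ≤ T} and
   {P > T}.

Recursion stops when a node holds at most r samples (default r = 1) or
at maximal depth l (default: the number of samples). A split is
*degenerate* when the ordination retains no axis with positive variance,
the chosen projection is constant, or T lands so that one side is empty;
the node then redraws a fresh feature subset up to 3 times before
terminating as a leaf. Without this cap, a node of identical profiles
would retry forever.

A training sample's path length in a tree is its leaf depth (root = 0)
plus c(leaf size), the standard adjustment for unresolved leaves;
without it, max-depth truncation would inflate scores of samples in
large leaves. c(n) = 2(H(n−1) − (n−1)/n), with c(0) = c(1) = 0 by
convention since the formula is undefined there. Harmonic numbers are
computed by exact cumulative summation (memoized) up to 10^5 and by the
Euler–Maclaurin expansion above, which agrees to far better than 1e−6
at the crossover. The score is s(x) = 2^(−E(d(x))/c(n)); a mean depth
of exactly c(n) gives 0.5, and scores above the 0.5 flag threshold
(overridable) mark potential anomalies.

### Numerical conventions

- Bray–Curtis between two all-zero profiles is 0 (indistinguishable);
  between an all-zero and a non-zero profile it is 1. The textbook
  formula is 0/0 in those cases.
- Bray–Curtis is non-Euclidean, so PCoA can produce negative
  eigenvalues; axes with non-positive eigenvalues are discarded and
  explained-variance fractions are computed over the positive
  eigenvalues before truncating to the 20-axis candidate prefix.
- Eigenvector/loading signs follow a deterministic convention (the
  largest-magnitude loading is made positive) so results do not depend
  on the linear-algebra backend.
- Per-node renormalization applies in the PCoA/Bray–Curtis pipeline
  (compositional data). In PCA mode the node subset is mean-centered on
  the given scale without row renormalization: PCA mode targets
  non-compositional omics, where any table-level normalization is a
  preprocessing decision, and renormalizing would make single-feature
  subsets constant.
- PCA mode stores each node's feature means and loadings, so new
  samples can be projected through the fitted forest and scored
  out-of-sample; PCoA has no out-of-sample projection, so that mode
  scores only the fitted samples.

### Determinism

One master seed spawns an independent, indexed substream per tree
(numpy `SeedSequence.spawn`), so serial and parallel builds (joblib,
`n_jobs`) produce bit-identical forests, and every CLI command with a
fixed seed is byte-reproducible.

### Baseline

The single-feature baseline (`baseline_if`) shares the tree machinery,
depth bookkeeping and score formula but splits each node on one
uniformly chosen feature with a threshold uniform on that feature's
range — the classic isolation-forest rule — making method comparisons
differ only in the splitting strategy.

## Synthetic communities

The generator emulates the data properties the detector is designed
for: sparsity, compositionality, heavy-tailed rank abundances and
tunable group separation. A community draws per-taxon baseline
log-abundances θ_j ~ N(log_mean, log_sd²) once; a sample is
exp(θ_j + sample_log_sd · z_ij) with each taxon zeroed with probability
`sparsity`, then renormalized. Anomalous samples may add a
multiplicative shift on one fixed random taxon subset, a dispersion
factor ≥ 1 multiplying the sample-level noise sd (emulating the
elevated within-group variability of perturbed communities — the
"Anna Karenina" pattern), and/or a restriction to a disjoint taxon
support.

Three presets are used throughout the bundled experiments:

| preset  | n_taxa | log_sd | sample_log_sd | sparsity | anomaly departure |
|---------|--------|--------|---------------|----------|-------------------|
| sparse  | 300    | 2.0    | 0.7           | 0.6      | disjoint 20% support |
| tight   | 300    | 2.0    | 0.3           | 0.3      | disjoint 20% support |
| even    | 100    | 0.5    | 0.3           | 0.2      | (scenario-specific) |

`sparse` mimics a noisy genus-level gut cohort; `tight` the same
community with low between-sample noise, used where the injected
anomaly is itself subtle (mixture contamination); `even` a small,
even, low-noise community in which inflating a handful of taxa — or
inflating dispersion — visibly distorts composition. These synthetic
populations capture sparsity/compositional structure but not real
taxon inventories, phylogenetic correlation, batch effects or
sequencing noise; passing benchmarks demonstrates the machinery
works as specified, not field performance on any particular cohort.

## Injection scenarios and evaluation

Pools of 50 samples are built per repetition: mislabeling draws
round(fraction·50) members (floor 1, half-up rounding) from the
anomalous population without replacement; mixture contamination blends
that many normal members with independently drawn anomalous partners at
level p; inflation multiplies max(5, round(1% of taxa)) randomly chosen
taxa of each affected sample by the contamination factor and
renormalizes. The harness repeats each grid cell, pools all scores
(repetitions × pool size points; 2500 at the defaults) and computes one
ROC AUC on the pooled vector via the Mann–Whitney statistic with
half-credit ties; per-repetition AUCs are diagnostics only. Pool
construction is seeded independently of the scoring method, so methods
are compared on identical pools.

## Sliding-window longitudinal scoring

For each focal sample at time t the fitted pool is the preceding
samples with timestamps in (t − 60 days, t] plus the focal sample
itself (included because the default PCoA mode cannot score
out-of-sample points); the focal sample's score is reported. Samples
with fewer than `min_history` (default 20) predecessors in the window
are undefined (NaN) — small pools make c(n) and depth statistics
meaningless. The presentation trace is a trailing 7-sample rolling
average computed over defined values, using the available prefix at the
series head; undefined positions stay undefined.

## Reference experiment sizes

The bundled experiments (`kadaif.experiments`, also exercised by
`scripts/acceptance.py`) use problem sizes chosen to make each
benchmark a minutes-scale desk computation while keeping the pooled
score vectors large enough for stable AUCs:

- mislabeling: `sparse` preset, 2% anomalies, pools of 50, 50
  repetitions, t = 100, KADAIF vs the single-feature baseline;
- mixture contamination: `tight` preset, 4% contaminated, p ∈
  {0.1, 0.3, 0.5, 0.7, 0.9}, 20 repetitions per level, t = 100;
- inflation: `even` preset, 4% affected, factors {1, 20}, 20
  repetitions, t = 100 (factor 1 is a no-signal control whose AUC
  should be ≈ 0.5);
- sliding window: `even` preset with dispersion 4 on days 80–90 of a
  200-day series sampled every other day, window 60 days, min_history
  20, t = 25; detection = the rolling-average peak inside days 75–95.

## Known limitations

- PCoA mode cannot score unseen samples; use PCA mode for novelty
  detection or out-of-sample scoring.
- Score distributions compress toward 0.5 as within-group variability
  grows; the 0.5 flag threshold is a heuristic and should be examined
  against the score distribution for noisy cohorts.
- Low-level (p ≲ 0.2) mixture contamination is intrinsically hard for
  community-level splits: a mostly normal profile looks normal; a
  single-feature detector can outperform there.
- The inflation scenario's detectability depends on the inflated taxa's
  share of the community; in very heavy-tailed communities, inflating a
  few random (usually rare) taxa changes little of the composition.
- Tree building is O(t · n² · ψ) per level with small constants but is
  pure Python/numpy; forests over thousands of samples will be slow.
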