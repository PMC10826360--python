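# Methods

## Simulation model

Each simulated data set represents an amplicon sequencing experiment with
two treatment groups of 40 samples each. The generative model has four
stages.

**Parent communities.** Two relative-abundance vectors
**p**<sub>A</sub>, **p**<sub>B</sub> over a shared OTU index play the role
of the two source environments. Synthetically they are lognormal
species-abundance distributions (σ = 2.0 by default, a typical SAD shape
for microbial surveys) with a configurable support overlap: a fraction
`overlap_fraction` (default 0.6) of OTUs carries nonzero mass in both
parents and the remainder is split evenly into group-exclusive taxa.
Alternatively `build_parents_from_counts` derives parents from a real
sample × OTU table by pooling two named sample groups, keeping OTUs observed
in more than one pooled sample, sorting by prevalence then total abundance,
and truncating to the top *n* OTUs. A random bifurcating phylogeny with
Exponential(1) branch lengths supplies the tree UniFrac needs; it captures
"a tree exists with heterogeneous branch lengths", not any real phylogeny.

**Effect-size mixing.** Group sampling distributions are
mix<sub>A</sub> ∝ *f*·**p**<sub>A</sub> + **p**<sub>B</sub> and
mix<sub>B</sub> ∝ **p**<sub>A</sub> + *f*·**p**<sub>B</sub> with effect size
*f* ∈ {1.00, 1.15, 1.25, 1.50, 1.75, 2.00, 2.50, 3.50}. Multiplying each
group's *own* parent makes the construction symmetric, exactly null at
*f* = 1.00, and monotonically more separated as *f* grows.

**Sequencing depths.** Two depth models span the observed range
58,688–2,357,181 reads. `empirical_resample` keeps a pool of 26 depths
drawn from a normal distribution clipped to that range (mean 1,085,256.8;
the sd default 600,000 was chosen so that draws fill the range without
piling on the clip boundaries) and resamples the pool with replacement for
the 80 samples, so depths repeat ~80/26 ≈ 3.08 times — the signature of a
small re-used sequencing run. `log_scaled` places 80 unique depths evenly
on the log scale across the same range (median 372,040, mean 629,824.8) —
no duplicates, as in real collections. Depths are rescaled so their median
hits a target Ñ<sub>L</sub> ∈ {1,000, 2,000, 5,000, 10,000, 50,000}
(round to nearest integer, floor 1; rounding direction is a free choice and
is immaterial at these magnitudes). Group labels are attached either
randomized (independent of depth) or fully confounded: after sorting, the
40 shallowest libraries all go to group A. Full confounding is an extreme
but diagnostic design — any normalization that lets depth leak into the
metric will turn depth structure into apparent treatment structure.

**Counts.** Every sample is one multinomial draw of its library size from
its group's mixture. Row sums therefore equal assigned depths exactly.

**Rare-OTU filter (optional grid dimension).** Step 1 removes an OTU only
if total < 3 *and* prevalence < 3; step 2 removes it only if at most 5% of
samples have counts above one *and* the total is ≤ half the per-group
sample count (20 for 40/40). Each step is a conjunction: an OTU must fail
both clauses of a step to be removed. The filter is idempotent and never
touches surviving counts.

## Normalizations

- **raw** — untouched counts.
- **relabund** — per-sample proportions.
- **vst** — counts + 1 pseudocount, size factors by median-of-ratios
  against the geometric-mean reference, a mean-dispersion curve
  α(μ) = a₀/μ + a₁ fitted by method of moments (per-OTU dispersion
  (var − x̄·μ)/μ², x̄ the mean reciprocal size factor, regressed on 1/μ),
  and the closed-form variance-stabilizing transform for that curve,
  log2-scaled so it approaches log₂(μ) for large counts. Small counts can
  map below zero; negative values are *not* clipped, and
  `detect_negative_fraction` quantifies them. A non-positive a₁ estimate
  (no asymptotic overdispersion, e.g. near-Poisson data) falls back to
  10⁻⁸ with a logged warning. The contract is monotonicity, asymptotic
  log₂ behaviour and variance flattening — not bit-equality with any
  particular implementation.
- **uq_logfc** — per-sample factors = 75th percentile of nonzero counts /
  library size, rescaled to geometric mean 1; output log₂(CPM + 1) against
  the effective library size (depth × factor). The pseudocount sits on the
  CPM scale so the output is exactly invariant to rescaling a sample's
  counts.
- **subsample** — one multivariate-hypergeometric draw (without
  replacement) of N<sub>L,m</sub> reads per retained sample.
- **rarefy** — the same draw repeated `n_iterations` times (default 100;
  desk runs use 25) with the *metric* averaged across draws. Averaging
  happens on distance matrices or alpha values, never on counts.

**Threshold quantiles.** N<sub>L,m</sub> is set from a percentile
q ∈ {0, 5, 10, 15, 20, 25, 40} of the 80 depths using the
linear-interpolation empirical quantile, so with distinct depths exactly
q% of samples fall below the cutoff and are discarded; N<sub>L,m</sub> is
then the smallest retained depth. (The inverse-ECDF quantile would remove
one sample fewer at each listed q; the interpolating rule is the one that
makes "remove the shallowest 15%" mean exactly 12 of 80 samples, which is
what the accuracy penalty arithmetic requires.) Quantile 0 keeps every
sample. The whole-table normalizations (raw, relabund, vst, uq) always use
quantile 0.

## Distances and pairing rules

Bray-Curtis (Σ|x−y| / Σ(x+y)), Euclidean, the Poisson deviance
dissimilarity (per-pair pooled rates split by total-count ratio, counts
power-transformed with the exponent whose Pearson chi-square against
independence is closest to its degrees of freedom), unweighted and weighted
UniFrac (scikit-bio; weighted defaults to the normalized variant), and
top-MSD (root mean of the `n_top` = 500 largest squared per-OTU
differences of log-scale values; clamped with a warning when fewer OTUs
exist). Admissible pairings follow the benchmark's design: raw counts feed
Bray-Curtis/Euclidean/Poisson/weighted UniFrac; proportions feed
Bray-Curtis and both UniFracs; subsampled and rarefied counts feed all
six; VST output feeds Euclidean only (its negative values poison any
abundance-summing formula — Bray-Curtis and weighted UniFrac are available
only behind a `pathology=True` flag for reproducing that failure mode);
upper-quartile log output feeds top-MSD only. Inadmissible cells are
recorded as NA, never silently dropped. For rarefaction the mean of the
per-iteration distance matrices is the distance matrix.

## Clustering and accuracy

PAM is classical k-medoids (greedy BUILD, then SWAP until no single medoid
replacement improves the cost; ties break toward the lowest index). BUILD +
SWAP is a local search: on adversarial non-metric matrices it can stop in a
single-swap local optimum, so exact agreement with exhaustive medoid search
is guaranteed only for separated data (tests check both: exhaustive
equality on clustered toys, swap-local-optimality always). K-means (10
restarts, seeded) runs on the distance-matrix rows as feature vectors,
mirroring the common direct call of a K-means routine on a square distance
matrix; since rows-as-features is geometrically unorthodox, a
principal-coordinates embedding is available via `embed="pcoa"`.
Hierarchical clustering is complete linkage cut at k = 2. Accuracy is the
best of the two cluster↔group matchings divided by the *total* sample
count including discarded samples, so a 15% removal caps accuracy at 85%,
and the forced two-cluster split of null data caps it at 41/80 ≈ 0.51.

## Hypothesis tests

PERMANOVA: SS_total = Σ_{i<j} d²_ij/n, within-group sums divided by group
size, pseudo-F = (SS_between/(a−1))/(SS_within/(n−a)), p = (1 + #{F_perm ≥
F_obs})/(n_perm + 1) over seeded label permutations (999 by default), with
exact enumeration of all balanced partitions available for small n. The
pseudo-F statistic is cross-checked against scikit-bio's implementation in
the tests. Wilcoxon rank-sum is exact for groups of ≤ 10 tie-free values
and otherwise uses the normal approximation with continuity correction;
constant pooled data return p = 1. Alpha-diversity exclusions: VST output
is incompatible with richness and Shannon (negative values); upper-quartile
log output is excluded from richness because it leaves every cell nonzero.

## Orchestration and reproducibility

All randomness flows from one master seed through
`SeedSequence(master_seed, spawn_key=(condition_index, replicate))`, so
adding conditions never perturbs existing replicates and every record is
reproducible in isolation. `run_grid` writes one long-format TSV row per
processing cell with an 8-hex-digit checksum (floats canonicalized to 12
significant digits); interrupted runs resume by skipping intact
(condition, replicate) blocks and recomputing any block containing a
corrupt row. Grid presets: `wnwn` (8 effect sizes × 4 target medians × 5
replicates = 160 data sets, the original layout), `full` (8 × 2 depth
models × 5 medians × 2 assignments × 2 filter settings × 100 replicates),
and `desk` (200 OTUs, depth range scaled down 10×, 25 replicates,
rarefaction 25 iterations — the scale used by the analysis scripts and
acceptance run, chosen to keep a full pass in minutes on one core while
leaving every qualitative contrast intact). The per-data-set processing
menu counts 280 combinations (2 filter settings × 20 normalizations
[4 whole-table scalings + TMM and RLE, which are enumerated but not
evaluated + subsampling and rarefaction at 7 quantiles each] × 7 distance
calculations, including the never-discussed BCV slot).

## What the synthetic generator does and does not capture

It reproduces the statistical skeleton the benchmark needs: two overlapping
heavy-tailed parent communities, multinomial sampling noise, realistic
depth ranges, depth-group confounding, and the OTU-filtering regime. It
does **not** model sequencing error, chimeras, PCR bias, overdispersion
beyond multinomial sampling (within a group, counts are not more variable
than multinomial), or a real phylogeny's structure. Passing results
therefore demonstrate properties of the *normalization arithmetic* under
controlled uneven sampling — e.g., that confounded depth inflates type-I
error for every non-rarefaction method — not claims about any particular
real data set.

## Numerical choices and edge cases

Bray-Curtis on two all-zero samples is an error; a zero-depth sample cannot
be converted to proportions; subsampling below a sample's depth is an
error; the rare-OTU filter erroring out when nothing survives is explicit.
Distance matrices are validated symmetric (1e-10) with zero diagonals.
The permutation p-value's +1 correction keeps p ≥ 1/(n_perm+1); the
perfect-separation F is reported as ∞ and compared accordingly. Ties in
PAM break toward lower indices; K-means determinism comes from its seed.

## Known limitations

- The empirical depth pool matches the published range and mean but not the
  exact 26 depths (only summaries are available), so empirical-model runs
  emulate moments, not the original vector.
- Top-MSD is the top-k mean-squared-difference skeleton; it does not
  reproduce edgeR's dispersion-shrunken predicted fold changes.
- The VST is contract-equivalent, not numerically identical, to the R
  implementation it emulates.
- BUILD+SWAP PAM is a local search (see above).
- Desk-scale runs (200 OTUs, 25 replicates) trade Monte-Carlo resolution
  for speed; rejection-fraction estimates carry binomial error of a few
  percentage points at those replicate counts.
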