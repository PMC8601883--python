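# Methods

This note documents the models and conventions behind `replidepth`: what
each stage computes, the defaults and why, and what the synthetic
generator does and does not emulate. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model

The unit of analysis is the PCR replicate: one column of a dense
taxon-by-replicate integer count table. Biological structure (which
replicates come from which DNA extract, which marker, which columns are
extraction/PCR negatives or the positive control) lives in a separate
metadata table. Lineages are stored per taxon as semicolon-delimited
`rank:value` tokens, so a taxon resolved only to genus or family carries
fewer tokens rather than padded blanks. TSV is canonical; a dense
JSON-BIOM subset is provided for interoperability. Sparse storage and
sequence-level (FASTQ/ASV) handling are out of scope.

## Synthetic experiments

The generator emulates a high-replication soil eDNA design: by default
6 extracts × 24 PCR replicates for one marker, plus one extraction
negative, two PCR negatives and one positive-control column.

- **Community:** each extract gets its own pool of `richness_per_extract
  = 300` taxa with lognormal rank abundances (σ = 2, unitless log-scale
  sd). This produces the phenomenology the analyses probe: a few
  dominant taxa at percent-to-tens-of-percent within-replicate
  frequencies and a long tail of taxa near the detection limit. A
  geometric model (ratio g) is available as an alternative stand-in;
  neither is a claim about any real community's distribution family.
- **PCR noise:** replicate proportions are drawn from
  `Dirichlet(θ·p)` around the extract's true composition `p`, then reads
  are drawn multinomially. θ (default 50) controls overdispersion: the
  expected within-replicate frequency of every taxon equals `p_i` for
  all θ (verified by a Monte-Carlo property test), while the variance of
  replicate frequencies grows as θ falls. θ ≥ 1e9 switches the Dirichlet
  step off (the deterministic multinomial limit). A cycle-by-cycle PCR
  branching simulator is deliberately out of scope; the two-parameter
  Dirichlet-multinomial already reproduces stochastic detection of rare
  taxa across replicates, occupancy–abundance correlation, and
  depth-dependent drop-out.
- **Depths:** per-replicate read totals are lognormal (meanlog 10.3,
  sdlog 0.7, i.e. a median near 30k reads) truncated to
  [6148, 166279], the retained-read range the emulated design spans.
  Drawing depths per replicate (rather than fixing them) is what makes
  rarefaction drop-out occur naturally.
- **Controls:** two contaminant taxa (ids disjoint from all community
  pools) appear in each negative control with probability 0.9 and in
  true samples with probability 0.05, at 1 + Poisson(29) reads where
  present. One positive-control column carries 100,000 reads of a spike
  taxon; a configurable `hop_rate` fraction of those reads is reassigned
  uniformly to other columns to emulate index hopping (default 0).
- **Seeding:** one integer master seed; every replicate, stage and grid
  cell derives a named child stream (`SeedSequence` spawn keys from
  CRC32-hashed tokens), so any cell is recomputable in isolation and the
  same config regenerates byte-identical tables.

What the generator does **not** emulate: primer and amplification-
efficiency bias, chimeras and sequence-level error, tag-jumping
mechanisms beyond uniform read reassignment, taxonomic mis-assignment,
and shared taxa between extracts (extract pools are disjoint, so
between-extract distances are near 1 and ordination tests here speak
only to within-extract structure). Tests passing on synthetic data
therefore validate the estimators and the direction of design effects,
not any claim about a particular habitat.

## Decontamination

The prevalence criterion asks whether a taxon is present in negative
controls more readily than in samples. Each taxon gets a one-sided 2×2
presence/absence association score (present/absent × control/sample):
Pearson chi-square with continuity correction when all four expected
cells are ≥ 5, otherwise Fisher's exact test; taxa absent from all
controls score 1 by construction. A taxon is removed (whole row, all
replicates) when score < 0.1, and extraction and PCR negatives are
pooled into one control class. The score is monotone in control
prevalence within the exact-test regime; mixing the chi-square and
Fisher branches can in principle break monotonicity at the expected-cell
boundary, which is why the monotonicity property is only guaranteed (and
tested) for designs with few controls, where the exact branch always
applies. Controls are not rarefied before scoring — presence/absence is
depth-sensitive, and this choice is deliberate and documented rather
than resolved. Frequency-based (concentration-aware) scoring and
batch-aware designs are out of scope.

## Rarefaction and thresholds

Rarefaction draws exactly *d* reads without replacement (multivariate
hypergeometric), so expected rarefied richness has the closed form
E[S_d] = Σᵢ (1 − C(N−xᵢ, d)/C(N, d)) used as a test oracle. Sampling
with replacement was rejected because subsampling a sequenced read pool
is the operation being modelled. The minimum read threshold is applied
per replicate after rarefaction, and is inclusive: `t = 5` keeps a taxon
with exactly 5 reads, so `t = 2` removes exactly the singletons.
Replicates with fewer than *d* total reads are flagged dropped for that
depth rather than raising, and the retained count per depth is reported.
Grid cells are averaged over R = 25 independent rarefactions.

## Alpha diversity

Shannon uses natural log; Simpson is the Gini–Simpson complement
1 − Σ pᵢ². Interpolated richness is the exact hypergeometric form
computed with log-gamma to avoid overflow. Extrapolation follows the
standard sample-size-based Hill-number (q = 0) formulas: the unseen-taxa
estimate f₀̂ = ((n−1)/n)·f₁²/(2f₂) (bias-corrected variant when f₂ = 0),
S(n+m*) = S_obs + f₀̂·[1 − (1 − f₁/(n·f₀̂+f₁))^{m*}], with asymptote
Ŝ = S_obs + f₀̂; the curve is continuous at the reference sample and
flat when there are no singletons. Uncertainty comes from a bootstrap on
the coverage-adjusted community (observed proportions shrunk by the
estimated coverage, ⌈f₀̂⌉ unseen taxa sharing the deficit equally),
nboot = 50, normal-approximation 95% CI, 40 knots spanning [1, 2n].
Outlier calls use the 1.5×IQR rule with type-7 (linear interpolation)
quantiles — flags can flip under other quantile rules, so the rule is
fixed and stated. Depth contrasts are Welch two-sided t-tests (the safer
default when variances differ), computed on replicates present at both
depths. Extrapolation is done per replicate first; the IQR test is then
applied across a group's replicate values. Hill numbers for q > 0 and
coverage-standardised comparison are out of scope.

The pipeline averages all three indices (not just richness) over the
R = 25 rarefactions of each (replicate, depth) cell; a single convention
keeps the outputs deterministic and mutually comparable.

## Replicate accumulation and occupancy

Accumulation shuffles the replicate order uniformly (permutation, not
resampling) B = 100 times and averages the cumulative unique-taxon
count. Averaging happens before the saturation rule: the curve is
saturated at the smallest k whose next mean increment is < 1 taxon, with
sentinel ">K" when no such k exists — K being the replicates retained
after rarefaction. The occupancy–abundance fit is OLS of occupancy on
log₁₀ mean reads where present; the slope scales with the log base but
t, p and adjusted R² do not (tested). Occupancy is fixed as the
response; for simple regression, r² and the slope's t statistic are the
same under either orientation.

## Beta diversity

LCBD follows the variance-decomposition definition: transform
(Hellinger, i.e. square root of within-replicate proportions, the
conventional default; `none` also available and flagged in output),
centre each taxon across replicates, sum squared deviations per
replicate and normalise by the total, so Σ LCBD = 1 exactly. The
permutation null shuffles values within each taxon row independently;
p-values use the (exceed+1)/(n_perm+1) convention with Holm adjustment,
and "outlier" means adjusted p ≤ 0.05 (n_perm = 999 and the adjustment
are configurable because the upstream convention varies). An
all-identical table is degenerate: uniform 1/n with p = 1.

PCoA is Gower double-centring plus symmetric eigendecomposition.
Jaccard matrices are non-Euclidean, so negative eigenvalues occur; the
dispersion computation retains them following the PERMDISP2 convention
(squared distance to the group spatial median = real part − imaginary
part, floored at 0), while ordination exports expose positive axes only.
The spatial median is the geometric median by Weiszfeld iteration
(tolerance 1e-8, centroid start — for a two-point group this returns the
midpoint, a valid minimiser of the non-unique objective). Bias
adjustment multiplies each group's distances by √(n_g/(n_g−1)).
Homogeneity is tested by one-way ANOVA on the distances, with both the
F-distribution p and a permutation p (group labels of the computed
distances are permuted, the standard shortcut), plus Tukey HSD on group
means. Degenerate inputs (all distances equal) report F = 0, p = 1.
Chi-square contrasts of outlier counts use Yates correction only for
2×2 tables. NMDS, PERMANOVA and model-based ordination are out of scope.

## Problem sizes and test design

Monte-Carlo assertions use explicit error budgets: closed-form oracles
are checked within 3 Monte-Carlo σ, binomial survival/hop rates within
4σ. The dispersion test's type-I rate is calibrated over 500 null
simulations (3 groups × 8 points from one isotropic Gaussian, 199
permutations each); the decontamination null uses 1,000
label-independent taxa; Chao1 recovery uses geometric communities with
g = 0.95 and S_true = 60 at depth 50·S_true, a regime in which every
taxon is expected at ≥ 2 reads, i.e. the community is effectively fully
observed — the regime where a lower-bound estimator can be expected to
recover the truth. The saturation-trend check uses a deeply sequenced,
very uneven community (S = 500, lognormal σ = 2.5, θ = 1000) because the
trend is only observable when the saturation point is not censored at
the replicate ceiling: under heavier PCR noise every cell reports ">24"
and the ordering carries no information. The depth–dispersion contrast
uses the default θ = 50 noise level, where replicate composition is
noisy enough to disperse but sampling depth still controls rare-taxon
detection; at extreme overdispersion (θ ≲ 10) replicate-level noise
swamps the depth effect and the contrast loses power — a model
behaviour, documented rather than hidden.

## Known limitations

- The prevalence score is a generic one-sided association test, not a
  re-implementation of any specific tool's internals.
- LCBD p-values inherit the usual caveats of row-permutation nulls under
  strong mean–variance coupling.
- The bootstrap SE for the richness curve uses the coverage-adjusted
  multinomial scheme; it understates uncertainty for very small n.
- Extract communities are disjoint in the generator, so between-extract
  beta diversity is saturated near 1 by construction.
- `aggregate_by_rank` pools taxa lacking the rank into "unassigned"; a
  rank absent from every lineage is treated as a typo and rejected.
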