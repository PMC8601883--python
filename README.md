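# replidepth

Replicate-, depth- and threshold-aware diversity analysis for eDNA
metabarcoding taxon tables.

## The problem

A single soil or water DNA extract is usually amplified in a handful of
PCR replicates, sequenced to some depth, and filtered with an ad-hoc
minimum read count before diversity is estimated. All three choices —
how many PCR replicates, how many reads are subsampled per replicate
(the rarefaction depth *d*), and the per-replicate minimum read
threshold *t* — change the answer, because a large fraction of taxa in
an uneven community are detected stochastically: present in one
replicate, absent from the next, hovering at one or two reads.

`replidepth` implements the full analysis grid for this question on a
taxon-by-replicate count table plus replicate metadata (extract, marker,
sample type), and ships a synthetic-experiment generator with known
ground truth so the entire pipeline is testable without any sequencing
data. It is aimed at molecular ecologists designing or auditing
replication strategies for metabarcoding surveys.

## What it computes

- **Decontamination** — each taxon is scored with a one-sided 2×2
  presence/absence association test (Fisher exact, or chi-square with
  continuity correction when expected cells allow) between negative
  controls and true samples; taxa with score < 0.1 are removed. A
  positive-control spike taxon quantifies index hopping.
- **Rarefaction grid** — without-replacement subsampling (multivariate
  hypergeometric) of each replicate to every depth in the design
  (default 1,000–20,000 by 1,000), followed by thresholds *t* ∈ {2, 5, 10}
  applied per replicate (a taxon needs ≥ *t* reads to survive), with
  25-rarefaction averaging of observed richness and explicit drop-out
  bookkeeping for replicates shallower than *d*.
- **Alpha diversity** — S_obs, Shannon *H* = −Σ pᵢ ln pᵢ, Gini–Simpson
  1 − Σ pᵢ²; the exact interpolated richness
  S(m) = S_obs − Σᵢ C(n−xᵢ, m)/C(n, m); Chao1-based extrapolation to 2n
  with f₀̂ = ((n−1)/n) f₁²/(2 f₂) and asymptote Ŝ = S_obs + f₀̂;
  bootstrap SEs on the coverage-adjusted community (nboot = 50, 95% CI,
  40 knots); 1.5×IQR outlier flags; Welch t-tests and fold changes
  between depths.
- **Replicate accumulation** — cumulative richness as replicates are
  added in 100 shuffled orders; the curve is *saturated* at the smallest
  k whose next replicate adds fewer than one taxon on average (sentinel
  “>K” otherwise); occupancy spectra and the OLS fit of occupancy on
  log₁₀ mean reads.
- **Beta diversity** — binary Jaccard and Bray–Curtis distances; LCBD
  (each replicate's share of total community variance, Hellinger
  transform by default, row-permutation p-values with Holm adjustment);
  PCoA via Gower double-centring; PERMDISP2-style dispersion to the
  group spatial median with negative-eigenvalue correction, bias
  adjustment √(n/(n−1)), ANOVA + permutation p and Tukey HSD; chi-square
  contrasts of outlier counts.

## Worked example

```python
import numpy as np
from replidepth import (SyntheticConfig, simulate_experiment, prevalence_scores,
    remove_contaminants, rarefy_table, accumulation_curve, occupancy_spectrum,
    alpha_indices, extrapolated_richness)

cfg = SyntheticConfig(n_extracts=2, replicates_per_extract=12,
                      richness_per_extract=150,
                      depth_min=6148, depth_max=166279, seed=42)
table, meta, truth = simulate_experiment(cfg)
print("table:", table.n_taxa, "taxa x", table.n_replicates, "replicates")

calls = prevalence_scores(table, meta, threshold=0.1)
print("flagged contaminants:", [c.taxon_id for c in calls if c.is_contaminant])

clean = remove_contaminants(table, calls, 0.1, meta).drop_taxa([truth.spike_taxon])
clean = clean.select_replicates([r for r in clean.replicate_ids
                                 if r in set(meta.sample_ids)])
col = clean.column("E1.r00")
s, h, si = alpha_indices(col)
print(f"E1.r00 raw: n={col.sum()} S_obs={s} H={h:.3f} Simpson={si:.3f}")

cell = rarefy_table(clean.select_replicates(meta.extracts()["E1"]), 5000, 5, seed=0)
curve = accumulation_curve(cell, B=100, seed=0)
print("accumulation mean:", np.round(curve.mean[:5], 1),
      "... saturation:", curve.saturation_label)
print(f"occupancy-1 fraction: {occupancy_spectrum(cell)[1]:.3f}")
```

prints

```
table: 303 taxa x 28 replicates
flagged contaminants: ['contam00', 'contam01']
E1.r00 raw: n=31106 S_obs=40 H=1.922 Simpson=0.704
accumulation mean: [28.8 42.3 52.1 60.5 67.4] ... saturation: >12
occupancy-1 fraction: 0.388
```

The generator injected exactly two contaminant taxa, and the prevalence
test recovers both and nothing else. At a 5,000-read depth with a
threshold of five, the first replicate of extract E1 detects ~29 taxa,
the second adds ~13 more, and the curve is still rising by more than one
taxon per replicate after all 12 ("saturation: >12") — almost 39% of
detected taxa appear in only a single replicate, which is why replicate
number matters.

There is also a CLI mirroring the library stages:

```sh
replidepth simulate --config config.yaml --out sim/
replidepth decontam --counts sim/counts.tsv --meta sim/metadata.tsv --out dec/
replidepth run --config pipeline.yaml     # full grid, TSV reports + manifest
```

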