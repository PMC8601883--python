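"""Synthetic metabarcoding experiments with known ground truth.

Emulates the replicate/depth structure of a soil-eDNA replication study:
six DNA extracts, 24 PCR replicates per extract, two markers, per-replicate
read depths spanning roughly 6,000-170,000 reads, highly uneven communities
in which a few ubiquitous taxa carry percent-level within-replicate
frequencies while many taxa hover near the detection limit, negative
controls carrying a small number of contaminant taxa, and one exotic
positive-control taxon used to detect index hopping.

PCR stochasticity is modelled as a Dirichlet-multinomial: each replicate
draws its own taxon proportions from ``Dirichlet(theta * p)`` around the
extract's true composition ``p`` and then draws reads multinomially at a
depth sampled from a truncated lognormal.  Smaller ``theta`` means noisier
replicates; the expected within-replicate frequency of every taxon equals
its true frequency for all ``theta``.  A cycle-by-cycle PCR simulator is a
non-goal: the two-parameter model already reproduces the phenomenology the
downstream analyses probe (stochastic detection of rare taxa across
replicates, occupancy-abundance correlation, depth-dependent drop-out).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._seeding import child_rng
from .tables import ReplicateMetadata, SampleType, TaxonTable

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "sample_community",
    "simulate_replicates",
    "spike_contaminants_and_controls",
    "simulate_experiment",
]

THETA_DETERMINISTIC = 1e9  # at or above this, Dirichlet noise is switched off


@dataclass
class SyntheticConfig:
    """Study-design parameters for a synthetic experiment.

    Defaults reproduce the study conditions this package targets: 6
    extracts x 24 PCR replicates per marker, lognormal rank-abundance with
    sd 2 over 300 taxa per extract (a handful of dominant taxa at percent-
    to tens-of-percent frequencies, a long tail of near-singletons),
    Dirichlet concentration theta=50 for PCR noise, retained depths
    lognormal around ~30k reads truncated to [6148, 166279], two
    contaminant taxa visible in negative controls, and one positive-control
    spike taxon at 100k reads.
    """

    n_extracts: int = 6
    replicates_per_extract: int = 24
    richness_per_extract: int = 300
    rank_abundance: str = "lognormal"  # or "geometric"
    geometric_ratio: float = 0.95
    lognormal_sigma: float = 2.0
    theta: float = 50.0
    depth_log_mean: float = 10.3   # ln reads; exp(10.3) ~ 29,700
    depth_log_sd: float = 0.7
    depth_min: int = 6148
    depth_max: int = 166279
    n_contaminants: int = 2
    contaminant_prevalence_in_controls: float = 0.9
    contaminant_prevalence_in_samples: float = 0.05
    contaminant_mean_reads: float = 30.0
    n_extraction_controls: int = 1
    n_pcr_controls: int = 2
    spike_depth: int = 100_000
    hop_rate: float = 0.0
    marker: str = "M1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        for p in (
            self.contaminant_prevalence_in_controls,
            self.contaminant_prevalence_in_samples,
            self.hop_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.depth_min <= 0 or self.depth_max < self.depth_min:
            raise ValueError("depth bounds must be positive and ordered")
        if min(self.n_extracts, self.replicates_per_extract, self.richness_per_extract) < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually did, for downstream verification."""

    abundances: dict[str, list[float]] = field(default_factory=dict)  # extract -> p
    taxon_ids: dict[str, list[str]] = field(default_factory=dict)  # extract -> community taxa
    contaminant_ids: list[str] = field(default_factory=list)
    spike_taxon: str | None = None
    hopped_reads: dict[str, int] = field(default_factory=dict)  # replicate -> spike reads hopped in
    seed: int = 0

    def __post_init__(self) -> None:
        for ext, p in self.abundances.items():
            if p and abs(sum(p) - 1.0) > 1e-12:
                raise ValueError(f"abundances for {ext} do not sum to 1")
        community = {t for ids in self.taxon_ids.values() for t in ids}
        if community & set(self.contaminant_ids):
            raise ValueError("contaminant ids overlap community ids")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def sample_community(richness: int, model: str = "lognormal", *, geometric_ratio: float = 0.5,
                     lognormal_sigma: float = 2.0, seed: int = 0) -> np.ndarray:
    """Draw a strictly positive relative-abundance vector summing to 1.

    ``geometric``: p_i proportional to g**(i-1), deterministic given g.
    ``lognormal``: p_i proportional to exp(z_i), z_i ~ Normal(0, sigma^2),
    sorted descending.
    """
    if richness < 1:
        raise ValueError("richness must be >= 1")
    if model == "geometric":
        g = geometric_ratio
        if not 0.0 < g <= 1.0:
            raise ValueError("geometric ratio must lie in (0, 1]")
        raw = g ** np.arange(richness, dtype=float)
    elif model == "lognormal":
        if lognormal_sigma <= 0:
            raise ValueError("lognormal sigma must be > 0")
        rng = child_rng(seed, "community")
        raw = np.exp(rng.normal(0.0, lognormal_sigma, size=richness))
        raw = np.sort(raw)[::-1]
    else:
        raise ValueError(f"unknown rank-abundance model {model!r}")
    p = raw / raw.sum()
    # guard against underflow to exactly 0 in extreme tails
    p = np.clip(p, np.finfo(float).tiny, None)
    return p / p.sum()


def _draw_depth(rng: np.random.Generator, config: SyntheticConfig) -> int:
    """Truncated-lognormal per-replicate depth (rejection sampling)."""
    for _ in range(1000):
        d = int(round(float(np.exp(rng.normal(config.depth_log_mean, config.depth_log_sd)))))
        if config.depth_min <= d <= config.depth_max:
            return d
    return int(np.clip(d, config.depth_min, config.depth_max))


def simulate_replicates(
    abundances: np.ndarray,
    n_replicates: int,
    theta: float,
    config: SyntheticConfig | None = None,
    *,
    seed: int = 0,
    taxon_prefix: str = "t",
    replicate_prefix: str = "r",
) -> TaxonTable:
    """Simulate PCR replicates from one community.

    Each replicate gets its own child RNG stream, its own Dirichlet draw
    of proportions (skipped for theta >= 1e9, the deterministic limit) and
    a multinomial read draw at a depth from the configured truncated
    lognormal; the column sum equals the drawn depth exactly.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    config = config or SyntheticConfig()
    p = np.asarray(abundances, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    S = len(p)
    taxon_ids = [f"{taxon_prefix}{i:04d}" for i in range(S)]
    replicate_ids = [f"{replicate_prefix}{j:02d}" for j in range(n_replicates)]
    counts = np.zeros((S, n_replicates), dtype=np.int64)
    for j in range(n_replicates):
        rng = child_rng(seed, "replicate", j)
        depth = _draw_depth(rng, config)
        if theta >= THETA_DETERMINISTIC:
            props = p
        else:
            props = rng.dirichlet(theta * p)
            if props.sum() <= 0 or not np.all(np.isfinite(props)):
                props = p
        counts[:, j] = rng.multinomial(depth, props / props.sum())
    return TaxonTable(taxon_ids, replicate_ids, counts)


def spike_contaminants_and_controls(
    table: TaxonTable,
    config: SyntheticConfig,
    metadata: ReplicateMetadata,
    *,
    seed: int = 0,
) -> tuple[TaxonTable, ReplicateMetadata, GroundTruth]:
    """Append contaminants, negative controls and one positive control.

    Contaminant taxa are present in each negative control with the
    configured prevalence and in true samples at a low configured
    prevalence; read counts where present are 1 + Poisson(mean - 1).  One
    positive-control column carries only the spike taxon; a ``hop_rate``
    fraction of its reads is reassigned uniformly across the other
    columns, emulating index hopping.
    """
    rng = child_rng(seed, "controls")
    n_controls = config.n_extraction_controls + config.n_pcr_controls
    contaminant_ids = [f"contam{i:02d}" for i in range(config.n_contaminants)]
    spike_taxon = "spikein"

    control_ids = [f"extctl{i:02d}" for i in range(config.n_extraction_controls)] + [
        f"pcrctl{i:02d}" for i in range(config.n_pcr_controls)
    ]
    pos_id = "posctl00"

    sample_cols = table.n_replicates
    all_rep_ids = list(table.replicate_ids) + control_ids + [pos_id]
    n_cols = len(all_rep_ids)
    S = table.n_taxa
    counts = np.zeros((S + config.n_contaminants + 1, n_cols), dtype=np.int64)
    counts[:S, :sample_cols] = table.counts

    mean = max(config.contaminant_mean_reads - 1.0, 0.0)
    for ci in range(config.n_contaminants):
        row = S + ci
        for j in range(sample_cols):
            if rng.random() < config.contaminant_prevalence_in_samples:
                counts[row, j] = 1 + rng.poisson(mean)
        for j in range(sample_cols, sample_cols + n_controls):
            if rng.random() < config.contaminant_prevalence_in_controls:
                counts[row, j] = 1 + rng.poisson(mean)

    # positive control: spike reads, some hopped to random other columns
    spike_row = S + config.n_contaminants
    pos_col = n_cols - 1
    hopped = rng.binomial(config.spike_depth, config.hop_rate) if config.hop_rate > 0 else 0
    counts[spike_row, pos_col] = config.spike_depth - hopped
    hop_targets: dict[str, int] = {}
    if hopped > 0:
        targets = rng.integers(0, n_cols - 1, size=hopped)  # any non-positive column
        for tgt in targets:
            counts[spike_row, tgt] += 1
            rid = all_rep_ids[tgt]
            hop_targets[rid] = hop_targets.get(rid, 0) + 1

    taxon_ids = list(table.taxon_ids) + contaminant_ids + [spike_taxon]
    lineage = None
    if table.lineage is not None:
        lineage = list(table.lineage) + [""] * (config.n_contaminants + 1)
    out = TaxonTable(taxon_ids, all_rep_ids, counts, lineage)

    rows = list(metadata.records.itertuples(index=False, name=None))
    for i, cid in enumerate(control_ids):
        st = (
            SampleType.EXTRACTION_CONTROL.value
            if i < config.n_extraction_controls
            else SampleType.PCR_CONTROL.value
        )
        rows.append((cid, "control", config.marker, st))
    rows.append((pos_id, "positive", config.marker, SampleType.POSITIVE_CONTROL.value))
    meta = ReplicateMetadata.from_rows(rows)

    truth = GroundTruth(
        contaminant_ids=contaminant_ids,
        spike_taxon=spike_taxon,
        hopped_reads=hop_targets,
        seed=seed,
    )
    return out, meta, truth


def simulate_experiment(config: SyntheticConfig) -> tuple[TaxonTable, ReplicateMetadata, GroundTruth]:
    """Full paper-shaped experiment: extracts x replicates + controls.

    Extracts share no taxa (taxon ids are namespaced per extract), each
    with its own community drawn from the configured rank-abundance model.
    Deterministic for a given config (including its seed).
    """
    blocks: list[TaxonTable] = []
    truth = GroundTruth(seed=config.seed)
    meta_rows: list[tuple[str, str, str, str]] = []
    for e in range(config.n_extracts):
        ext = f"E{e + 1}"
        p = sample_community(
            config.richness_per_extract,
            config.rank_abundance,
            geometric_ratio=config.geometric_ratio,
            lognormal_sigma=config.lognormal_sigma,
            seed=int(child_rng(config.seed, "extract", ext).integers(2**31)),
        )
        block = simulate_replicates(
            p,
            config.replicates_per_extract,
            config.theta,
            config,
            seed=int(child_rng(config.seed, "replicates", ext).integers(2**31)),
            taxon_prefix=f"{ext}.t",
            replicate_prefix=f"{ext}.r",
        )
        truth.abundances[ext] = [float(x) for x in p]
        truth.taxon_ids[ext] = list(block.taxon_ids)
        blocks.append(block)
        meta_rows.extend(
            (rid, ext, config.marker, SampleType.SAMPLE.value) for rid in block.replicate_ids
        )

    # block-diagonal merge
    all_taxa = [t for b in blocks for t in b.taxon_ids]
    all_reps = [r for b in blocks for r in b.replicate_ids]
    counts = np.zeros((len(all_taxa), len(all_reps)), dtype=np.int64)
    ti = 0
    ri = 0
    for b in blocks:
        counts[ti : ti + b.n_taxa, ri : ri + b.n_replicates] = b.counts
        ti += b.n_taxa
        ri += b.n_replicates
    merged = TaxonTable(all_taxa, all_reps, counts)
    meta = ReplicateMetadata.from_rows(meta_rows)

    table, meta, spike_truth = spike_contaminants_and_controls(
        merged, config, meta, seed=int(child_rng(config.seed, "spike").integers(2**31))
    )
    truth.contaminant_ids = spike_truth.contaminant_ids
    truth.spike_taxon = spike_truth.spike_taxon
    truth.hopped_reads = spike_truth.hopped_reads
    return table, meta, truth
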