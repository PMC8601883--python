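"""Prevalence-based contaminant identification and the index-hop check.

A taxon that shows up in negative controls (extraction blanks, PCR
no-template controls) more readily than in true samples is a likely
reagent or lab contaminant.  Each taxon is scored with a one-sided 2x2
association test on presence/absence (present/absent x control/sample):
Pearson chi-square with continuity correction when every expected cell is
at least 5, otherwise Fisher's exact test.  Small scores indicate
enrichment in controls; taxa scoring below the threshold (default 0.1,
the convention of the prevalence method this mirrors) are flagged and
removed wholesale.  Extraction and PCR negatives are pooled into a single
control class.

The positive-control check counts reads of an exotic spike taxon that
leak into other libraries (index hopping) and foreign reads that leak
into the positive control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tables import ReplicateMetadata, TaxonTable

__all__ = [
    "ContaminantCall",
    "prevalence_scores",
    "remove_contaminants",
    "index_hop_check",
    "IndexHopReport",
]

DEFAULT_THRESHOLD = 0.1


@dataclass
class ContaminantCall:
    taxon_id: str
    prevalence_in_samples: float
    prevalence_in_controls: float
    score: float
    is_contaminant: bool


def _one_sided_score(present_ctrl: int, n_ctrl: int, present_samp: int, n_samp: int) -> float:
    """One-sided p for presence enriched in controls over samples."""
    if present_ctrl == 0:
        return 1.0
    a, b = present_ctrl, n_ctrl - present_ctrl
    c, d = present_samp, n_samp - present_samp
    table = np.array([[a, b], [c, d]], dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    enriched = (a / n_ctrl) > (c / n_samp)
    if np.all(expected >= 5):
        chi2, p_two, _, _ = stats.chi2_contingency(table, correction=True)
        if chi2 == 0:
            return 1.0
        return p_two / 2.0 if enriched else 1.0 - p_two / 2.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def prevalence_scores(
    table: TaxonTable,
    metadata: ReplicateMetadata,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[ContaminantCall]:
    """Score every taxon for control enrichment.

    Requires at least one negative-control and one true-sample replicate
    among the table's columns; taxa absent from all controls score 1.
    """
    sample_ids = [r for r in table.replicate_ids if r in set(metadata.sample_ids)]
    control_ids = [r for r in table.replicate_ids if r in set(metadata.negative_control_ids)]
    if not control_ids:
        raise ValueError(
            "no negative-control replicates present: decontamination unavailable, skip it"
        )
    if not sample_ids:
        raise ValueError("no true-sample replicates present")
    samp_idx = [table.replicate_ids.index(r) for r in sample_ids]
    ctrl_idx = [table.replicate_ids.index(r) for r in control_ids]
    present = table.counts > 0
    calls = []
    for i, tid in enumerate(table.taxon_ids):
        ps = int(present[i, samp_idx].sum())
        pc = int(present[i, ctrl_idx].sum())
        score = _one_sided_score(pc, len(ctrl_idx), ps, len(samp_idx))
        calls.append(
            ContaminantCall(
                taxon_id=tid,
                prevalence_in_samples=ps / len(samp_idx),
                prevalence_in_controls=pc / len(ctrl_idx),
                score=score,
                is_contaminant=score < threshold,
            )
        )
    return calls


def remove_contaminants(
    table: TaxonTable,
    calls: list[ContaminantCall],
    threshold: float = DEFAULT_THRESHOLD,
    metadata: ReplicateMetadata | None = None,
) -> TaxonTable:
    """Drop flagged taxon rows entirely; with metadata, also drop control columns."""
    called = {c.taxon_id for c in calls}
    missing = [t for t in table.taxon_ids if t not in called]
    if missing:
        raise ValueError(f"calls do not cover all taxa (missing {missing[:3]}...)")
    flagged = {c.taxon_id for c in calls if c.score < threshold}
    out = table.drop_taxa(flagged)
    if metadata is not None:
        controls = set(metadata.negative_control_ids) | set(metadata.positive_control_ids)
        out = out.drop_replicates([r for r in out.replicate_ids if r in controls])
    return out


@dataclass
class IndexHopReport:
    reads_of_spike_outside_control: int
    foreign_reads_in_control: int
    rate: float


def index_hop_check(
    table: TaxonTable, metadata: ReplicateMetadata, spike_taxon: str
) -> IndexHopReport:
    """Quantify leakage of the positive-control spike taxon.

    ``rate`` is spike reads found outside positive-control columns divided
    by total spike reads.
    """
    if spike_taxon not in table.taxon_ids:
        raise ValueError(f"spike taxon {spike_taxon!r} absent from table")
    pos = set(metadata.positive_control_ids)
    if not pos & set(table.replicate_ids):
        raise ValueError("no positive-control replicate in table")
    row = table.counts[table.taxon_ids.index(spike_taxon)]
    pos_idx = [j for j, r in enumerate(table.replicate_ids) if r in pos]
    other_idx = [j for j, r in enumerate(table.replicate_ids) if r not in pos]
    outside = int(row[other_idx].sum())
    total_spike = int(row.sum())
    foreign = int(table.counts[:, pos_idx].sum() - row[pos_idx].sum())
    rate = outside / total_spike if total_spike else 0.0
    return IndexHopReport(outside, foreign, rate)
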