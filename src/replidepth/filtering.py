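"""Rarefaction to fixed read depths and per-replicate minimum-read thresholds.

Rarefaction is true subsampling WITHOUT replacement (multivariate
hypergeometric draws from the replicate's read pool), so expected rarefied
richness has the clean closed form ``E[S_d] = sum_i 1 - C(N-x_i, d)/C(N, d)``
used by the tests.  A replicate whose total falls below the requested depth
"drops out" of that grid cell (the RAR bookkeeping) rather than erroring at
pipeline level.

Thresholding is applied per replicate AFTER rarefaction; "minimum read
threshold t" retains a taxon iff its count is >= t (a taxon with exactly t
reads survives, so t=2 removes exactly the singletons).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeding import child_rng
from .tables import TaxonTable

__all__ = [
    "FilterSpec",
    "rarefy",
    "apply_min_read_threshold",
    "rarefaction_grid",
    "rarefy_table",
]


@dataclass
class FilterSpec:
    depth: int
    min_read_threshold: int = 0
    n_repeats: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.min_read_threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def rarefy(column: np.ndarray, depth: int, rng: np.random.Generator | int = 0) -> np.ndarray:
    """Subsample a count vector to exactly ``depth`` reads without replacement."""
    column = np.asarray(column, dtype=np.int64)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    total = int(column.sum())
    if total < depth:
        raise ValueError(f"depth {depth} exceeds column total {total}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if total == depth:
        return column.copy()
    return rng.multivariate_hypergeometric(column, depth).astype(np.int64)


def apply_min_read_threshold(column: np.ndarray, t: int) -> np.ndarray:
    """Zero out counts below ``t``; counts >= t are unchanged."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    column = np.asarray(column, dtype=np.int64)
    out = column.copy()
    out[out < t] = 0
    return out


def _cell_rng(seed: int, replicate_id: str, depth: int, threshold: int, repeat: int):
    return child_rng(seed, "rarefy", replicate_id, depth, threshold, repeat)


def rarefaction_grid(
    table: TaxonTable,
    depths: list[int],
    thresholds: list[int],
    R: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean observed richness per (replicate, depth, threshold) cell.

    Averages richness of threshold-after-rarefy over ``R`` independent
    draws per cell; each cell's RNG stream is derived from (seed,
    replicate id, depth, threshold, repeat) so any cell is recomputable in
    isolation.  Replicates with fewer total reads than the depth are
    flagged ``dropped`` with richness NaN.

    Returns a tidy DataFrame with columns ``replicate_id, depth,
    threshold, mean_richness, dropped``.
    """
    if list(depths) != sorted(depths):
        raise ValueError("depths must be ascending")
    rows = []
    totals = table.depths
    for j, rid in enumerate(table.replicate_ids):
        col = table.counts[:, j]
        total = int(totals[j])
        for d in depths:
            for t in thresholds:
                if total < d:
                    rows.append((rid, d, t, np.nan, True))
                    continue
                rich = 0.0
                for r in range(R):
                    sub = rarefy(col, d, _cell_rng(seed, rid, d, t, r))
                    sub = apply_min_read_threshold(sub, t)
                    rich += float((sub > 0).sum())
                rows.append((rid, d, t, rich / R, False))
    return pd.DataFrame(
        rows, columns=["replicate_id", "depth", "threshold", "mean_richness", "dropped"]
    )


def retained_counts(grid: pd.DataFrame) -> pd.DataFrame:
    """Replicates retained (not dropped) per depth — the RAR ledger."""
    g = grid.drop_duplicates(["replicate_id", "depth"])
    out = (
        g.groupby("depth")["dropped"]
        .apply(lambda s: int((~s).sum()))
        .reset_index(name="retained")
    )
    return out


def rarefy_table(
    table: TaxonTable, depth: int, threshold: int = 0, seed: int = 0
) -> TaxonTable:
    """One seeded rarefaction draw of every sufficiently deep replicate.

    Columns with total reads below ``depth`` are dropped (RAR); the
    returned table keeps all taxon rows (possibly all-zero) so tables from
    different cells stay row-aligned.
    """
    keep = []
    cols = []
    for j, rid in enumerate(table.replicate_ids):
        col = table.counts[:, j]
        if int(col.sum()) < depth:
            continue
        sub = rarefy(col, depth, _cell_rng(seed, rid, depth, threshold, 0))
        cols.append(apply_min_read_threshold(sub, threshold))
        keep.append(rid)
    counts = (
        np.column_stack(cols) if cols else np.zeros((table.n_taxa, 0), dtype=np.int64)
    )
    return TaxonTable(list(table.taxon_ids), keep, counts, table.lineage)
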