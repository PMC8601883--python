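"""PCR-replicate accumulation curves, saturation, and occupancy analyses.

The accumulation curve answers "how many more taxa does one more PCR
replicate buy?".  Replicate order is shuffled uniformly (a permutation,
not resampling) B times (default 100); the cumulative unique-taxon count
is averaged over shuffles.  The curve is "saturated" at the smallest k
whose next-step mean increment is below one taxon; if no such k exists
the sentinel "more than K" is reported, K being the number of replicates
retained after rarefaction.

Occupancy is the number of retained replicates in which a taxon is
detected at the chosen depth/threshold.  The occupancy-abundance fit
regresses occupancy on log10 mean within-replicate reads (where present)
by ordinary least squares; t, p and adjusted R^2 are invariant to the log
base, the slope scales by a constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._seeding import child_rng
from .tables import TaxonTable

__all__ = [
    "AccumulationCurve",
    "accumulation_curve",
    "occupancy_spectrum",
    "occupancy_records",
    "occupancy_abundance_fit",
]


@dataclass
class AccumulationCurve:
    k: np.ndarray  # 1..K
    mean: np.ndarray  # bootstrap-mean cumulative richness
    sd: np.ndarray
    increments: np.ndarray  # mean[k+1] - mean[k], length K-1
    saturation_k: int | None  # None = not saturated within K

    @property
    def n_replicates(self) -> int:
        return len(self.k)

    @property
    def saturation_label(self) -> str:
        if self.saturation_k is None:
            return f">{self.n_replicates}"
        return str(self.saturation_k)


def accumulation_curve(
    columns: np.ndarray | TaxonTable, B: int = 100, seed: int = 0
) -> AccumulationCurve:
    """Bootstrapped taxon accumulation over replicate additions.

    ``columns`` is a taxa x replicates count matrix (or TaxonTable) from
    one extract at one (depth, threshold) cell.
    """
    counts = columns.counts if isinstance(columns, TaxonTable) else np.asarray(columns)
    if counts.ndim != 2 or counts.shape[1] < 1:
        raise ValueError("need at least one retained replicate")
    presence = (counts > 0).T  # replicates x taxa
    K = presence.shape[0]
    rng = child_rng(seed, "accumulation")
    curves = np.empty((B, K))
    for b in range(B):
        order = rng.permutation(K)
        cum = np.logical_or.accumulate(presence[order], axis=0)
        curves[b] = cum.sum(axis=1)
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0, ddof=1) if B > 1 else np.zeros(K)
    inc = np.diff(mean)
    sat: int | None = None
    for i, d in enumerate(inc):
        if d < 1.0:
            sat = i + 1  # smallest k whose next replicate adds < 1 taxon
            break
    if sat is None and K == 1:
        sat = None
    return AccumulationCurve(np.arange(1, K + 1), mean, sd, inc, sat)


def occupancy_spectrum(
    columns: np.ndarray | TaxonTable,
) -> tuple[np.ndarray, float]:
    """Histogram of taxon occupancy 1..K and the occupancy-1 fraction.

    Returns ``(hist, singleton_fraction)`` where ``hist[k-1]`` counts taxa
    present in exactly k replicates; taxa present nowhere are excluded.
    """
    counts = columns.counts if isinstance(columns, TaxonTable) else np.asarray(columns)
    K = counts.shape[1]
    occ = (counts > 0).sum(axis=1)
    occ = occ[occ > 0]
    hist = np.bincount(occ, minlength=K + 1)[1 : K + 1]
    total = hist.sum()
    frac = float(hist[0] / total) if total else 0.0
    return hist, frac


def occupancy_records(columns: np.ndarray | TaxonTable) -> pd.DataFrame:
    """Per-taxon occupancy and mean reads where present."""
    if isinstance(columns, TaxonTable):
        counts = columns.counts
        taxa = columns.taxon_ids
    else:
        counts = np.asarray(columns)
        taxa = [f"t{i}" for i in range(counts.shape[0])]
    present = counts > 0
    occ = present.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_reads = np.where(
            occ > 0, counts.sum(axis=1) / np.maximum(occ, 1), np.nan
        )
    df = pd.DataFrame({"taxon_id": taxa, "occupancy": occ, "mean_reads": mean_reads})
    return df[df["occupancy"] > 0].reset_index(drop=True)


def occupancy_abundance_fit(records: pd.DataFrame) -> dict[str, float]:
    """OLS of occupancy on log10(mean reads where present).

    Returns slope, intercept, the slope's t statistic, its two-sided p,
    and adjusted R^2.  Requires at least 3 taxa and a non-constant
    predictor.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 taxa")
    x = np.log10(records["mean_reads"].to_numpy(dtype=float))
    y = records["occupancy"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log-abundance predictor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "t_statistic": float(fit.tvalues[1]),
        "p": float(fit.pvalues[1]),
        "adjusted_r2": float(fit.rsquared_adj),
    }
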