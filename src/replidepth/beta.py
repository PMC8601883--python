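"""Beta diversity: distances, LCBD, PCoA ordination and group dispersion.

LCBD (local contribution to beta diversity) decomposes the total
community variance across replicates: after an optional Hellinger
transform (square root of within-replicate proportions), each taxon is
centred across replicates, the squared deviations are summed per
replicate (``SS_i``) and normalised by the total (``LCBD_i = SS_i /
SS_total``, summing to 1).  Replicates whose LCBD is unusually large are
compositional outliers; significance comes from independently permuting
the values within each taxon row, with Holm adjustment across replicates.

Ordination is classical PCoA via Gower double-centring.  Jaccard
distances are non-Euclidean, so some eigenvalues are negative; the
dispersion test keeps those "imaginary" axes and follows the PERMDISP2
convention: squared distance to the group's spatial median is the real
part minus the imaginary part, floored at zero.  The spatial median
(geometric median) is found by iteratively reweighted least squares.
Bias adjustment multiplies each group's distances by sqrt(n_g/(n_g-1)).
Group homogeneity is tested by one-way ANOVA on the distances (parametric
F and a label-permutation p) with Tukey HSD pairwise follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ._seeding import child_rng
from .tables import TaxonTable

__all__ = [
    "DistanceMatrix",
    "jaccard_distance",
    "bray_curtis_distance",
    "LcbdResult",
    "lcbd",
    "PcoaResult",
    "pcoa",
    "DispersionResult",
    "beta_dispersion",
    "outlier_count_test",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.values, dtype=float)
        if D.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(D)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (D < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = D

    @property
    def n(self) -> int:
        return len(self.labels)

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])


def jaccard_distance(table: TaxonTable) -> DistanceMatrix:
    """Binary Jaccard dissimilarity between replicate columns.

    ``D_ij = 1 - |A & B| / |A | B|`` on presence/absence; a pair of empty
    columns has distance 0 by convention.
    """
    if table.n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    P = (table.counts > 0).astype(float).T  # replicates x taxa
    n = P.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        inter = (P[i] * P).sum(axis=1)
        union = ((P[i] + P) > 0).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(union > 0, 1.0 - inter / union, 0.0)
        D[i] = row
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(table.replicate_ids), D)


def bray_curtis_distance(table: TaxonTable, warn_unequal: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)`` between columns.

    Intended for rarefied (equal-sum) columns; unequal sums trigger a
    warning because depth differences then masquerade as composition
    differences.
    """
    if table.n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    sums = table.depths
    if warn_unequal and len(set(int(s) for s in sums if s > 0)) > 1:
        import warnings

        warnings.warn("Bray-Curtis on unequal column sums; rarefy first", stacklevel=2)
    X = table.counts.T.astype(float)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        num = np.abs(X[i] - X).sum(axis=1)
        den = (X[i] + X).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            D[i] = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(table.replicate_ids), D)


# ---------------------------------------------------------------------------
# LCBD


@dataclass
class LcbdResult:
    replicate_id: str
    lcbd: float
    p: float
    p_adj: float
    outlier: bool


def _transform_columns(counts: np.ndarray, transform: str) -> np.ndarray:
    X = counts.astype(float)
    if transform == "none":
        return X
    if transform == "hellinger":
        sums = X.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(sums > 0, X / np.maximum(sums, 1e-300), 0.0)
        return np.sqrt(P)
    raise ValueError(f"unknown transform {transform!r}")


def _lcbd_values(Y: np.ndarray) -> tuple[np.ndarray, float]:
    """(LCBD vector, SS_total) from a replicates x taxa matrix."""
    centred = Y - Y.mean(axis=0, keepdims=True)
    ss_i = (centred**2).sum(axis=1)
    ss_total = float(ss_i.sum())
    if ss_total <= 1e-12 * max(1.0, float((Y**2).sum())):
        return np.full(Y.shape[0], 1.0 / Y.shape[0]), 0.0
    return ss_i / ss_total, ss_total


def lcbd(
    table: TaxonTable,
    transform: str = "hellinger",
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[list[LcbdResult], float, float]:
    """Local contributions to beta diversity with permutation tests.

    Returns ``(results, SS_total, BD_total)`` where ``BD_total =
    SS_total/(n-1)``.  The null permutes values within each taxon row
    independently; ``p = (#{perm LCBD_i >= obs_i} + 1)/(n_perm + 1)``,
    Holm-adjusted; ``outlier`` means ``p_adj <= alpha``.  If all
    replicates are identical (SS_total = 0) LCBD is degenerate and a
    uniform 1/n vector is returned with p = 1.
    """
    if table.n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    Y = _transform_columns(table.counts, transform).T  # replicates x taxa
    values, ss_total = _lcbd_values(Y)
    n = table.n_replicates
    if ss_total == 0.0:
        res = [
            LcbdResult(r, 1.0 / n, 1.0, 1.0, False) for r in table.replicate_ids
        ]
        return res, 0.0, 0.0
    rng = child_rng(seed, "lcbd")
    exceed = np.zeros(n, dtype=np.int64)
    for _ in range(n_perm):
        # independent permutation within each taxon column of Y
        order = np.argsort(rng.random(Y.shape), axis=0)
        Yp = np.take_along_axis(Y, order, axis=0)
        perm_vals, _ = _lcbd_values(Yp)
        exceed += perm_vals >= values
    p = (exceed + 1) / (n_perm + 1)
    p_adj = multipletests(p, method="holm")[1]
    results = [
        LcbdResult(r, float(values[i]), float(p[i]), float(p_adj[i]), bool(p_adj[i] <= alpha))
        for i, r in enumerate(table.replicate_ids)
    ]
    return results, ss_total, ss_total / (n - 1)


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PcoaResult:
    labels: list[str]
    coordinates: np.ndarray  # n x n, scaled eigenvectors, all axes
    eigenvalues: np.ndarray  # signed, descending
    imaginary: np.ndarray  # bool mask of negative-eigenvalue axes

    @property
    def positive_coordinates(self) -> np.ndarray:
        """Axes with positive eigenvalues, for ordination plots/exports."""
        keep = self.eigenvalues > 1e-10
        return self.coordinates[:, keep]


def pcoa(D: DistanceMatrix) -> PcoaResult:
    """Classical principal-coordinates analysis (Gower double-centring).

    Negative-eigenvalue axes (non-Euclidean distances such as Jaccard)
    are retained and flagged ``imaginary``; their coordinates are scaled
    by sqrt(|eigenvalue|) for use in the PERMDISP2 dispersion
    computation.
    """
    A = -0.5 * D.values**2
    n = D.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    eigval[np.abs(eigval) < 1e-10] = 0.0
    coords = eigvec * np.sqrt(np.abs(eigval))[None, :]
    return PcoaResult(list(D.labels), coords, eigval, eigval < 0)


def _spatial_median(points: np.ndarray, tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Geometric median by Weiszfeld iteration, started at the centroid."""
    if points.shape[0] == 0:
        return np.zeros(points.shape[1])
    m = points.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(points - m, axis=1)
        if np.any(d < 1e-300):
            # median coincides with a data point; check optimality crudely
            d = np.maximum(d, 1e-12)
        w = 1.0 / d
        new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - m) < tol:
            return new
        m = new
    return m


@dataclass
class DispersionResult:
    labels: list[str]
    groups: list[str]
    distances: np.ndarray  # per-replicate distance to own group's spatial median
    group_means: dict[str, float]
    f_statistic: float
    p_parametric: float
    p_permutation: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject


def beta_dispersion(
    D: DistanceMatrix,
    groups: dict[str, str] | list[str],
    bias_adjust: bool = True,
    n_perm: int = 999,
    seed: int = 0,
) -> DispersionResult:
    """Homogeneity of group dispersions (PERMDISP2 with spatial medians).

    ``groups`` maps each replicate label to its group (or is a list
    aligned with ``D.labels``).  Singleton groups are excluded with a
    warning.  Degenerate inputs (zero variance in distances) report F = 0,
    p = 1.
    """
    if isinstance(groups, dict):
        glabels = [groups[l] for l in D.labels]
    else:
        glabels = list(groups)
        if len(glabels) != D.n:
            raise ValueError("groups length must match distance matrix")
    counts = pd.Series(glabels).value_counts()
    singletons = set(counts[counts < 2].index)
    if singletons:
        import warnings

        warnings.warn(f"excluding singleton groups: {sorted(singletons)}", stacklevel=2)
        keep = [i for i, g in enumerate(glabels) if g not in singletons]
        labels = [D.labels[i] for i in keep]
        D = D.submatrix(labels)
        glabels = [glabels[i] for i in keep]
    if len(set(glabels)) < 2:
        raise ValueError("need at least 2 non-singleton groups")

    ord_res = pcoa(D)
    real = ord_res.coordinates[:, ~ord_res.imaginary]
    imag = ord_res.coordinates[:, ord_res.imaginary]

    dist = np.zeros(D.n)
    for g in sorted(set(glabels)):
        idx = np.array([i for i, x in enumerate(glabels) if x == g])
        med_r = _spatial_median(real[idx])
        med_i = _spatial_median(imag[idx]) if imag.shape[1] else np.zeros(0)
        d_r2 = ((real[idx] - med_r) ** 2).sum(axis=1)
        d_i2 = ((imag[idx] - med_i) ** 2).sum(axis=1) if imag.shape[1] else 0.0
        d2 = np.maximum(d_r2 - d_i2, 0.0)  # PERMDISP2 imaginary correction
        d_g = np.sqrt(d2)
        if bias_adjust:
            n_g = len(idx)
            d_g = d_g * np.sqrt(n_g / (n_g - 1))
        dist[idx] = d_g

    garr = np.asarray(glabels)
    group_names = sorted(set(glabels))
    samples = [dist[garr == g] for g in group_names]
    grand = dist.mean()
    ss_total = ((dist - grand) ** 2).sum()
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b = len(group_names) - 1
    df_w = len(dist) - len(group_names)
    if ss_total <= 1e-12 or ss_within <= 1e-12 and (ss_total - ss_within) <= 1e-12:
        f_stat, p_param = 0.0, 1.0
    elif ss_within <= 1e-12:
        f_stat, p_param = np.inf, 0.0
    else:
        f_stat = ((ss_total - ss_within) / df_b) / (ss_within / df_w)
        p_param = float(stats.f.sf(f_stat, df_b, df_w))

    # permutation p: shuffle group labels of the computed distances
    rng = child_rng(seed, "betadisper")
    if np.isfinite(f_stat) and f_stat > 0:
        group_masks = [garr == g for g in group_names]
        perms = np.argsort(rng.random((n_perm, len(dist))), axis=1)
        dp = dist[perms]  # n_perm x n
        sw = np.zeros(n_perm)
        for mask in group_masks:
            sub = dp[:, mask]
            sw += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            perm_f = np.where(
                sw <= 1e-12, np.inf, ((ss_total - sw) / df_b) / (sw / df_w)
            )
        p_perm = float((np.sum(perm_f >= f_stat) + 1) / (n_perm + 1))
    else:
        p_perm = 1.0 if f_stat == 0 else 0.0

    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tk = pairwise_tukeyhsd(dist, garr)
        tukey = pd.DataFrame(
            tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
        )
        tukey = tukey.rename(columns={"p-adj": "p_adj"})
    except Exception:
        pairs = [
            (a, b)
            for i, a in enumerate(group_names)
            for b in group_names[i + 1 :]
        ]
        tukey = pd.DataFrame(
            [(a, b, np.nan, np.nan, False) for a, b in pairs],
            columns=["group1", "group2", "meandiff", "p_adj", "reject"],
        )

    return DispersionResult(
        labels=list(D.labels),
        groups=glabels,
        distances=dist,
        group_means={g: float(dist[garr == g].mean()) for g in group_names},
        f_statistic=float(f_stat),
        p_parametric=float(p_param),
        p_permutation=p_perm,
        tukey=tukey,
    )


def outlier_count_test(counts: np.ndarray | list[list[int]]) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table of outlier counts.

    Continuity (Yates) correction is applied for 2x2 tables only.
    Returns ``(statistic, dof, p)``; a zero row/column marginal is an
    error because expected counts are then undefined.
    """
    T = np.asarray(counts, dtype=float)
    if T.ndim != 2 or T.shape[0] < 2 or T.shape[1] < 2:
        raise ValueError("need a table of at least 2x2")
    if (T < 0).any() or not np.all(T == np.floor(T)):
        raise ValueError("counts must be non-negative integers")
    if np.any(T.sum(axis=0) == 0) or np.any(T.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    correction = T.shape == (2, 2)
    stat, p, dof, _ = stats.chi2_contingency(T, correction=correction)
    return float(stat), int(dof), float(p)
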