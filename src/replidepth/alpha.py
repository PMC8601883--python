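"""Alpha diversity: indices, rarefaction/extrapolation curves, outliers.

Indices
-------
Observed richness ``S_obs`` counts taxa with nonzero reads.  Shannon
entropy ``H = -sum p_i ln p_i`` uses natural log (the ecology default);
the Simpson index is the Gini-Simpson complement ``1 - sum p_i^2``.

Interpolation / extrapolation (Hill number q = 0)
-------------------------------------------------
For a replicate with ``n`` reads and abundances ``x_i`` the expected
richness of a subsample of ``m <= n`` reads has the exact hypergeometric
form::

    S(m) = S_obs - sum_i C(n - x_i, m) / C(n, m)

computed in log space.  Beyond the reference sample the curve follows the
standard sample-size-based extrapolation built on the Chao1 estimate of
the number of unseen taxa::

    f0_hat = ((n-1)/n) f1^2 / (2 f2)            (f2 > 0)
           = ((n-1)/n) f1 (f1-1) / (2 (f2+1))   (f2 = 0)
    S(n + m*) = S_obs + f0_hat [1 - (1 - f1 / (n f0_hat + f1))^{m*}]

with asymptote ``S_hat = S_obs + f0_hat``.  With no singletons the curve
is flat at ``S_obs``.  Uncertainty comes from a bootstrap on the
coverage-adjusted abundance distribution (nboot=50, 95% normal CI by
default), mirroring the conventions of the standard interpolation/
extrapolation tooling for Hill numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from ._seeding import child_rng

__all__ = [
    "AlphaRecord",
    "alpha_indices",
    "interpolated_richness",
    "extrapolated_richness",
    "chao1_unseen",
    "richness_curve",
    "bootstrap_se",
    "iqr_outliers",
    "depth_contrast_tests",
]


@dataclass
class AlphaRecord:
    replicate_id: str
    depth: int
    threshold: int
    observed: float
    shannon: float
    simpson: float


def alpha_indices(column: np.ndarray) -> tuple[int, float, float]:
    """(S_obs, Shannon H in nats, Gini-Simpson) for one count vector."""
    x = np.asarray(column, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    s_obs = int((x > 0).sum())
    if total == 0 or s_obs == 0:
        return 0, 0.0, 0.0
    p = x[x > 0] / total
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p**2).sum())
    return s_obs, shannon, simpson


def _log_choose(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(np.asarray(n, dtype=float) + 1) - gammaln(k + 1) - gammaln(
        np.asarray(n, dtype=float) - k + 1
    )


def interpolated_richness(column: np.ndarray, m: int) -> float:
    """Expected richness of an m-read subsample (m <= n), exact closed form."""
    x = np.asarray(column, dtype=np.int64)
    x = x[x > 0]
    n = int(x.sum())
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > n:
        raise ValueError(f"m={m} exceeds reference depth n={n}; use extrapolation")
    s_obs = len(x)
    if m == n:
        return float(s_obs)
    keep = (n - x) >= m  # taxa with n - x_i < m are always seen
    terms = np.zeros(s_obs)
    if keep.any():
        terms[keep] = np.exp(_log_choose(n - x[keep], m) - _log_choose(n, m))
    return float(s_obs - terms.sum())


def chao1_unseen(column: np.ndarray) -> float:
    """Chao1-type estimate of the number of unseen taxa, f0_hat."""
    x = np.asarray(column, dtype=np.int64)
    x = x[x > 0]
    n = int(x.sum())
    if n == 0:
        return 0.0
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f1 == 0:
        return 0.0
    coef = (n - 1) / n if n > 1 else 0.0
    if f2 > 0:
        return coef * f1 * f1 / (2.0 * f2)
    return coef * f1 * (f1 - 1) / (2.0 * (f2 + 1))


def extrapolated_richness(column: np.ndarray, m_star: int) -> tuple[float, float]:
    """Richness expected after ``m_star`` additional reads, and asymptote.

    Returns ``(S(n + m_star), S_hat)``; continuous with the interpolated
    curve at ``m_star = 0`` and monotone towards ``S_hat``.
    """
    if m_star < 0:
        raise ValueError("m_star must be >= 0")
    x = np.asarray(column, dtype=np.int64)
    x = x[x > 0]
    n = int(x.sum())
    s_obs = float(len(x))
    f0 = chao1_unseen(x)
    s_hat = s_obs + f0
    if f0 == 0.0 or m_star == 0:
        return (s_obs, s_hat)
    f1 = int((x == 1).sum())
    rate = f1 / (n * f0 + f1)
    return (s_obs + f0 * (1.0 - (1.0 - rate) ** m_star), s_hat)


def richness_curve(column: np.ndarray, knots: int = 40) -> pd.DataFrame:
    """q=0 rarefaction/extrapolation curve over ``knots`` sizes in [1, 2n]."""
    x = np.asarray(column, dtype=np.int64)
    n = int(x.sum())
    if n == 0:
        return pd.DataFrame({"m": [], "richness": [], "method": []})
    sizes = np.unique(np.round(np.linspace(1, 2 * n, knots)).astype(int))
    rows = []
    for m in sizes:
        if m <= n:
            rows.append((int(m), interpolated_richness(x, int(m)), "interpolated"))
        else:
            rows.append((int(m), extrapolated_richness(x, int(m) - n)[0], "extrapolated"))
    return pd.DataFrame(rows, columns=["m", "richness", "method"])


def _bootstrap_community(column: np.ndarray) -> np.ndarray:
    """Coverage-adjusted abundance distribution for the richness bootstrap.

    Observed proportions are shrunk by the estimated sample coverage and
    the estimated ``f0_hat`` unseen taxa share the coverage deficit
    equally.
    """
    x = np.asarray(column, dtype=np.int64)
    x = x[x > 0]
    n = int(x.sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if n == 0:
        return np.array([])
    if f1 == 0:
        coverage = 1.0
    else:
        denom = (n - 1) * f1 + 2 * f2
        a = (n - 1) * f1 / denom if denom > 0 else 0.0
        coverage = 1.0 - (f1 / n) * a
    p_seen = (x / n) * coverage
    f0 = int(np.ceil(chao1_unseen(x)))
    if f0 > 0 and coverage < 1.0:
        p_unseen = np.full(f0, (1.0 - coverage) / f0)
        p = np.concatenate([p_seen, p_unseen])
    else:
        p = p_seen
    total = p.sum()
    return p / total if total > 0 else p


def bootstrap_se(
    column: np.ndarray,
    m_grid: np.ndarray | list[int],
    nboot: int = 50,
    conf: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap SE and normal CI of the richness curve at each knot.

    Each bootstrap resamples ``n`` reads from the coverage-adjusted
    community and re-evaluates the interpolation/extrapolation curve; SE
    is the standard deviation over bootstraps and the CI is
    ``estimate +/- z * SE``.
    """
    if nboot < 2:
        raise ValueError("nboot must be >= 2")
    x = np.asarray(column, dtype=np.int64)
    n = int(x.sum())
    m_grid = [int(m) for m in m_grid]
    est = np.array(
        [
            interpolated_richness(x, m) if m <= n else extrapolated_richness(x, m - n)[0]
            for m in m_grid
        ]
    )
    p = _bootstrap_community(x)
    rng = child_rng(seed, "alpha-bootstrap")
    z = stats.norm.ppf(0.5 + conf / 2.0)
    if len(p) <= 1:
        se = np.zeros(len(m_grid))
    else:
        boot = np.empty((nboot, len(m_grid)))
        for b in range(nboot):
            xb = rng.multinomial(n, p)
            for k, m in enumerate(m_grid):
                boot[b, k] = (
                    interpolated_richness(xb, m)
                    if m <= n
                    else extrapolated_richness(xb, m - n)[0]
                )
        se = boot.std(axis=0, ddof=1)
    return pd.DataFrame(
        {
            "m": m_grid,
            "richness": est,
            "se": se,
            "ci_lower": est - z * se,
            "ci_upper": est + z * se,
        }
    )


def iqr_outliers(values: np.ndarray | list[float]) -> np.ndarray:
    """Boolean flags for the 1.5 x IQR rule (type-7 linear-interpolation quantiles)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least 4 values for an IQR outlier test")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # numpy default = type 7
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (v < lo) | (v > hi)


def depth_contrast_tests(
    records: pd.DataFrame,
    d1: int,
    d2: int,
    indices: tuple[str, ...] = ("observed", "shannon", "simpson"),
) -> pd.DataFrame:
    """Welch two-sided t-tests of each alpha index between two depths.

    ``records`` must be tidy with columns ``replicate_id, extract_id,
    depth`` plus the index columns.  Only replicates present at BOTH
    depths are compared (rarefaction drop-outs excluded pairwise).  The
    fold change mean(index at d2)/mean(index at d1) is reported per
    extract; extracts with fewer than two retained replicates are skipped.
    """
    rows = []
    for extract, grp in records.groupby("extract_id", sort=True):
        at1 = grp[grp["depth"] == d1].set_index("replicate_id")
        at2 = grp[grp["depth"] == d2].set_index("replicate_id")
        common = at1.index.intersection(at2.index)
        if len(common) < 2:
            continue
        for index in indices:
            a = at1.loc[common, index].to_numpy(dtype=float)
            b = at2.loc[common, index].to_numpy(dtype=float)
            if np.allclose(a, b):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_ind(b, a, equal_var=False)
            fold = float(b.mean() / a.mean()) if a.mean() != 0 else np.nan
            rows.append((extract, index, len(common), float(t_stat), float(p), fold))
    return pd.DataFrame(
        rows, columns=["extract_id", "index", "n", "t", "p", "fold_change"]
    )
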