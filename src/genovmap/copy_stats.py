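"""Copy-number matrices, retention screening and expansion outlier tests.

The screen mirrors a standard non-parametric cascade for gene-family
copy-number data: copy counts per (orthogroup, species) cell — zeros for
absent species included — are first checked for normality (Anderson–Darling;
count data are right-skewed and fail), compared across orthogroups with a
tie-corrected Kruskal–Wallis rank test, and, when that global test is
significant, each orthogroup is contrasted against the pooled rest with
Dunn's rank-based z statistic. Families whose adjusted p falls below alpha
*and* whose mean copy number exceeds the grand mean are flagged as expanded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import OrthogroupTable

__all__ = [
    "OutlierReport",
    "copy_matrix",
    "retention",
    "normality_check",
    "kruskal_wallis",
    "dunn_flag",
]

ADJUST_METHODS = ("bh", "bonferroni", "holm", "none")


@dataclass
class OutlierReport:
    """Full result of the normality -> Kruskal–Wallis -> Dunn cascade."""

    ad_statistic: float
    ad_p: float
    normality_rejected: bool
    skewness: float
    kw_h: float
    kw_df: int
    kw_p: float
    grand_mean: float
    dunn: pd.DataFrame  # orthogroup, z, p, p_adj, group_mean, flagged
    flagged: list[str] = field(default_factory=list)


def copy_matrix(table: OrthogroupTable,
                focal_species: Sequence[str]) -> pd.DataFrame:
    """Orthogroup x species integer copy-count matrix over the focal clade.

    Species with no copy get an explicit zero, so row sums equal total gene
    counts and the grand mean is total genes / (orthogroups x species).
    """
    unknown = [sp for sp in focal_species if sp not in table.species]
    if unknown:
        raise KeyError(f"focal species not in roster: {unknown}")
    data = {
        og: [table.copy_count(og, sp) for sp in focal_species]
        for og in table.orthogroup_ids
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=list(focal_species), dtype=int)


def retention(matrix: pd.DataFrame, threshold: float = 0.75) -> pd.DataFrame:
    """Per-orthogroup retention fraction and retained flag.

    fraction = (#species with >= 1 copy) / (#focal species); retained iff
    fraction >= threshold (inclusive, so presence in 75 of 99 species passes
    a 0.75 threshold).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    n_sp = matrix.shape[1]
    if n_sp == 0:
        raise ValueError("matrix has no species columns")
    frac = (matrix >= 1).sum(axis=1) / n_sp
    return pd.DataFrame({
        "n_present": (matrix >= 1).sum(axis=1),
        "fraction": frac,
        "retained": frac >= threshold,
    })


def _ad_normal_pvalue(a2: float, n: int) -> float:
    """P-value for the Anderson–Darling normality statistic with estimated
    mean and variance (Stephens' case-3 approximation)."""
    a = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a >= 32.0:  # far beyond the approximation's range; p underflows
        return 0.0
    if a >= 0.6:
        return math.exp(1.2937 - 5.709 * a + 0.0186 * a * a)
    if a >= 0.34:
        return math.exp(0.9177 - 4.279 * a - 1.38 * a * a)
    if a >= 0.2:
        return 1.0 - math.exp(-8.318 + 42.796 * a - 59.938 * a * a)
    return 1.0 - math.exp(-13.436 + 101.14 * a - 223.73 * a * a)


def normality_check(matrix: pd.DataFrame | np.ndarray,
                    alpha: float = 0.05) -> tuple[float, float, bool, float]:
    """Anderson–Darling normality test on the pooled copy-count cells.

    Returns ``(A2, p, reject, skewness)``. A constant vector is degenerate
    (zero variance) and is reported as an automatic rejection with p = 0.
    Fewer than 8 observations is an error: the p approximation is unstable.
    """
    x = np.asarray(matrix, dtype=float).ravel()
    if x.size < 8:
        raise ValueError(f"need >= 8 observations, got {x.size}")
    skew = float(stats.skew(x)) if np.ptp(x) > 0 else 0.0
    if np.ptp(x) == 0:
        return math.inf, 0.0, True, skew
    res = stats.anderson(x, dist="norm", method="interpolate")
    a2 = float(res.statistic)
    p = min(1.0, _ad_normal_pvalue(a2, x.size))
    return a2, p, p < alpha, skew


def kruskal_wallis(
    matrix: pd.DataFrame,
) -> tuple[float, int, float, float]:
    """Tie-corrected Kruskal–Wallis test across orthogroups.

    Groups are orthogroups (matrix rows); observations are per-species copy
    counts, zeros included. Returns ``(H, df, p, grand_mean)``. Identical
    groups give H = 0, p = 1.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 orthogroups (groups)")
    groups = [matrix.iloc[i].to_numpy(dtype=float)
              for i in range(matrix.shape[0])]
    grand_mean = float(np.mean(matrix.to_numpy(dtype=float)))
    df = matrix.shape[0] - 1
    if np.ptp(matrix.to_numpy(dtype=float)) == 0:
        return 0.0, df, 1.0, grand_mean  # no rank variation at all
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p), grand_mean


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "holm":
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(running, 1.0)
        return adj
    if method == "bh":
        return stats.false_discovery_control(p, method="bh")
    raise ValueError(f"unknown adjustment {method!r}; use one of "
                     f"{ADJUST_METHODS}")


def _dunn_one_vs_rest(matrix: pd.DataFrame) -> pd.DataFrame:
    """Dunn z for each orthogroup against the pooled remainder, with tie
    correction on the joint ranking."""
    values = matrix.to_numpy(dtype=float)
    k, n_sp = values.shape
    flat = values.ravel()
    n = flat.size
    ranks = stats.rankdata(flat).reshape(k, n_sp)
    # tie correction over the joint ranking
    _, counts = np.unique(flat, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    s2 = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    rows = []
    total_rank = ranks.sum()
    for i, og in enumerate(matrix.index):
        n_i = n_sp
        n_rest = n - n_i
        mean_i = ranks[i].sum() / n_i
        mean_rest = (total_rank - ranks[i].sum()) / n_rest
        se = math.sqrt(s2 * (1.0 / n_i + 1.0 / n_rest))
        z = (mean_i - mean_rest) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((og, z, p, float(values[i].mean())))
    return pd.DataFrame(rows, columns=["orthogroup", "z", "p", "group_mean"]
                        ).set_index("orthogroup")


def _dunn_all_pairs(matrix: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Dunn; each orthogroup's reported z/p is its most extreme
    pairwise contrast (per-orthogroup summary of the pairwise table)."""
    values = matrix.to_numpy(dtype=float)
    k, n_sp = values.shape
    flat = values.ravel()
    n = flat.size
    ranks = stats.rankdata(flat).reshape(k, n_sp)
    _, counts = np.unique(flat, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    s2 = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    means = ranks.mean(axis=1)
    se = math.sqrt(s2 * (2.0 / n_sp))
    best_z = np.zeros(k)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            z = (means[i] - means[j]) / se if se > 0 else 0.0
            if abs(z) > abs(best_z[i]):
                best_z[i] = z
    p = 2.0 * stats.norm.sf(np.abs(best_z))
    return pd.DataFrame({
        "z": best_z, "p": p, "group_mean": values.mean(axis=1),
    }, index=matrix.index).rename_axis("orthogroup")


def dunn_flag(
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    adjust: str = "bh",
    scheme: str = "one_vs_rest",
    two_sided_flagging: bool = False,
    require_kw: bool = True,
) -> OutlierReport:
    """Run the full outlier cascade and flag expanded orthogroups.

    Each orthogroup is compared against the pooled copy distribution of all
    remaining orthogroups (``scheme="one_vs_rest"``, default) or against each
    other orthogroup (``scheme="all_pairs"``). P-values are adjusted
    (Benjamini–Hochberg default); an orthogroup is flagged iff adjusted
    p < alpha and, unless *two_sided_flagging*, its mean exceeds the grand
    mean (expansion, not contraction). With *require_kw* (default) no flags
    are raised unless the global Kruskal–Wallis test is itself significant.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if adjust not in ADJUST_METHODS:
        raise ValueError(f"unknown adjustment {adjust!r}")
    if scheme not in ("one_vs_rest", "all_pairs"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("copy counts must be non-negative")
    if matrix.shape[1] == 0 or matrix.isna().any().any():
        raise ValueError("every orthogroup needs complete observations")

    ad_stat, ad_p, ad_reject, skew = normality_check(matrix)
    kw_h, kw_df, kw_p, grand_mean = kruskal_wallis(matrix)

    dunn = (_dunn_one_vs_rest(matrix) if scheme == "one_vs_rest"
            else _dunn_all_pairs(matrix))
    dunn["p_adj"] = _adjust(dunn["p"].to_numpy(), adjust)
    elevated = dunn["group_mean"] > grand_mean
    sig = dunn["p_adj"] < alpha
    flags = sig if two_sided_flagging else (sig & elevated)
    if require_kw and kw_p >= alpha:
        flags = flags & False
    dunn["flagged"] = flags
    return OutlierReport(
        ad_statistic=ad_stat, ad_p=ad_p, normality_rejected=ad_reject,
        skewness=skew, kw_h=kw_h, kw_df=kw_df, kw_p=kw_p,
        grand_mean=grand_mean, dunn=dunn,
        flagged=sorted(dunn.index[dunn["flagged"]].tolist()),
    )
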