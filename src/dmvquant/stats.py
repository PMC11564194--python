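"""Nonparametric cohort statistics for skewed vein measurements.

DMV counts, widths and tortuosities (and drainage-vein diameters) are
skewed, so group comparisons use the Mann-Whitney U test and
correlations use Spearman's rank correlation.  The Mann-Whitney
implementation reports the first-sample statistic ``U = #{x_i > y_j} +
ties/2`` together with the tie-corrected large-sample ``Z = (U - n1 n2 / 2) /
sigma`` (no continuity correction) and a two-sided p; for small samples
an exact p is obtained by full enumeration of the C(n, n1) group
labelings of the pooled midranks, which is valid under ties as well.

Table builders compare a two-level factor across several outcomes
(group mean +/- sd, Z, p, significance stars) and assemble a Spearman
correlation matrix between drainage-vein widths and DMV parameters.
Absent measurements are dropped pairwise per outcome — an undetected
vein is excluded from that comparison only, never zero-filled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MWUResult",
    "SpearmanResult",
    "DescriptiveStats",
    "mann_whitney",
    "spearman_corr",
    "describe",
    "format_mean_sd",
    "compare_groups",
    "correlation_table",
    "holm_adjust",
]

#: exact enumeration is used below this per-group size (auto mode)
EXACT_LIMIT = 10
#: hard cap on forced exact enumeration (C(24,12) ~ 2.7e6 labelings)
EXACT_HARD_CAP = 12


@dataclass
class MWUResult:
    u: float
    z: float
    p_two_sided: float
    n1: int
    n2: int
    method: str  # "exact" | "normal"


@dataclass
class SpearmanResult:
    rho: float
    p_two_sided: float
    n: int


@dataclass
class DescriptiveStats:
    mean: float
    sd: float | None  # None when n = 1
    min: float
    max: float
    n: int


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of the first sample: #{(i, j): x_i > y_j} plus half the
    cross-sample ties, via the midrank sum of the first sample (the
    statistic SPSS-style cohort tables report alongside Z)."""
    n1 = len(x)
    ranks = _midranks(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def _tie_sigma(pooled_ranks: np.ndarray, n1: int, n2: int) -> float:
    n = n1 + n2
    _, counts = np.unique(pooled_ranks, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return math.sqrt(max(var, 0.0))


def _exact_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating every assignment of the pooled
    midranks to group 1; the U distribution is symmetric about
    n1 n2 / 2 under exchangeability, with or without ties."""
    n = len(ranks)
    n2 = n - n1
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu) - 1e-12
    total = hits = 0
    for idx in combinations(range(n), n1):
        r1 = sum(ranks[i] for i in idx)
        u = r1 - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev:
            hits += 1
    return hits / total


def mann_whitney(x, y, mode: str = "auto",
                 continuity: bool = False) -> MWUResult:
    """Mann-Whitney U test of two independent samples.

    ``mode`` is ``"exact"`` (full enumeration, feasible up to group sizes
    of ~12), ``"normal"`` (tie-corrected Z approximation), or ``"auto"``
    (exact when both groups have at most 10 observations).  The reported
    Z carries no continuity correction, matching the large-sample
    statistic printed in SPSS-style cohort tables; ``continuity`` applies
    the 0.5 correction to the normal-approximation p only (it tightens
    small-sample agreement with the exact test).  Two-sided throughout.
    When every pooled value is tied the test is degenerate:
    U = n1 n2 / 2, Z = 0, p = 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError("mode must be auto, exact or normal")
    ranks = _midranks(np.concatenate([x, y]))
    u = _u_statistic(x, y)
    sigma = _tie_sigma(ranks, n1, n2)
    mu = n1 * n2 / 2.0
    if sigma == 0.0:  # all values tied across both samples
        return MWUResult(u=mu, z=0.0, p_two_sided=1.0, n1=n1, n2=n2,
                         method="normal")
    use_exact = mode == "exact" or (mode == "auto"
                                    and max(n1, n2) <= EXACT_LIMIT)
    if mode == "exact" and max(n1, n2) > EXACT_HARD_CAP:
        raise ValueError(
            f"exact enumeration infeasible for group sizes {n1}, {n2} "
            f"(limit {EXACT_HARD_CAP}); use mode='normal'")
    if use_exact:
        p = _exact_p(ranks, n1, u)
        return MWUResult(u=u, z=(u - mu) / sigma, p_two_sided=p,
                         n1=n1, n2=n2, method="exact")
    z = (u - mu) / sigma
    dev = max(abs(u - mu) - 0.5, 0.0) if continuity else abs(u - mu)
    p = 2.0 * sps.norm.sf(dev / sigma)
    return MWUResult(u=u, z=z, p_two_sided=min(p, 1.0), n1=n1, n2=n2,
                     method="normal")


def spearman_corr(x, y) -> SpearmanResult:
    """Spearman rank correlation (Pearson correlation of midranks) with
    the two-sided t-approximation p-value on n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("correlation undefined for a constant input")
    rho, p = sps.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p_two_sided=float(p), n=n)


def describe(values) -> DescriptiveStats:
    """Mean, sample sd (n - 1 denominator; absent when n = 1), min, max, n."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("cannot describe an empty sample")
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else None
    return DescriptiveStats(mean=float(np.mean(v)), sd=sd,
                            min=float(v.min()), max=float(v.max()),
                            n=len(v))


def format_mean_sd(d: DescriptiveStats, decimals: int = 2,
                   with_range: bool = True) -> str:
    """Cohort-table presentation, e.g. ``"12.46 ± 5.58 (1–31)"``."""
    s = f"{d.mean:.{decimals}f}"
    if d.sd is not None:
        s += f" ± {d.sd:.{decimals}f}"
    if with_range:
        s += f" ({d.min:g}–{d.max:g})"
    return s


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(cohort: pd.DataFrame, factor: str, outcomes: list,
                   mode: str = "normal", adjust: str = "none",
                   decimals: int = 2) -> pd.DataFrame:
    """Two-level group comparison table across several outcomes.

    For each outcome: group n, mean +/- sd, Mann-Whitney U, Z, two-sided
    p and significance stars (0.05 / 0.01).  Subjects with an absent
    outcome value are dropped for that outcome only (pairwise deletion);
    an all-absent outcome is skipped with a warning.  ``adjust="holm"``
    appends Holm-adjusted p-values (off by default: each test is reported
    at its nominal level, as is conventional for these cohort tables).
    """
    if factor not in cohort.columns:
        raise ValueError(f"factor column {factor!r} not in cohort")
    fac = cohort[factor].dropna()
    levels = sorted(fac.unique())
    if len(levels) != 2:
        raise ValueError(
            f"factor {factor!r} must have exactly 2 non-empty levels, "
            f"found {levels}")
    rows = []
    for outcome in outcomes:
        if outcome not in cohort.columns:
            raise ValueError(f"outcome column {outcome!r} not in cohort")
        if cohort[outcome].count() == 0:
            warnings.warn(f"outcome {outcome!r} has no observed values; "
                          "skipped")
            continue
        sub = cohort[[factor, outcome]].dropna()
        samples = [sub.loc[sub[factor] == lev, outcome].to_numpy(float)
                   for lev in levels]
        if any(len(s) == 0 for s in samples):
            empty = levels[[len(s) for s in samples].index(0)]
            raise ValueError(f"level {empty!r} of {factor!r} has no "
                             f"observations for {outcome!r}")
        res = mann_whitney(samples[0], samples[1], mode=mode)
        d1, d2 = describe(samples[0]), describe(samples[1])
        rows.append({
            "outcome": outcome, "factor": factor,
            "level_1": levels[0], "n_1": d1.n,
            "summary_1": format_mean_sd(d1, decimals, with_range=False),
            "mean_1": d1.mean, "sd_1": d1.sd,
            "level_2": levels[1], "n_2": d2.n,
            "summary_2": format_mean_sd(d2, decimals, with_range=False),
            "mean_2": d2.mean, "sd_2": d2.sd,
            "U": res.u, "Z": res.z, "p": res.p_two_sided,
            "method": res.method, "significance": _stars(res.p_two_sided),
        })
    table = pd.DataFrame(rows)
    if adjust == "holm" and len(table):
        table["p_holm"] = holm_adjust(table["p"].to_numpy())
        table["significance_holm"] = [_stars(p) for p in table["p_holm"]]
    elif adjust not in ("none", "holm"):
        raise ValueError("adjust must be 'none' or 'holm'")
    return table


def correlation_table(cohort: pd.DataFrame, row_columns: list,
                      col_columns: list) -> pd.DataFrame:
    """Spearman rho (with p) between two column sets, pairwise-complete.

    Shaped like a drainage-vein x DMV-parameter correlation matrix: one
    row per ``row_columns`` entry, one (rho, p) column pair per
    ``col_columns`` entry.
    """
    rows = []
    for rc in row_columns:
        row = {"variable": rc}
        for cc in col_columns:
            res = spearman_corr(cohort[rc].to_numpy(float),
                                cohort[cc].to_numpy(float))
            row[f"rho_{cc}"] = res.rho
            row[f"p_{cc}"] = res.p_two_sided
            row[f"n_{cc}"] = res.n
        rows.append(row)
    return pd.DataFrame(rows)
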