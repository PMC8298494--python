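"""Scored-cell quantifications: shares, per-animal statistics, Mann-Whitney.

Works on tables of scored-cell counts (unit id, category, numerator,
denominator) of the kind reported in histology and scRNA-seq figure
legends. Two percentage conventions coexist in such reports and both are
provided: one-decimal *truncation* (23.98% prints as 23.9) and rounding
(one decimal or integer); the raw fraction is always retained. Group
comparisons use the two-sided Mann-Whitney U test, evaluated by
exhaustive enumeration of rank assignments (mid-ranks for ties) for
small combined sizes and by the tie- and continuity-corrected normal
approximation above that.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

__all__ = [
    "read_scored_counts",
    "category_share",
    "per_unit_stats",
    "mann_whitney_two_sided",
    "format_percent",
]

EXACT_MAX_N = 12


def read_scored_counts(path: str) -> pd.DataFrame:
    """Read a scored-counts TSV (unit, category, numerator, denominator)."""
    t = pd.read_csv(path, sep="\t", comment="#")
    return validate_scored_counts(t)


def validate_scored_counts(t: pd.DataFrame) -> pd.DataFrame:
    required = {"unit", "category", "numerator", "denominator"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"scored-counts table missing columns: {sorted(missing)}")
    if ((t["numerator"] < 0) | (t["numerator"] > t["denominator"])).any():
        raise ValueError("need 0 <= numerator <= denominator in every row")
    return t


def format_percent(x: float, fmt: str) -> float:
    """Format a percentage: 'truncate1', 'round1' or 'round0'."""
    if fmt == "truncate1":
        return float(np.floor(x * 10 + 1e-9) / 10)
    if fmt == "round1":
        return float(round(x, 1))
    if fmt == "round0":
        return float(round(x))
    raise ValueError(f"unknown format {fmt!r}")


def category_share(
    t: pd.DataFrame, mode: str = "share_of_total", fmt: str = "truncate1"
) -> pd.DataFrame:
    """Pooled percentage per category.

    ``share_of_total``: categories partition one pool; each percent is
    100 * its pooled numerator / the summed numerators. ``share_of_
    denominator``: 100 * pooled numerator / pooled denominator per
    category. Both the raw fraction and the formatted percent are
    returned.
    """
    t = validate_scored_counts(t)
    pooled = t.groupby("category", sort=False)[["numerator", "denominator"]].sum()
    if mode == "share_of_total":
        total = pooled["numerator"].sum()
        if total == 0:
            raise ValueError("zero total count")
        frac = pooled["numerator"] / total
    elif mode == "share_of_denominator":
        if (pooled["denominator"] == 0).any():
            raise ValueError("zero denominator for some category")
        frac = pooled["numerator"] / pooled["denominator"]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = pd.DataFrame(
        {
            "numerator": pooled["numerator"],
            "denominator": pooled["denominator"],
            "fraction": frac,
            "percent": [format_percent(100 * f, fmt) for f in frac],
        }
    )
    return out


def per_unit_stats(t: pd.DataFrame) -> pd.DataFrame:
    """Per-category mean +/- s.e.m. of per-unit percentages.

    Each unit (animal/donor/dataset) contributes one percentage,
    100 * numerator / denominator; the s.e.m. is the sample standard
    deviation over units divided by sqrt(n), reported as NaN for n = 1.
    """
    t = validate_scored_counts(t)
    rows = []
    for cat, sub in t.groupby("category", sort=False):
        pct = 100.0 * sub["numerator"] / sub["denominator"]
        n = len(pct)
        sem = float(pct.std(ddof=1) / sqrt(n)) if n > 1 else float("nan")
        rows.append(
            {
                "category": cat,
                "n_units": n,
                "mean_percent": float(pct.mean()),
                "sem_percent": sem,
                "unit_percents": list(pct),
            }
        )
    return pd.DataFrame(rows).set_index("category")


def _u_statistic(ranks: np.ndarray, idx_a: tuple[int, ...], n_a: int) -> float:
    return float(ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_exact(a, b) -> float:
    """Two-sided exact p by enumerating all rank assignments (mid-rank ties).

    p = min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))) over the uniform
    distribution of group-A index choices.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = _u_statistic(ranks, tuple(range(n_a)), n_a)
    n = n_a + n_b
    n_total = comb(n, n_a)
    le = ge = 0
    eps = 1e-9
    for idx in combinations(range(n), n_a):
        u = _u_statistic(ranks, idx, n_a)
        if u <= u_obs + eps:
            le += 1
        if u >= u_obs - eps:
            ge += 1
    p = 2.0 * min(le, ge) / n_total
    return min(1.0, p)


def mann_whitney_two_sided(a, b) -> float:
    """Two-sided Mann-Whitney p: exact enumeration for combined n <= 12,
    tie/continuity-corrected normal approximation above."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(a) + len(b) <= EXACT_MAX_N:
        return mann_whitney_exact(a, b)
    return float(
        mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=True).pvalue
    )
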