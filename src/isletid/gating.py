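"""Hormone gating: density antimode thresholds and per-cell identity.

For each hormone gene (Gcg, Ins2, Ppy, Sst — or the human orthologs), the
distribution of log-normalized expression across the whole dataset is
bimodal: a non-expressing mode near zero and an expressing mode at high
values. A Gaussian kernel density estimate is computed over the pooled
values (zeros included), the two principal modes are located, and the
local density minimum between them — the antimode — becomes the
expression threshold. A cell expresses a hormone iff its value is
strictly higher than that hormone's antimode. The combination of
expressed hormones is the cell's identity; cells expressing none are
flagged non-endocrine and dropped downstream. Finally, a cluster
consistency filter keeps monohormonal cells only inside their own
cell-type cluster and Ppy-bihormonal cells only inside the designated
bihormonal cluster.

Bimodality amplitude, (h_low - h_anti) / h_low with h_low the smaller
principal-mode height and h_anti the antimode height, quantifies how
separated the modes are; thresholds with amplitude at or below the floor
are flagged low-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .io_qc import NormalizedMatrix

__all__ = [
    "DensityCurve",
    "AntimodeResult",
    "HormoneThresholds",
    "UnimodalError",
    "DegenerateDistributionError",
    "ConfigurationError",
    "estimate_density",
    "find_antimode",
    "hormone_thresholds",
    "assign_hormone_status",
    "assign_identity",
    "ppy_anchored_label",
    "cluster_consistency_filter",
    "BIHORMONAL_SENTINEL",
]

MIN_VALUES = 100
BIHORMONAL_SENTINEL = "bihormonal"


class UnimodalError(ValueError):
    """Fewer than two principal modes: no antimode exists."""


class DegenerateDistributionError(ValueError):
    """All values identical: no density can be estimated."""


class ConfigurationError(ValueError):
    """Missing hormone gene or unmapped cluster label."""


@dataclass
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class AntimodeResult:
    threshold: float
    amplitude: float
    mode_locations: tuple[float, float]
    mode_heights: tuple[float, float]
    antimode_height: float
    low_confidence: bool


@dataclass
class HormoneThresholds:
    """Per-hormone antimode thresholds with their density curves."""

    per_hormone: dict[str, AntimodeResult] = field(default_factory=dict)
    curves: dict[str, DensityCurve] = field(default_factory=dict)

    def threshold(self, hormone: str) -> float:
        return self.per_hormone[hormone].threshold

    def to_dict(self) -> dict:
        return {
            h: {
                "threshold": r.threshold,
                "amplitude": r.amplitude,
                "mode_locations": list(r.mode_locations),
                "mode_heights": list(r.mode_heights),
                "antimode_height": r.antimode_height,
                "low_confidence": r.low_confidence,
            }
            for h, r in self.per_hormone.items()
        }


def estimate_density(
    values: np.ndarray,
    bandwidth: float | None = None,
    grid_size: int = 512,
) -> DensityCurve:
    """Gaussian KDE on an even grid, Silverman's rule by default.

    For non-negative data (the usual case: log-normalized expression) the
    kernel mass leaking below zero is reflected back, so the curve on
    [0, max] integrates to ~1 and the zero spike forms a proper boundary
    mode. ``bandwidth`` overrides the rule with a value in data units.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < MIN_VALUES:
        raise ValueError(
            f"need at least {MIN_VALUES} values for a reliable threshold, got {values.size}"
        )
    sd = values.std(ddof=1)
    if sd == 0:
        raise DegenerateDistributionError("all values identical; density is degenerate")
    if bandwidth is None:
        kde = gaussian_kde(values, bw_method="silverman")
    else:
        kde = gaussian_kde(values, bw_method=bandwidth / sd)
    bw = float(kde.factor * sd)
    lo, hi = float(values.min()), float(values.max())
    if lo >= 0.0:
        grid = np.linspace(0.0, hi, grid_size)
        density = kde(grid) + kde(-grid)  # boundary reflection at 0
    else:
        grid = np.linspace(lo - 3 * bw, hi + 3 * bw, grid_size)
        density = kde(grid)
    return DensityCurve(grid=grid, density=density, bandwidth=bw)


def _local_maxima(density: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima, boundary points included."""
    n = density.size
    interior = np.where((density[1:-1] > density[:-2]) & (density[1:-1] > density[2:]))[0] + 1
    idx = list(interior)
    if n >= 2 and density[0] > density[1]:
        idx.insert(0, 0)
    if n >= 2 and density[-1] > density[-2]:
        idx.append(n - 1)
    return np.array(sorted(idx), dtype=int)


def find_antimode(curve: DensityCurve, amplitude_floor: float = 0.05) -> AntimodeResult:
    """Antimode between the two principal (highest) modes of a curve.

    Local maxima are found by the sign change of the first difference;
    the two with the greatest density are the principal modes, and the
    threshold is the grid point of minimum density strictly between
    them. Raises :class:`UnimodalError` when fewer than two maxima exist
    (the caller may widen the bandwidth or abort).
    """
    maxima = _local_maxima(curve.density)
    if maxima.size < 2:
        raise UnimodalError("density has fewer than two local maxima")
    top2 = maxima[np.argsort(curve.density[maxima])[-2:]]
    i1, i2 = int(top2.min()), int(top2.max())
    inner = np.arange(i1 + 1, i2)
    if inner.size == 0:
        raise UnimodalError("principal modes are adjacent on the grid")
    j = inner[np.argmin(curve.density[inner])]
    h1, h2 = float(curve.density[i1]), float(curve.density[i2])
    h_low = min(h1, h2)
    h_anti = float(curve.density[j])
    amplitude = (h_low - h_anti) / h_low if h_low > 0 else 0.0
    return AntimodeResult(
        threshold=float(curve.grid[j]),
        amplitude=float(amplitude),
        mode_locations=(float(curve.grid[i1]), float(curve.grid[i2])),
        mode_heights=(h1, h2),
        antimode_height=h_anti,
        low_confidence=amplitude <= amplitude_floor,
    )


def hormone_thresholds(
    nm: NormalizedMatrix,
    hormones: list[str],
    bandwidth: float | None = None,
    amplitude_floor: float = 0.05,
) -> HormoneThresholds:
    """Estimate the antimode threshold for each hormone gene, dataset-wide."""
    out = HormoneThresholds()
    for h in hormones:
        if h not in nm.gene_names:
            raise ConfigurationError(f"hormone gene {h!r} not present in the matrix")
        curve = estimate_density(nm.row(h), bandwidth=bandwidth)
        out.curves[h] = curve
        out.per_hormone[h] = find_antimode(curve, amplitude_floor=amplitude_floor)
    return out


def assign_hormone_status(
    nm: NormalizedMatrix, hormones: list[str], thresholds: HormoneThresholds
) -> pd.DataFrame:
    """Cells x hormones boolean table: value strictly above the antimode."""
    status = {}
    for h in hormones:
        if h not in nm.gene_names:
            raise ConfigurationError(f"hormone gene {h!r} not present in the matrix")
        status[h] = nm.row(h) > thresholds.threshold(h)
    return pd.DataFrame(status, index=nm.cell_ids)


def ppy_anchored_label(hormones: tuple[str, ...]) -> str:
    """Label with Ppy first, as in Ppy-anchored views (e.g. 'Ppy+Gcg')."""
    if not hormones:
        return "none"
    anchored = [h for h in hormones if h.lower() == "ppy"]
    rest = sorted(h for h in hormones if h.lower() != "ppy")
    return "+".join(anchored + rest)


def assign_identity(status: pd.DataFrame) -> pd.DataFrame:
    """Per-cell identity from the hormone-status table.

    The label is the sorted concatenation of expressed hormones ('none'
    for the empty set); ``endocrine`` is False exactly for 'none' cells,
    which are excluded from downstream comparisons.
    """
    hormones = list(status.columns)
    sets = [
        tuple(sorted(h for h in hormones if status.at[c, h])) for c in status.index
    ]
    labels = ["+".join(s) if s else "none" for s in sets]
    return pd.DataFrame(
        {
            "hormones": sets,
            "label": labels,
            "n_hormones": [len(s) for s in sets],
            "endocrine": [len(s) > 0 for s in sets],
        },
        index=status.index,
    )


def cluster_consistency_filter(
    ids: pd.DataFrame,
    clusters: pd.Series,
    cluster_map: dict[str, str],
    anchor: str = "Ppy",
) -> pd.DataFrame:
    """Keep cells whose identity is compatible with their cluster.

    ``cluster_map`` maps each cluster label to its expected identity: a
    single hormone label for a monohormonal cluster or the sentinel
    ``'bihormonal'`` for the hybrid cluster. Monohormonal cells are
    retained iff their hormone matches the cluster's expected type;
    bihormonal cells containing the anchor hormone (Ppy) are retained
    iff they sit in the bihormonal cluster. Everything else — 'none'
    cells, bihormonal cells without the anchor — is excluded, with the
    reason recorded per cell.
    """
    unmapped = set(pd.unique(clusters)) - set(cluster_map)
    if unmapped:
        raise ConfigurationError(f"unmapped cluster labels: {sorted(unmapped)}")
    retained = []
    reasons = []
    for c in ids.index:
        hset = ids.at[c, "hormones"]
        expected = cluster_map[clusters.loc[c]]
        if len(hset) == 0:
            retained.append(False)
            reasons.append("non_endocrine")
        elif len(hset) == 1:
            if expected == hset[0]:
                retained.append(True)
                reasons.append("")
            else:
                retained.append(False)
                reasons.append("cluster_mismatch")
        elif anchor in hset:
            if expected == BIHORMONAL_SENTINEL:
                retained.append(True)
                reasons.append("")
            else:
                retained.append(False)
                reasons.append("outside_bihormonal_cluster")
        else:
            retained.append(False)
            reasons.append("bihormonal_without_anchor")
    out = ids.copy()
    out["cluster"] = clusters.loc[ids.index].to_numpy()
    out["retained"] = retained
    out["exclusion_reason"] = reasons
    return out
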