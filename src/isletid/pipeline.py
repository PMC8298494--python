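"""End-to-end single-cell identity pipeline.

Chains QC -> log-normalization -> hormone gating -> cluster consistency
-> pairwise NB-GLM DE -> identity-set derivation -> bihormonal overlap
reporting, for an islet dataset with the four hormones Gcg, Ins2, Ppy
and Sst (or orthologous names). Each stage is also available separately
from its own module; this driver exists so scripted analyses and the
CLI agree on the orchestration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .gating import (
    BIHORMONAL_SENTINEL,
    HormoneThresholds,
    assign_hormone_status,
    assign_identity,
    cluster_consistency_filter,
    hormone_thresholds,
    ppy_anchored_label,
)
from .identity import IdentitySet, OverlapReport, bihormonal_overlap, derive_id_genes
from .io_qc import CountMatrix, QCConfig, QCReport, log_normalize, qc_filter
from .sc_de import DEConfig, run_de, upregulated_set

__all__ = ["PipelineResult", "sc_identity_pipeline", "DEFAULT_CLUSTER_MAP", "HORMONE_TYPE"]

HORMONE_TYPE = {"Gcg": "alpha", "Ins2": "beta", "Sst": "delta", "Ppy": "gamma"}
DEFAULT_CLUSTER_MAP = {
    "alpha": "Gcg",
    "beta": "Ins2",
    "delta": "Sst",
    "gamma": "Ppy",
    "bihormonal": BIHORMONAL_SENTINEL,
}


@dataclass
class PipelineResult:
    qc_report: QCReport
    thresholds: HormoneThresholds
    identities: pd.DataFrame  # per retained-input cell: label, cluster, retained, reason
    groups: dict  # label -> list of retained cell ids
    de_tables: dict  # (label_a, label_b) -> DE table
    id_sets: dict  # hormone -> IdentitySet
    bihorm_up: dict = field(default_factory=dict)  # anchored label -> upregulated genes
    overlaps: dict = field(default_factory=dict)  # anchored label -> OverlapReport
    shares: pd.DataFrame | None = None  # bihormonal shares of the anchor pool


def _reverse(res: pd.DataFrame) -> pd.DataFrame:
    out = res.copy()
    out["logfc"] = -out["logfc"]
    return out


def sc_identity_pipeline(
    m: CountMatrix,
    hormones: tuple[str, ...] = ("Gcg", "Ins2", "Ppy", "Sst"),
    anchor: str = "Ppy",
    cluster_map: dict | None = None,
    qc: QCConfig | None = None,
    de_cfg: DEConfig | None = None,
    bandwidth: float | None = None,
) -> PipelineResult:
    """Run the full single-cell identity analysis on a raw count matrix.

    Derives the identity gene set of every hormone type from the six
    pairwise monohormonal comparisons, then profiles each
    anchor-bihormonal population (e.g. Ppy+Gcg) against monohormonal
    anchor cells and intersects its upregulated genes with the partner
    type's ID set.
    """
    if cluster_map is None:
        cluster_map = DEFAULT_CLUSTER_MAP
    if de_cfg is None:
        de_cfg = DEConfig()
    filtered, qc_report = qc_filter(m, qc)
    nm = log_normalize(filtered)
    thr = hormone_thresholds(nm, list(hormones), bandwidth=bandwidth)
    status = assign_hormone_status(nm, list(hormones), thr)
    ids = assign_identity(status)
    ids = cluster_consistency_filter(
        ids, filtered.cell_meta["cluster"], cluster_map, anchor=anchor
    )

    retained = ids[ids["retained"]]
    groups: dict[str, list] = {}
    for label, sub in retained.groupby("label"):
        groups[label] = list(sub.index)

    # pairwise DE among monohormonal types (each pair once, both directions)
    up: dict[str, dict[str, list[str]]] = {h: {} for h in hormones}
    de_tables: dict[tuple[str, str], pd.DataFrame] = {}
    mono = [h for h in hormones if h in groups]
    for i, ha in enumerate(mono):
        for hb in mono[i + 1 :]:
            res = run_de(filtered, nm, groups[ha], groups[hb], de_cfg)
            de_tables[(ha, hb)] = res
            up[ha][hb] = upregulated_set(res, de_cfg)
            up[hb][ha] = upregulated_set(_reverse(res), de_cfg)

    id_sets: dict[str, IdentitySet] = {}
    for h in mono:
        others = [o for o in mono if o != h]
        if len(others) == 3:
            id_sets[h] = derive_id_genes(
                up[h][others[0]],
                up[h][others[1]],
                up[h][others[2]],
                cell_type=HORMONE_TYPE.get(h, h),
                provenance={"comparisons": [f"{h}_vs_{o}" for o in others]},
            )

    # bihormonal populations vs monohormonal anchor cells
    bihorm_up: dict[str, list[str]] = {}
    overlaps: dict[str, OverlapReport] = {}
    share_rows = []
    n_pool = len(groups.get(anchor, []))
    bihorm_labels = [
        lbl for lbl in groups if lbl != anchor and anchor in lbl.split("+") and "+" in lbl
    ]
    n_pool_total = n_pool + sum(len(groups[lbl]) for lbl in bihorm_labels)
    for lbl in sorted(bihorm_labels):
        partner = [h for h in lbl.split("+") if h != anchor][0]
        anchored = ppy_anchored_label(tuple(lbl.split("+")))
        res = run_de(filtered, nm, groups[lbl], groups[anchor], de_cfg)
        de_tables[(lbl, anchor)] = res
        up_genes = upregulated_set(res, de_cfg)
        bihorm_up[anchored] = up_genes
        if up_genes and partner in id_sets and len(id_sets[partner]):
            overlaps[anchored] = bihormonal_overlap(up_genes, id_sets[partner])
        share_rows.append(
            {
                "label": anchored,
                "n_cells": len(groups[lbl]),
                "share_of_pool": len(groups[lbl]) / n_pool_total if n_pool_total else float("nan"),
            }
        )
    shares = pd.DataFrame(share_rows).set_index("label") if share_rows else None
    return PipelineResult(
        qc_report=qc_report,
        thresholds=thr,
        identities=ids,
        groups=groups,
        de_tables=de_tables,
        id_sets=id_sets,
        bihorm_up=bihorm_up,
        overlaps=overlaps,
        shares=shares,
    )
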