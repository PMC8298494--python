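"""Loaders for the small published count tables shipped with the package.

These are transcriptions of printed scored-cell counts (figure-legend
numbers), not raw data: cell counts per category for the Ppy+ pool of
the mouse single-cell dataset, the Ppy-negative fraction of reprogrammed
gamma-cells, and the published ID-set overlap counts. Gene-level inputs
are never shipped; they are simulated (see :mod:`isletid.sim`).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .identity import IdentitySet, OverlapReport
from .quantify import validate_scored_counts

__all__ = [
    "load_scored_counts",
    "load_overlap_counts",
    "overlap_from_counts",
    "SCORED_TABLES",
]

SCORED_TABLES = ("ppy_pool_sc_counts", "reprogrammed_ppy_loss_counts")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("isletid.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_scored_counts(name: str) -> pd.DataFrame:
    """Load one of the shipped scored-cell count tables by name."""
    if name not in SCORED_TABLES:
        raise KeyError(f"unknown table {name!r}; available: {SCORED_TABLES}")
    return validate_scored_counts(_read(name))


def load_overlap_counts() -> pd.DataFrame:
    """Published ID-set overlap counts (per comparison)."""
    return _read("id_overlap_counts").set_index("comparison")


def overlap_from_counts(n_overlap: int, n_id: int, n_up: int | None = None) -> OverlapReport:
    """Reconstruct an :class:`OverlapReport` from printed counts.

    Placeholder gene names (``g1`` ...) stand in for the unpublished
    lists; the percentages depend only on the counts. When the
    upregulated-list size was not printed, ``n_up`` defaults to the
    overlap itself, leaving ``pct_of_id`` (the only published view for
    those rows) unaffected.
    """
    if n_up is None:
        n_up = n_overlap
    id_genes = [f"g{i + 1}" for i in range(n_id)]
    up_genes = id_genes[:n_overlap] + [f"u{i + 1}" for i in range(n_up - n_overlap)]
    rep = OverlapReport(
        n_overlap=n_overlap, n_id=n_id, n_up=n_up, genes=id_genes[:n_overlap]
    )
    # sanity: consistent with recomputing through the set operation
    from .identity import bihormonal_overlap

    check = bihormonal_overlap(up_genes, IdentitySet(cell_type="", genes=id_genes))
    assert check.n_overlap == rep.n_overlap
    return rep
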