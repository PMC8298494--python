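"""Identity gene sets, hybrid-identity overlaps and cross-set logic.

A cell type's identity (ID) genes are the genes upregulated in that type
against *each* of the other three islet types in pairwise DE — the
intersection of the three upregulated sets. Bihormonal cells are then
profiled by intersecting the genes upregulated in a bihormonal
population (vs monohormonal Ppy cells) with the partner type's ID set;
the report carries both percentage views (share of the ID set and share
of the upregulated list). Cross-dataset and cross-species comparisons
intersect upregulated sets after mapping gene names into a common
namespace (uppercase human symbols by default, via an ortholog table),
and pathway concordance keeps only pathways regulated in the same
direction in two datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "IdentitySet",
    "OverlapReport",
    "ConcordanceResult",
    "derive_id_genes",
    "bihormonal_overlap",
    "cross_dataset_intersection",
    "pathway_concordance",
    "read_gene_list",
    "write_gene_list",
    "read_ortholog_map",
    "read_pathway_table",
]

logger = logging.getLogger(__name__)

DIRECTIONS = ("activated", "inhibited")


@dataclass
class IdentitySet:
    """An ordered cell-type identity gene list with its provenance."""

    cell_type: str
    genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("identity genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class OverlapReport:
    """Overlap between an upregulated gene list and an ID set.

    ``pct_of_id`` (100 * n_overlap / n_id) is conventionally printed as
    a rounded integer, ``pct_of_up`` (100 * n_overlap / n_up) to one
    decimal; the raw fractions are what analyses should consume.
    """

    n_overlap: int
    n_id: int
    n_up: int
    genes: list[str]

    @property
    def pct_of_id(self) -> float:
        return 100.0 * self.n_overlap / self.n_id

    @property
    def pct_of_up(self) -> float:
        return 100.0 * self.n_overlap / self.n_up

    @property
    def pct_of_id_display(self) -> int:
        return int(round(self.pct_of_id))

    @property
    def pct_of_up_display(self) -> float:
        return round(self.pct_of_up, 1)


def derive_id_genes(
    up_a: list[str],
    up_b: list[str],
    up_c: list[str],
    cell_type: str = "",
    provenance: dict | None = None,
) -> IdentitySet:
    """Intersect the three pairwise upregulated sets of one focal type.

    The output order follows ``up_a`` (typically descending logFC). A
    gene failing the logFC floor in even one comparison is absent from
    its upregulated set and hence from the identity set. An empty
    intersection is a valid result.
    """
    common = set(up_a) & set(up_b) & set(up_c)
    ordered = [g for g in up_a if g in common]
    return IdentitySet(
        cell_type=cell_type,
        genes=ordered,
        provenance=provenance or {"n_inputs": [len(up_a), len(up_b), len(up_c)]},
    )


def bihormonal_overlap(up_bihorm: list[str], id_set: IdentitySet) -> OverlapReport:
    """Overlap of a bihormonal population's upregulated genes with an ID set."""
    if len(up_bihorm) == 0 or len(id_set) == 0:
        raise ValueError("both gene lists must be non-empty")
    idg = set(id_set.genes)
    genes = [g for g in up_bihorm if g in idg]
    return OverlapReport(
        n_overlap=len(set(genes)),
        n_id=len(id_set),
        n_up=len(set(up_bihorm)),
        genes=genes,
    )


def _map_gene(gene: str, mapping: dict[str, list[str]] | None, policy: str) -> list[str]:
    if mapping is not None and gene in mapping:
        targets = mapping[gene]
        if len(targets) == 1:
            return targets
        if policy == "expand":
            return targets
        return []  # ambiguous, dropped
    # already in the common namespace (uppercase human symbol)?
    if gene.upper() == gene:
        return [gene]
    return []


def cross_dataset_intersection(
    up_sets: list[list[str]],
    ortholog_map: dict[str, list[str]] | pd.DataFrame | None = None,
    policy: str = "drop",
) -> set[str]:
    """Intersect upregulated sets after mapping to a common namespace.

    Genes found in the ortholog map are translated; genes absent from it
    are kept only when they already look like common-namespace symbols
    (all-uppercase). One-to-many mappings are dropped by default or
    expanded with ``policy='expand'``. Unmapped genes are dropped with a
    logged count. Associative and commutative over its inputs.
    """
    if len(up_sets) < 2:
        raise ValueError("need at least two gene sets to intersect")
    if policy not in ("drop", "expand"):
        raise ValueError("policy must be 'drop' or 'expand'")
    mapping: dict[str, list[str]] | None
    if isinstance(ortholog_map, pd.DataFrame):
        src, dst = ortholog_map.columns[:2]
        mapping = {}
        for s, d in zip(ortholog_map[src], ortholog_map[dst]):
            mapping.setdefault(str(s), []).append(str(d))
    else:
        mapping = ortholog_map
    mapped_sets = []
    for i, genes in enumerate(up_sets):
        mapped: set[str] = set()
        n_unmapped = 0
        for g in genes:
            targets = _map_gene(g, mapping, policy)
            if targets:
                mapped.update(targets)
            else:
                n_unmapped += 1
        if n_unmapped:
            logger.warning("set %d: %d gene(s) could not be mapped and were dropped", i, n_unmapped)
        mapped_sets.append(mapped)
    out = mapped_sets[0]
    for s in mapped_sets[1:]:
        out = out & s
    return out


@dataclass
class ConcordanceResult:
    concordant: pd.DataFrame
    discordant: pd.DataFrame
    one_sided: pd.DataFrame


def _normalize_pathways(table: pd.DataFrame, tag: str) -> pd.DataFrame:
    t = table.copy()
    t["pathway_key"] = t["pathway"].astype(str).str.strip().str.casefold()
    t["direction"] = t["direction"].astype(str).str.strip().str.lower()
    bad = ~t["direction"].isin(DIRECTIONS)
    if bad.any():
        raise ValueError(f"{tag}: invalid direction values: {sorted(t.loc[bad, 'direction'].unique())}")
    dup = t.groupby("pathway_key")["direction"].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        raise ValueError(f"{tag}: conflicting directions within one table: {list(conflicts.index)}")
    return t.drop_duplicates("pathway_key")


def pathway_concordance(table_a: pd.DataFrame, table_b: pd.DataFrame) -> ConcordanceResult:
    """Pathways modulated in the very same direction in both datasets.

    Inputs are tables with columns ``pathway``, ``direction``
    ('activated'/'inhibited') and optionally ``score``. Pathway names
    are compared case- and whitespace-insensitively. Discordant and
    one-sided pathways are reported separately.
    """
    a = _normalize_pathways(table_a, "table A")
    b = _normalize_pathways(table_b, "table B")
    merged = a.merge(b, on="pathway_key", how="outer", suffixes=("_a", "_b"), indicator=True)
    both = merged[merged["_merge"] == "both"]
    same = both["direction_a"] == both["direction_b"]
    concordant = pd.DataFrame(
        {"pathway": both.loc[same, "pathway_a"], "direction": both.loc[same, "direction_a"]}
    ).reset_index(drop=True)
    discordant = pd.DataFrame(
        {
            "pathway": both.loc[~same, "pathway_a"],
            "direction_a": both.loc[~same, "direction_a"],
            "direction_b": both.loc[~same, "direction_b"],
        }
    ).reset_index(drop=True)
    only = merged[merged["_merge"] != "both"]
    one_sided = pd.DataFrame(
        {
            "pathway": only["pathway_a"].fillna(only["pathway_b"]),
            "source": only["_merge"].map({"left_only": "A", "right_only": "B"}),
        }
    ).reset_index(drop=True)
    return ConcordanceResult(concordant=concordant, discordant=discordant, one_sided=one_sided)


# ---------------------------------------------------------------------------
# Plain-text formats
# ---------------------------------------------------------------------------

def read_gene_list(path: str) -> list[str]:
    """One gene per line; lines starting with '#' are provenance comments."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split("\t")[0])
    return genes


def write_gene_list(genes: list[str], path: str, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for g in genes:
            fh.write(f"{g}\n")


def read_ortholog_map(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("ortholog map needs two columns (source, target)")
    return df


def read_pathway_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "pathway" not in df.columns or "direction" not in df.columns:
        raise ValueError("pathway table needs 'pathway' and 'direction' columns")
    return df
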