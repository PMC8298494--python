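"""Pairwise single-cell differential expression (NB GLM, Bonferroni).

The comparison between two cell populations runs in two stages:

1. a log-fold-change pre-filter on the normalized scale — the natural
   log of the ratio of group means of expm1(value), each mean offset by
   a pseudocount of 1 — keeping genes with |logFC| >= 0.5 by default;
2. a negative-binomial GLM on the raw counts of the candidate genes,
   with the group indicator plus nuisance covariates (per-cell total
   UMIs, detected genes, and experimental replicate), Wald-tested on
   the group coefficient and Bonferroni-corrected against the total
   number of genes in the dataset, not just the candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qc import CountMatrix, NormalizedMatrix
from .nbglm import fit_nb_glm

__all__ = ["DEConfig", "prefilter_logfc", "nb_glm_test", "run_de", "upregulated_set"]

COVARIATE_CHOICES = ("n_umis", "n_genes", "replicate")


@dataclass
class DEConfig:
    """Thresholds and covariates for the single-cell DE stage."""

    min_logfc: float = 0.5  # natural-log floor applied before testing
    covariates: tuple[str, ...] = ("n_umis", "n_genes", "replicate")
    alpha: float = 0.05  # adjusted-p cutoff
    pseudocount: float = 1.0
    min_detection_frac: float = 0.0  # optional pre-test detection filter

    def __post_init__(self) -> None:
        if self.min_logfc < 0:
            raise ValueError("min_logfc must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.covariates) - set(COVARIATE_CHOICES)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


def _masks(cell_ids: pd.Index, group_a, group_b) -> tuple[np.ndarray, np.ndarray]:
    a = cell_ids.isin(group_a)
    b = cell_ids.isin(group_b)
    if not a.any() or not b.any():
        raise ValueError("both groups must be non-empty")
    if (a & b).any():
        raise ValueError("groups must be disjoint")
    return a, b


def prefilter_logfc(
    nm: NormalizedMatrix, group_a, group_b, cfg: DEConfig | None = None
) -> pd.DataFrame:
    """Per-gene logFC between two cell groups with the candidate flag.

    logFC(g) = ln((mean_A expm1(value) + pc) / (mean_B expm1(value) + pc)).
    Also reports group means on the normalized scale and detection
    fractions, used for reporting downstream.
    """
    if cfg is None:
        cfg = DEConfig()
    a, b = _masks(nm.cell_ids, group_a, group_b)
    va = nm.values[:, a]
    vb = nm.values[:, b]
    mean_expm1_a = np.asarray(va.expm1().sum(axis=1)).ravel() / a.sum()
    mean_expm1_b = np.asarray(vb.expm1().sum(axis=1)).ravel() / b.sum()
    logfc = np.log((mean_expm1_a + cfg.pseudocount) / (mean_expm1_b + cfg.pseudocount))
    pct_a = np.asarray((va > 0).sum(axis=1)).ravel() / a.sum()
    pct_b = np.asarray((vb > 0).sum(axis=1)).ravel() / b.sum()
    candidate = np.abs(logfc) >= cfg.min_logfc
    if cfg.min_detection_frac > 0:
        candidate &= np.maximum(pct_a, pct_b) >= cfg.min_detection_frac
    return pd.DataFrame(
        {
            "logfc": logfc,
            "mean_a": np.asarray(va.sum(axis=1)).ravel() / a.sum(),
            "mean_b": np.asarray(vb.sum(axis=1)).ravel() / b.sum(),
            "pct_a": pct_a,
            "pct_b": pct_b,
            "candidate": candidate,
        },
        index=nm.gene_names,
    )


def _design(m: CountMatrix, cells: np.ndarray, group: np.ndarray, cfg: DEConfig) -> np.ndarray:
    """Intercept + group indicator + standardized nuisance covariates."""
    cols = [np.ones(cells.sum()), group.astype(float)]
    totals = m.total_umis()[cells].astype(float)
    ngenes = m.detected_genes()[cells].astype(float)
    values = {"n_umis": totals, "n_genes": ngenes}
    for name in cfg.covariates:
        if name == "replicate":
            rep = pd.Categorical(m.cell_meta.loc[cells, "replicate"])
            for level in rep.categories[1:]:
                cols.append((rep == level).astype(float))
        else:
            v = values[name]
            sd = v.std()
            cols.append((v - v.mean()) / sd if sd > 0 else np.zeros_like(v))
    return np.column_stack(cols)


def nb_glm_test(
    m: CountMatrix,
    candidates: list[str],
    group_a,
    group_b,
    cfg: DEConfig | None = None,
    n_total_genes: int | None = None,
) -> pd.DataFrame:
    """Wald-test candidate genes with the batched NB GLM on raw counts.

    Bonferroni adjustment uses ``n_total_genes`` (defaults to the number
    of genes in ``m``). Non-converged genes get p = NaN and are never
    significant.
    """
    if cfg is None:
        cfg = DEConfig()
    if len(candidates) == 0:
        raise ValueError("candidate gene list is empty")
    if n_total_genes is None:
        n_total_genes = m.n_genes
    a, b = _masks(m.cell_ids, group_a, group_b)
    cells = a | b
    gidx = m.gene_names.get_indexer(candidates)
    if (gidx < 0).any():
        missing = [g for g, i in zip(candidates, gidx) if i < 0]
        raise KeyError(f"candidate genes absent from matrix: {missing[:5]}")
    y = np.asarray(m.counts[gidx][:, cells].todense(), dtype=float)
    x = _design(m, cells, a[cells], cfg)
    fit = fit_nb_glm(y, x)
    p = fit.wald_p(1)
    p[~fit.converged] = np.nan
    p_adj = np.minimum(p * n_total_genes, 1.0)
    out = pd.DataFrame(
        {
            "coef": fit.beta[:, 1],
            "se": fit.se[:, 1],
            "dispersion": fit.alpha,
            "p": p,
            "p_adj": p_adj,
            "converged": fit.converged,
        },
        index=pd.Index(candidates, name="gene"),
    )
    out.attrs["n_total_genes"] = n_total_genes
    return out


def run_de(
    m: CountMatrix,
    nm: NormalizedMatrix,
    group_a,
    group_b,
    cfg: DEConfig | None = None,
) -> pd.DataFrame:
    """Pre-filter then NB-GLM-test one pairwise comparison.

    Returns the full DE table (one row per gene of the dataset):
    ``logfc`` for every gene; test columns are NaN outside the candidate
    list. ``attrs['n_total_genes']`` records the Bonferroni family size.
    """
    if cfg is None:
        cfg = DEConfig()
    pre = prefilter_logfc(nm, group_a, group_b, cfg)
    out = pre.copy()
    out["p"] = np.nan
    out["p_adj"] = np.nan
    out["converged"] = False
    candidates = list(pre.index[pre["candidate"]])
    if candidates:
        tested = nb_glm_test(m, candidates, group_a, group_b, cfg, n_total_genes=m.n_genes)
        out.loc[tested.index, ["p", "p_adj"]] = tested[["p", "p_adj"]].to_numpy()
        out.loc[tested.index, "converged"] = tested["converged"].to_numpy()
    out.attrs["n_total_genes"] = m.n_genes
    return out


def upregulated_set(res: pd.DataFrame, cfg: DEConfig | None = None) -> list[str]:
    """Genes with logFC >= min_logfc and adjusted p <= alpha, by falling logFC."""
    if cfg is None:
        cfg = DEConfig()
    ok = (
        (res["logfc"] >= cfg.min_logfc)
        & (res["p_adj"] <= cfg.alpha)
        & res["p_adj"].notna()
    )
    sub = res.loc[ok].sort_values("logfc", ascending=False)
    return list(sub.index)
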