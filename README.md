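# isletid

Identity analysis of mono- and bihormonal pancreatic islet cells from
single-cell and bulk RNA-seq.

Pancreatic islets contain four endocrine cell types — glucagon-secreting
α-cells, insulin-secreting β-cells, somatostatin-secreting δ-cells and
the rare pancreatic-polypeptide (Ppy)-secreting γ-cells. A fraction of
γ-cells is *bihormonal*: it expresses Ppy together with glucagon,
somatostatin or insulin, and carries a hybrid transcriptional profile
that mixes identity markers of both parent types. `isletid` implements
the computational workflow used to characterize these populations from
UMI count data, together with a seeded synthetic islet generator so the
whole pipeline can be exercised and validated against planted ground
truth without access to restricted primary data.

## What the package computes

**Hormone gating by density antimodes.** For each hormone gene *h*, the
log-normalized expression `v = ln(1 + 10^4 · count / cell total)` pooled
over all cells is bimodal. A Gaussian KDE (Silverman bandwidth,
boundary-reflected at 0) locates the two principal modes; the threshold
is the antimode — the density minimum between them — and a cell
expresses *h* iff `v(h, c) > threshold(h)` (strictly). The bimodality
amplitude `(h_low − h_anti) / h_low` flags unreliable thresholds. The
combination of expressed hormones is the cell identity; a cluster
consistency filter keeps monohormonal cells only in their own cluster
and Ppy-bihormonal cells only in the designated hybrid cluster.

**Single-cell differential expression.** Pairwise comparisons use a
log-fold-change pre-filter on the normalized scale,

    logFC(g) = ln[(mean_A expm1(v) + 1) / (mean_B expm1(v) + 1)],  |logFC| ≥ 0.5,

followed by a negative-binomial GLM on raw counts (NB2,
`var = μ + α μ²`; log link) with the group indicator plus nuisance
covariates (total UMIs, detected genes, replicate), a Wald test on the
group coefficient, and Bonferroni correction against the total number
of genes in the dataset. A cell type's **identity (ID) genes** are the
intersection of its three pairwise upregulated sets; bihormonal
populations are profiled by intersecting their upregulated genes (vs
monohormonal Ppy cells) with the partner type's ID set.

**Bulk differential expression.** Median-of-ratios size factors, a
mean-count ≥ 5 filter per comparison, gene-wise NB dispersion by profile
maximum likelihood, Wald tests with Benjamini-Hochberg adjustment, and
normal-prior shrinkage of the log2 fold changes,

    LFC_shrunk = LFC_mle · σ²_prior / (σ²_prior + se²),

with DE calls at |shrunken log2FC| ≥ 1 and padj ≤ 0.05 (inclusive).

**Scored-cell quantifications.** Pooled and per-animal percentages with
mean ± s.e.m., and two-sided Mann-Whitney tests (exact enumeration with
mid-rank ties for combined n ≤ 12).

## Worked example

The shipped table `ppy_pool_sc_counts` transcribes the published scored
Ppy⁺ cell counts of the mouse single-cell dataset:

```python
from isletid.datasets import load_scored_counts
from isletid.quantify import category_share

t = load_scored_counts("ppy_pool_sc_counts")
print(category_share(t, mode="share_of_total", fmt="truncate1"))
```

```
          numerator  denominator  fraction  percent
category
Ppy            1167         1730  0.674566     67.4
Ppy+Gcg         415         1730  0.239884     23.9
Ppy+Sst          84         1730  0.048555      4.8
Ppy+Ins2         64         1730  0.036994      3.6
```

The Ppy⁺Gcg⁺, Ppy⁺Sst⁺ and Ppy⁺Ins2⁺ bihormonal subtypes make up 23.9%,
4.8% and 3.6% of the Ppy⁺ pool — the published shares.

On synthetic data the whole pipeline runs end to end and is checked
against the planted truth:

```python
from isletid.sim import SimConfig, simulate_sc
from isletid.pipeline import sc_identity_pipeline

cfg = SimConfig(n_cells=3000, n_genes=1000, n_id_genes_per_type=20, seed=2)
m, truth = simulate_sc(cfg)
res = sc_identity_pipeline(m)
print({h: round(r.threshold, 2) for h, r in res.thresholds.per_hormone.items()})
print(len(res.id_sets["Ppy"]), set(res.id_sets["Ppy"].genes) == set(truth.id_sets["gamma"]))
```

```
{'Gcg': 2.77, 'Ins2': 2.73, 'Ppy': 2.9, 'Sst': 2.93}
21 True
```

All 21 planted γ-identity genes (the Ppy hormone gene plus 20 planted
markers) are recovered exactly.

A CLI mirrors the library (`isletid simulate / qc / normalize / gate /
de / idgenes / overlap / intersect / concordance / bulkde / quantify`);
every run with a fixed config and seed writes byte-identical outputs.

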