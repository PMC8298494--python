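# Methods

This note documents the statistical models, the synthetic data the
package validates itself on, the numerical choices, and the limits of
what the tests demonstrate.

## Hormone gating

Normalized expression is `v = ln(1 + s · count / total)` with scale
factor `s = 10,000` (natural-log convention; the DE fold-change floor
of 0.5 is interpreted on this scale). For each hormone the density of
`v` pooled over *all* cells — zeros included, since the non-expressing
mass is the left mode — is estimated with a Gaussian KDE on an even
grid of 512 points spanning `[0, max(v)]`. Kernel mass leaking below
zero is reflected back (`f(x) = k(x) + k(−x)`), so the curve integrates
to ≈ 1 and the zero spike forms a proper boundary mode. Bandwidth
follows Silverman's rule (scipy's variant) unless overridden; the rule
is deterministic, which keeps thresholds reproducible.

Local maxima are sign changes of the first difference, with boundary
points eligible (the non-expressing mode typically sits at 0). The two
highest maxima are the principal modes — highest, not outermost, so a
shoulder artifact cannot displace a genuine mode. The threshold is the
grid point of minimum density strictly between them. Bimodality
amplitude `(h_low − h_anti)/h_low ∈ [0, 1]` measures separation; at or
below the floor (default 0.05) the threshold is flagged low-confidence.
A unimodal curve raises an error rather than guessing a threshold: the
caller may widen the bandwidth or drop the hormone.

Ties at the threshold count as non-expressing (strict `>`), so the
decision boundary is unambiguous. Cells expressing no hormone are
non-endocrine and excluded downstream. The cluster consistency filter
needs a cluster → expected-identity map; monohormonal cells must sit in
their own type's cluster, and bihormonal cells containing the anchor
hormone (Ppy) must sit in the designated hybrid cluster. Thresholds are
computed once on the pooled dataset, not per replicate.

## Single-cell differential expression

Stage 1 (pre-filter): `logFC = ln[(mean_A expm1(v) + 1)/(mean_B
expm1(v) + 1)]`, the expm1-mean-with-pseudocount convention of the
standard single-cell toolkits — the 0.5 floor only has meaning under a
stated formula, and this is the de-facto one. Genes below the floor are
not tested.

Stage 2: per gene, an NB2 GLM of raw counts on the group indicator plus
nuisance covariates — per-cell total UMIs, detected genes (both
standardized) and replicate (dummy-coded). All three are on by default
and individually switchable. The Wald p-value of the group coefficient
is Bonferroni-corrected against the number of genes in the dataset
(not the candidate count). Non-converged genes get p = NA and can
never enter a significant set.

The GLM engine (`nbglm`) fits all genes at once: every gene shares one
design matrix, so IRLS reduces to batched `(X'WX)β = X'Wz` solves with
`w = μ/(1 + αμ)`. Per-gene dispersion is estimated by profile maximum
likelihood — golden-section search on log α against the full NB
likelihood — alternating with IRLS (three outer rounds). The lower
search bound is the Poisson limit, which doubles as the fallback for
underdispersed genes. Standard errors use the expected information at
the final fit with dispersion plugged in, the convention of standard
count-regression tools; tests cross-check coefficients, dispersions and
p-values against an independent full-MLE implementation and, on tiny
instances with moderate effects, against a brute-force
profile-likelihood-ratio grid oracle. (At small n with strong effects,
Wald and LR p-values genuinely diverge — a property of the asymptotics,
not a defect of either computation — so the oracle comparison is made
where the normal approximation is in its working range.)

## Identity sets and overlaps

A type's ID genes are the intersection of its three pairwise
upregulated sets (logFC ≥ 0.5 and Bonferroni-adjusted p ≤ 0.05 in each
comparison); a gene missing the floor against even one type is
excluded. Overlap reports carry both views: share of the ID set
(printed as a rounded integer, the field's habit for such overlaps) and
share of the upregulated list (one decimal); the raw fractions are
always retained and are what analyses should consume. Cross-species
intersections map gene symbols through a two-column ortholog table into
uppercase human symbols; one-to-many mappings are dropped by default
(or expanded on request) and unmapped genes are dropped with a logged
count. Human ID gene lists are consumed as plain files, not recomputed:
the human raw data is restricted-access, and the overlap logic is what
this package owns. Pathway direction-concordance keeps pathways
regulated in the same direction in both input tables; enrichment
scoring itself is out of scope.

## Bulk differential expression

Size factors are median-of-ratios over genes expressed in every sample.
Since factors are identified only up to a common scale, they are
returned normalized to geometric mean 1; offsets absorb the scale in
the GLM intercept, so DE results are unaffected. Genes with fewer than
5 counts per sample on average *within the pairwise comparison* are
discarded (the boundary mean of exactly 5 is retained), so gene
universes legitimately differ between comparisons. The same batched NB
engine fits intercept + group with `log(size factor)` offsets; p-values
are Wald and adjusted by Benjamini-Hochberg over the tested genes.

Shrinkage uses a zero-centered normal prior: the posterior mode is
`LFC · σ²/(σ² + se²)`, which contracts toward zero, never changes sign,
and vanishes as se → 0. With `shrink_prior_sd="auto"` the prior sd
matches the prior's 95th percentile of |LFC| to the observed one
(`q95(|LFC|)/1.96`), a deterministic data-driven rule recorded in the
output provenance. Deliberately *not* implemented: empirical-Bayes
dispersion-trend sharing across genes, independent filtering and
outlier (Cook's distance) machinery — the package validates by
simulation recovery, not by replicating another tool's exact numbers.

## The synthetic islet

`simulate_sc` draws cell labels i.i.d. from the seven-type mixture:
α 0.35, β 0.45, δ 0.10, γ 0.10, with the γ pool split into
monohormonal γ (0.67) and the bihormonal subtypes γ-α 0.24, γ-δ 0.05,
γ-β 0.04 — the rarity structure of a real islet preparation. Counts for
gene g in cell c are NB with mean `L_c · ρ_gc / Σ_g ρ_gc`, where `L_c`
is log-normal (μ = 9.2 ≈ 9,900 UMIs, σ = 0.3, typical droplet depth),
`ρ = exp(type profile + per-replicate batch offset)` and NB dispersion
0.1 shared across cells per gene — the same model family the DE stages
assume, which makes parameter recovery a fair test.

Hormone genes are bimodal by construction: expressing cells draw their
log-rate from N(4.0, 0.4); non-expressing cells from N(−1.0, 0.4) with
probability 0.4 and are otherwise dropped to zero (dropout 0.6), so the
left mode sits near zero as islet data shows. The component means are
well over 2 sd apart, the regime the antimode threshold needs. Each of
the four types has 25 planted ID genes at true ln-fold-change 1.2
(comfortably above the 0.5 floor at the simulated group sizes);
bihormonal subtypes take the γ profile, the partner hormone from the
high component, and the first 60% of the partner's ID genes from the
partner profile — which is what makes their hybrid signature
detectable. Ten mitochondrial genes (`mt-Sim*`) are tuned to a 3% count
share. Cluster labels are truth-derived and perturbed at a 2% mislabel
rate: clustering itself is out of scope, but the consistency filter
still gets exercised. Doublets (off by default) add a random partner
cell's counts. The γ lineage carries the sorted-fraction flag. A fixed
seed makes the output bit-identical.

`simulate_bulk` generates per-type NB samples with log-normal size
factors (σ = 0.3, geometric mean 1) recorded in the truth; each type's
ID genes are planted at true log2FC 2 against every other type and all
other genes are null.

What the generator does *not* emulate: ambient RNA, UMI collisions,
gene-gene correlation beyond type structure, empirical mean-variance
trends, or any attempt to match real datasets' gene-level means.
Passing tests therefore demonstrate that the pipeline recovers planted
structure under its own model assumptions — not that it is robust to
every artifact of real islet data.

## Problem sizes and determinism

The validation suite uses a 5,000-cell × 2,000-gene default simulation
for end-to-end recovery and gating accuracy; 20 × (5,000 genes,
200+200 cells) null replicates and 100 power replicates for single-cell
DE calibration; and 50 recovery + 20 null replicates for bulk DE —
sizes chosen so the full suite runs in about a minute on one CPU while
keeping the binomial/multinomial tolerance bands meaningful. All
randomness flows from explicit seeds through `numpy.random.default_rng`;
CLI runs with a fixed config and seed are byte-identical.

## Known limitations

* Thresholding assumes each hormone's pooled density is bimodal; a
  dataset where a hormone is unimodal (e.g. a pure sorted fraction)
  raises an error instead of producing a threshold, by design.
* Wald tests with plug-in dispersion are mildly anti-conservative at
  very small sample sizes; the bulk branch expects ≥ 2 (realistically
  ≥ 3) samples per group.
* Bonferroni over all dataset genes is deliberately conservative for
  the single-cell branch, matching the workflow it reproduces.
* The logFC pre-filter means genes with large counts but small fold
  changes are never tested; under the null this makes family-wise error
  control trivially strict rather than nominally calibrated.
* Exact Mann-Whitney enumeration is limited to combined n ≤ 12; above
  that the tie- and continuity-corrected normal approximation is used.
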