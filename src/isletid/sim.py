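"""Synthetic islet RNA-seq generator with planted ground truth.

Emulates the statistical structure the downstream analysis assumes:

* a mixture of four monohormonal endocrine cell types (alpha, beta, delta,
  gamma) plus three rare bihormonal gamma subtypes (gamma_alpha,
  gamma_beta, gamma_delta) that co-express Ppy and a partner hormone;
* hormone genes with bimodal expression — a zero-inflated low component
  and a high component whose log-means are well separated, so a density
  antimode exists on the normalized scale;
* planted per-type identity (ID) genes with a known log fold change;
* negative-binomial gene counts around per-cell-type mean profiles,
  scaled by a log-normal per-cell library size and a per-replicate
  multiplicative batch factor;
* truth-derived cluster labels perturbed at a small mislabel rate, a
  sorted-fraction flag marking the gamma lineage, and optional doublets.

A fixed seed makes the output bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io_qc import CountMatrix

__all__ = ["SimConfig", "SimTruth", "simulate_sc", "simulate_bulk", "HORMONES", "TYPE_HORMONE"]

HORMONES = ("Gcg", "Ins2", "Ppy", "Sst")
MONO_TYPES = ("alpha", "beta", "delta", "gamma")
TYPE_HORMONE = {"alpha": "Gcg", "beta": "Ins2", "delta": "Sst", "gamma": "Ppy"}
BIHORM_PARTNER = {"gamma_alpha": "alpha", "gamma_beta": "beta", "gamma_delta": "delta"}
BIHORM_CLUSTER = "bihormonal"
N_MITO_GENES = 10


@dataclass
class SimConfig:
    """Parameters of the synthetic islet.

    Log-scale means (``hormone_high_mean`` etc.) are natural-log rates in
    the latent per-cell expression profile; ``nb_dispersion`` is the NB
    dispersion d in var = m + d*m^2, shared across cells per gene.
    """

    n_cells: int = 5000
    type_proportions: dict = field(
        default_factory=lambda: {"alpha": 0.35, "beta": 0.45, "delta": 0.10, "gamma": 0.10}
    )
    # shares of the gamma pool; the remainder is monohormonal gamma
    bihorm_proportions: dict = field(
        default_factory=lambda: {"gamma_alpha": 0.24, "gamma_delta": 0.05, "gamma_beta": 0.04}
    )
    n_genes: int = 2000
    n_id_genes_per_type: int = 25
    id_lfc: float = 1.2  # natural-log fold change of planted ID genes
    hormone_high_mean: float = 4.0
    hormone_low_mean: float = -1.0
    hormone_sd: float = 0.4
    hormone_dropout: float = 0.6  # zero-inflation of the low component
    bihorm_partner_fraction: float = 0.6  # share of partner ID genes drawn from partner profile
    libsize_mu: float = 9.2  # ln scale; exp(9.2) ~ 9900 UMIs
    libsize_sigma: float = 0.3
    nb_dispersion: float = 0.1
    batch_effect_sd: float = 0.1
    n_replicates: int = 2
    mito_fraction_mean: float = 0.03
    doublet_rate: float = 0.0
    cluster_mislabel_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        tp = sum(self.type_proportions.values())
        if abs(tp - 1.0) > 1e-9:
            raise ValueError(f"type_proportions sum to {tp}, expected 1")
        for name, p in {**self.type_proportions, **self.bihorm_proportions}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"fraction {name}={p} outside [0, 1]")
        if sum(self.bihorm_proportions.values()) > 1.0 + 1e-9:
            raise ValueError("bihorm_proportions exceed the gamma pool")
        if not self.hormone_high_mean > self.hormone_low_mean:
            raise ValueError("hormone_high_mean must exceed hormone_low_mean (bimodality)")
        if self.hormone_high_mean - self.hormone_low_mean < 2 * self.hormone_sd:
            raise ValueError("hormone component means must differ by >= 2 * hormone_sd")
        if self.n_id_genes_per_type * 4 + len(HORMONES) + N_MITO_GENES > self.n_genes:
            raise ValueError("n_genes too small for the planted gene layout")

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def full_proportions(self) -> dict:
        """Proportions over the seven cell labels (gamma pool split)."""
        out = {t: p for t, p in self.type_proportions.items() if t != "gamma"}
        g = self.type_proportions["gamma"]
        bi = sum(self.bihorm_proportions.values())
        out["gamma"] = g * (1.0 - bi)
        for name, share in self.bihorm_proportions.items():
            out[name] = g * share
        return out


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated matrix."""

    cell_type: pd.Series  # per cell: one of the seven labels
    hormone_sets: pd.Series  # per cell: tuple of expressed hormones
    doublet: pd.Series  # per cell: True where counts are a two-cell mix
    gene_role: pd.DataFrame  # per gene: role, id_type, true_lfc
    id_sets: dict  # mono type -> list of true ID genes (hormone + planted)
    size_factors: pd.Series | None = None  # bulk only

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_type": self.cell_type,
                "hormones": ["+".join(h) for h in self.hormone_sets],
                "doublet": self.doublet,
            }
        )


def _gene_layout(cfg: SimConfig) -> pd.DataFrame:
    names: list[str] = list(HORMONES)
    role = ["hormone"] * 4
    id_type: list[str | None] = [
        {"Gcg": "alpha", "Ins2": "beta", "Sst": "delta", "Ppy": "gamma"}[h] for h in HORMONES
    ]
    for i in range(N_MITO_GENES):
        names.append(f"mt-Sim{i + 1}")
        role.append("mito")
        id_type.append(None)
    for t in MONO_TYPES:
        for i in range(cfg.n_id_genes_per_type):
            names.append(f"Id{t.capitalize()}{i + 1:03d}")
            role.append("id")
            id_type.append(t)
    n_bg = cfg.n_genes - len(names)
    for i in range(n_bg):
        names.append(f"Bg{i + 1:04d}")
        role.append("background")
        id_type.append(None)
    gene_role = pd.DataFrame(
        {"role": role, "id_type": id_type}, index=pd.Index(names, name="gene")
    )
    gene_role["true_lfc"] = np.where(gene_role["role"] == "id", cfg.id_lfc, 0.0)
    return gene_role


def _check_subpop_sizes(cfg: SimConfig, n_cells: int) -> None:
    props = cfg.full_proportions()
    smallest = min(p for p in props.values() if p > 0)
    if n_cells * smallest < 10:
        raise ValueError(
            f"smallest subpopulation expects {n_cells * smallest:.1f} cells (< 10); "
            "increase n_cells or its fraction"
        )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = m + d*m^2; d = 0 is plain Poisson."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    lam = rng.gamma(shape=r, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_sc(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Simulate a single-cell UMI count matrix with ground truth.

    Counts for gene g in cell c are NB with mean
    ``libsize(c) * rho(g, c) / sum_g rho(g, c)`` where
    ``rho = exp(type profile + batch offset)``, hormone genes being
    overridden per cell by their bimodal component draw.
    """
    _check_subpop_sizes(cfg, cfg.n_cells)
    rng = np.random.default_rng(cfg.seed)
    gene_role = _gene_layout(cfg)
    genes = gene_role.index
    n_genes = len(genes)

    props = cfg.full_proportions()
    labels = list(props)
    p = np.array([props[t] for t in labels])
    cell_type = np.array(labels, dtype=object)[rng.choice(len(labels), size=cfg.n_cells, p=p)]
    replicate = rng.integers(1, cfg.n_replicates + 1, size=cfg.n_cells)
    libsize = rng.lognormal(cfg.libsize_mu, cfg.libsize_sigma, size=cfg.n_cells)

    # per-type log-rate profiles for non-hormone genes
    base = rng.normal(1.0, 0.5, size=n_genes)
    is_hormone = (gene_role["role"] == "hormone").to_numpy()
    is_mito = (gene_role["role"] == "mito").to_numpy()
    profiles: dict[str, np.ndarray] = {}
    for t in MONO_TYPES:
        prof = base.copy()
        prof[(gene_role["role"] == "id").to_numpy() & (gene_role["id_type"] == t).to_numpy()] += cfg.id_lfc
        profiles[t] = prof
    for bt, partner in BIHORM_PARTNER.items():
        prof = profiles["gamma"].copy()
        k = int(round(cfg.bihorm_partner_fraction * cfg.n_id_genes_per_type))
        partner_ids = gene_role.index[
            (gene_role["role"] == "id") & (gene_role["id_type"] == partner)
        ][:k]
        idx = genes.get_indexer(partner_ids)
        prof[idx] = profiles[partner][idx]
        profiles[bt] = prof

    # mitochondrial genes: shared log-rate hitting the target count share
    mean_nonmito = np.mean(
        [np.exp(profiles[t][~is_hormone & ~is_mito]).sum() for t in MONO_TYPES]
    )
    mito_rate = cfg.mito_fraction_mean / (1 - cfg.mito_fraction_mean) * mean_nonmito / N_MITO_GENES
    for prof in profiles.values():
        prof[is_mito] = np.log(mito_rate)

    batch = rng.normal(0.0, cfg.batch_effect_sd, size=(cfg.n_replicates, n_genes))

    hormone_sets = {
        t: (TYPE_HORMONE[t],) for t in MONO_TYPES
    } | {bt: tuple(sorted({"Ppy", TYPE_HORMONE[p]})) for bt, p in BIHORM_PARTNER.items()}
    h_idx = {h: genes.get_loc(h) for h in HORMONES}

    blocks: list[sp.csr_matrix] = []
    chunk = 2000
    for start in range(0, cfg.n_cells, chunk):
        stop = min(start + chunk, cfg.n_cells)
        nb = stop - start
        rho = np.empty((n_genes, nb))
        for j, c in enumerate(range(start, stop)):
            rho[:, j] = np.exp(profiles[cell_type[c]] + batch[replicate[c] - 1])
        # bimodal hormone override, drawn per cell
        for h in HORMONES:
            gi = h_idx[h]
            expressed = np.array(
                [h in hormone_sets[cell_type[c]] for c in range(start, stop)]
            )
            lograte = rng.normal(cfg.hormone_low_mean, cfg.hormone_sd, size=nb)
            hi = rng.normal(cfg.hormone_high_mean, cfg.hormone_sd, size=nb)
            lograte[expressed] = hi[expressed]
            rate = np.exp(lograte)
            drop = rng.random(nb) < cfg.hormone_dropout
            rate[~expressed & drop] = 0.0
            rho[gi, :] = rate
        mean = rho / rho.sum(axis=0, keepdims=True) * libsize[start:stop]
        blocks.append(sp.csr_matrix(_nb_sample(rng, mean, cfg.nb_dispersion)))

    counts = sp.hstack(blocks, format="csr", dtype=np.int64)

    # doublets: add a random partner cell's counts
    doublet = np.zeros(cfg.n_cells, dtype=bool)
    n_doub = int(round(cfg.doublet_rate * cfg.n_cells))
    if n_doub:
        counts = counts.tolil()
        victims = rng.choice(cfg.n_cells, size=n_doub, replace=False)
        for c in victims:
            partner = int(rng.integers(cfg.n_cells))
            counts[:, c] = counts[:, c].toarray() + counts[:, partner].toarray()
            doublet[c] = True
        counts = counts.tocsr()

    # truth-derived cluster labels with mislabeling
    cluster_of = {t: t for t in MONO_TYPES} | {bt: BIHORM_CLUSTER for bt in BIHORM_PARTNER}
    all_clusters = list(MONO_TYPES) + [BIHORM_CLUSTER]
    cluster = np.array([cluster_of[t] for t in cell_type], dtype=object)
    flip = rng.random(cfg.n_cells) < cfg.cluster_mislabel_rate
    for c in np.where(flip)[0]:
        others = [cl for cl in all_clusters if cl != cluster[c]]
        cluster[c] = others[int(rng.integers(len(others)))]

    barcodes = pd.Index([f"cell{i + 1:05d}" for i in range(cfg.n_cells)], name="barcode")
    gamma_lineage = np.array([t == "gamma" or t in BIHORM_PARTNER for t in cell_type])
    cell_meta = pd.DataFrame(
        {
            "replicate": replicate,
            "fraction": np.where(gamma_lineage, "pos", "neg"),
            "cluster": cluster,
        },
        index=barcodes,
    )
    gene_meta = pd.DataFrame(index=genes.copy())
    gene_meta["mito"] = is_mito

    id_sets = {
        t: [TYPE_HORMONE[t]]
        + list(gene_role.index[(gene_role["role"] == "id") & (gene_role["id_type"] == t)])
        for t in MONO_TYPES
    }
    truth = SimTruth(
        cell_type=pd.Series(cell_type, index=barcodes),
        hormone_sets=pd.Series([hormone_sets[t] for t in cell_type], index=barcodes),
        doublet=pd.Series(doublet, index=barcodes),
        gene_role=gene_role,
        id_sets=id_sets,
    )
    return CountMatrix(counts=counts, gene_meta=gene_meta, cell_meta=cell_meta), truth


def simulate_bulk(
    cfg: SimConfig,
    n_samples_per_type: int = 3,
    base_log_mean: float = 4.5,
    bulk_l2fc: float = 2.0,
    sf_sigma: float = 0.3,
) -> tuple[CountMatrix, SimTruth]:
    """Simulate sorted-population bulk counts for the four mono types.

    Planted DE: each type's ID genes are upregulated in that type with
    true log2 fold change ``bulk_l2fc`` (>= 1) against every other type;
    all other genes are null. Per-sample log-normal size factors are
    recorded in the truth.
    """
    if n_samples_per_type < 2:
        raise ValueError("need at least 2 samples per type")
    _check_subpop_sizes(cfg, cfg.n_cells)
    rng = np.random.default_rng(cfg.seed)
    gene_role = _gene_layout(cfg)
    genes = gene_role.index
    n_genes = len(genes)
    gene_role = gene_role.copy()
    gene_role["true_lfc"] = np.where(gene_role["role"] == "id", bulk_l2fc, 0.0)

    base = rng.normal(base_log_mean, 1.0, size=n_genes)
    profiles = {}
    for t in MONO_TYPES:
        prof = base.copy()
        up = (gene_role["role"] == "id").to_numpy() & (gene_role["id_type"] == t).to_numpy()
        prof[up] += bulk_l2fc * np.log(2.0)
        hi = genes.get_loc(TYPE_HORMONE[t])
        prof[hi] = base[hi] + bulk_l2fc * np.log(2.0)
        profiles[t] = prof

    sample_ids, sample_type = [], []
    for t in MONO_TYPES:
        for i in range(n_samples_per_type):
            sample_ids.append(f"{t}_{i + 1}")
            sample_type.append(t)
    n_samples = len(sample_ids)
    if sf_sigma > 0:
        size_factors = rng.lognormal(0.0, sf_sigma, size=n_samples)
        size_factors /= np.exp(np.mean(np.log(size_factors)))  # geometric mean 1
    else:
        size_factors = np.ones(n_samples)

    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    for s in range(n_samples):
        mean = size_factors[s] * np.exp(profiles[sample_type[s]])
        counts[:, s] = _nb_sample(rng, mean, cfg.nb_dispersion)

    idx = pd.Index(sample_ids, name="sample")
    cell_meta = pd.DataFrame({"cell_type": sample_type}, index=idx)
    gene_meta = pd.DataFrame(index=genes.copy())
    gene_meta["mito"] = (gene_role["role"] == "mito").to_numpy()
    id_sets = {
        t: [TYPE_HORMONE[t]]
        + list(gene_role.index[(gene_role["role"] == "id") & (gene_role["id_type"] == t)])
        for t in MONO_TYPES
    }
    truth = SimTruth(
        cell_type=pd.Series(sample_type, index=idx),
        hormone_sets=pd.Series([(TYPE_HORMONE[t],) for t in sample_type], index=idx),
        doublet=pd.Series(False, index=idx),
        gene_role=gene_role,
        id_sets=id_sets,
        size_factors=pd.Series(size_factors, index=idx),
    )
    return CountMatrix(counts=sp.csr_matrix(counts), gene_meta=gene_meta, cell_meta=cell_meta), truth
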