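import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from isletid.io_qc import CountMatrix, NormalizedMatrix
from isletid.pipeline import sc_identity_pipeline
from isletid.sim import SimConfig, simulate_sc

HORMONES = ["Gcg", "Ins2", "Ppy", "Sst"]


def make_count_matrix(counts, gene_names=None, barcodes=None, mito=None, cell_meta=None):
    """Small dense-spec helper for hand-built matrices."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(n_genes)]
    if barcodes is None:
        barcodes = [f"c{i}" for i in range(n_cells)]
    gm = pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    if mito is not None:
        gm["mito"] = mito
    cm = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    if cell_meta:
        for k, v in cell_meta.items():
            cm[k] = v
    return CountMatrix(counts=sp.csr_matrix(counts), gene_meta=gm, cell_meta=cm)


def make_normalized(values, gene_names=None, barcodes=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(n_genes)]
    if barcodes is None:
        barcodes = [f"c{i}" for i in range(n_cells)]
    return NormalizedMatrix(
        values=sp.csr_matrix(values),
        gene_meta=pd.DataFrame(index=pd.Index(gene_names, name="gene")),
        cell_meta=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        scale_factor=10_000.0,
    )


def null_count_matrix(n_genes, n_cells, seed, disp=0.3, n_replicates=2):
    """One NB population: no gene differs between any two cell groups."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(0.0, 1.0, n_genes)
    lib = rng.lognormal(0.0, 0.2, n_cells)
    mu = np.outer(base, lib)
    y = rng.poisson(rng.gamma(1.0 / disp, mu * disp))
    return make_count_matrix(
        y,
        gene_names=[f"g{i}" for i in range(n_genes)],
        barcodes=[f"c{i}" for i in range(n_cells)],
        cell_meta={"replicate": rng.integers(1, n_replicates + 1, n_cells)},
    )


def tiny_sim_config(**kw):
    """A config with boosted rare fractions so tiny n_cells stays valid."""
    defaults = dict(
        n_cells=400,
        n_genes=200,
        n_id_genes_per_type=5,
        type_proportions={"alpha": 0.3, "beta": 0.3, "delta": 0.2, "gamma": 0.2},
        bihorm_proportions={"gamma_alpha": 0.3, "gamma_delta": 0.15, "gamma_beta": 0.15},
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """A modest synthetic islet used by unit tests (fast)."""
    cfg = SimConfig(n_cells=3000, n_genes=1000, n_id_genes_per_type=20, seed=2)
    m, truth = simulate_sc(cfg)
    return cfg, m, truth


@pytest.fixture(scope="session")
def default_sim():
    """The default study-scale simulation (5000 cells, 2000 genes)."""
    cfg = SimConfig()
    m, truth = simulate_sc(cfg)
    return cfg, m, truth


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    _, m, _ = default_sim
    return sc_identity_pipeline(m)
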