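import numpy as np
import pandas as pd
import pytest

from isletid.bulk_de import (
    BulkDEConfig,
    bulk_nb_wald,
    call_de,
    mean_count_filter,
    shrink_lfc_normal,
    size_factors,
    upregulated_calls,
)
from isletid.sim import simulate_bulk

from conftest import make_count_matrix, tiny_sim_config


def gamma_vs(m, other):
    ga = [s for s in m.cell_ids if s.startswith("gamma")]
    gb = [s for s in m.cell_ids if s.startswith(other)]
    return ga, gb


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        col = np.array([10, 3, 7, 1, 25])
        m = make_count_matrix(np.tile(col[:, None], (1, 4)))
        assert np.allclose(size_factors(m), 1.0)

    def test_doubled_sample_on_toy_table(self):
        a = np.array([10, 4, 8, 2, 30])
        m = make_count_matrix(np.column_stack([a, 2 * a]))
        sf = size_factors(m).to_numpy()
        assert sf[1] / sf[0] == pytest.approx(2.0, rel=1e-12)

    def test_recovers_simulated_factors_within_2pct(self):
        cfg = tiny_sim_config(n_genes=2000, n_id_genes_per_type=20, nb_dispersion=0.05, seed=1)
        m, truth = simulate_bulk(cfg, n_samples_per_type=3)
        sf = size_factors(m).to_numpy()
        rel = np.abs(sf / truth.size_factors.to_numpy() - 1)
        assert rel.max() <= 0.02

    def test_fixed_point_after_rescaling(self):
        cfg = tiny_sim_config(n_genes=1500, seed=2)
        m, _ = simulate_bulk(cfg, n_samples_per_type=3)
        sf = size_factors(m)
        counts = np.asarray(m.counts.todense(), dtype=float) / sf.to_numpy()[None, :]
        m2 = make_count_matrix(np.round(counts).astype(int), barcodes=list(m.cell_ids))
        sf2 = size_factors(m2)
        assert np.all(np.abs(sf2.to_numpy() - 1.0) < 0.01)

    def test_agrees_with_pydeseq2(self):
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet

        cfg = tiny_sim_config(n_genes=800, seed=3)
        m, _ = simulate_bulk(cfg, n_samples_per_type=3)
        counts = pd.DataFrame(
            np.asarray(m.counts.todense()).T, index=m.cell_ids, columns=m.gene_names
        )
        meta = pd.DataFrame({"condition": m.cell_meta["cell_type"]})
        dds = DeseqDataSet(counts=counts, metadata=meta, design="~condition", quiet=True)
        dds.fit_size_factors()
        ref = np.asarray(dds.obs["size_factors"], dtype=float)
        ref = ref / np.exp(np.mean(np.log(ref)))
        assert np.allclose(size_factors(m).to_numpy(), ref, rtol=1e-6)

    def test_no_universally_expressed_gene_raises(self):
        counts = np.array([[5, 0], [0, 7]])
        with pytest.raises(ValueError, match="nonzero"):
            size_factors(make_count_matrix(counts))


class TestMeanCountFilter:
    def test_boundaries(self):
        counts = np.array([[5, 5, 5], [4, 4, 4], [0, 0, 0], [15, 0, 0]])
        m = make_count_matrix(counts)
        kept = mean_count_filter(m)
        assert list(kept) == ["g0", "g3"]  # mean exactly 5 retained; below discarded


class TestBulkWald:
    def test_duplicated_groups_give_zero_lfc(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=(300, 3))
        counts = np.column_stack([base, base])  # group B duplicates group A
        m = make_count_matrix(
            counts, barcodes=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        )
        res = bulk_nb_wald(m, [f"a{i}" for i in range(3)], [f"b{i}" for i in range(3)])
        assert np.nanmax(np.abs(res["lfc_mle"])) < 1e-4

    def test_planted_lfc_recovery(self):
        cfg = tiny_sim_config(n_genes=2000, n_id_genes_per_type=20, nb_dispersion=0.05, seed=4)
        m, truth = simulate_bulk(cfg, n_samples_per_type=3, bulk_l2fc=2.0)
        res = bulk_nb_wald(m, *gamma_vs(m, "alpha"))
        gamma_ids = truth.gene_role.index[
            (truth.gene_role["role"] == "id") & (truth.gene_role["id_type"] == "gamma")
        ]
        gamma_ids = [g for g in gamma_ids if g in res.index]
        err = np.abs(res.loc[gamma_ids, "lfc_mle"] - 2.0)
        assert err.median() <= 0.3

    def test_planted_calls_exact_at_strong_effect(self):
        cfg = tiny_sim_config(n_genes=1000, n_id_genes_per_type=20, nb_dispersion=0.02, seed=5)
        m, truth = simulate_bulk(cfg, n_samples_per_type=4, bulk_l2fc=3.0)
        cfgb = BulkDEConfig()
        res = shrink_lfc_normal(bulk_nb_wald(m, *gamma_vs(m, "delta"), cfgb), cfgb)
        up = set(upregulated_calls(res, cfgb))
        truth_up = {
            g
            for g in truth.id_sets["gamma"]
            if g in res.index
        }
        assert up == truth_up


class TestShrinkage:
    def _res(self, lfc, se):
        return pd.DataFrame(
            {
                "lfc_mle": lfc,
                "se": se,
                "padj": 0.01,
                "p": 0.001,
                "base_mean": 100.0,
                "converged": True,
            },
            index=pd.Index([f"g{i}" for i in range(len(lfc))], name="gene"),
        )

    def test_zero_se_limit_keeps_mle(self):
        res = self._res([2.0], [1e-9])
        out = shrink_lfc_normal(res, BulkDEConfig(shrink_prior_sd=1.0))
        assert out["lfc_shrunk"].iloc[0] == pytest.approx(2.0, rel=1e-6)

    def test_prior_sd_equal_se_halves_mle(self):
        res = self._res([2.0], [0.7])
        out = shrink_lfc_normal(res, BulkDEConfig(shrink_prior_sd=0.7))
        assert out["lfc_shrunk"].iloc[0] == pytest.approx(1.0, rel=1e-12)

    def test_contraction_and_sign_preservation(self):
        rng = np.random.default_rng(1)
        res = self._res(rng.normal(0, 2, 200), np.abs(rng.normal(0.5, 0.2, 200)) + 0.05)
        out = shrink_lfc_normal(res, BulkDEConfig())
        assert (out["lfc_shrunk"].abs() <= out["lfc_mle"].abs() + 1e-6).all()
        assert (np.sign(out["lfc_shrunk"]) * np.sign(out["lfc_mle"]) >= 0).all()

    def test_shrinkage_helps_low_count_genes(self):
        # planted truth: shrunken estimates closer to truth than MLE for noisy genes
        rng = np.random.default_rng(2)
        n = 400
        true = rng.choice([0.0, 0.0, 0.0, 1.0], size=n)  # mostly null
        se = np.abs(rng.normal(0.8, 0.2, n)) + 0.3  # low-information genes
        mle = true + rng.normal(0, se)
        res = self._res(mle, se)
        out = shrink_lfc_normal(res, BulkDEConfig())
        mae_shrunk = np.abs(out["lfc_shrunk"] - true).mean()
        mae_mle = np.abs(out["lfc_mle"] - true).mean()
        assert mae_shrunk <= mae_mle


class TestCallDE:
    def _res(self, lfc_shrunk, padj):
        n = len(lfc_shrunk)
        return pd.DataFrame(
            {
                "lfc_shrunk": lfc_shrunk,
                "padj": padj,
                "converged": [True] * n,
            },
            index=pd.Index([f"g{i}" for i in range(n)], name="gene"),
        )

    def test_inclusive_boundaries(self):
        res = self._res([1.0, 3.0, -1.0, 0.99], [0.05, 0.2, 0.05, 0.01])
        called = call_de(res)
        assert called == ["g0", "g2"]  # boundary gene called; high-p and low-LFC not

    def test_bh_null_discovery_fraction(self):
        fracs = []
        for seed in range(3):
            cfg = tiny_sim_config(n_genes=2000, seed=30 + seed)
            m, _ = simulate_bulk(cfg, n_samples_per_type=6)
            alphas = [s for s in m.cell_ids if s.startswith("alpha")]
            res = bulk_nb_wald(m, alphas[:3], alphas[3:])  # null: same population
            fracs.append((res["padj"] <= 0.05).sum() / len(res))
        assert np.mean(fracs) <= 0.07
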