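import numpy as np
import pandas as pd
import pytest

from isletid.gating import (
    ConfigurationError,
    DegenerateDistributionError,
    UnimodalError,
    assign_hormone_status,
    assign_identity,
    cluster_consistency_filter,
    estimate_density,
    find_antimode,
    hormone_thresholds,
    ppy_anchored_label,
)
from isletid.io_qc import log_normalize, qc_filter

from conftest import HORMONES, make_normalized


def brute_force_antimode(curve):
    """Independent oracle: exhaustive scan for the interior minimum
    between the two highest grid maxima (boundaries included)."""
    d = curve.density
    maxima = []
    for i in range(len(d)):
        left = d[i - 1] if i > 0 else -np.inf
        right = d[i + 1] if i < len(d) - 1 else -np.inf
        if d[i] > left and d[i] > right:
            maxima.append(i)
    if len(maxima) < 2:
        return None
    top = sorted(maxima, key=lambda i: d[i])[-2:]
    i1, i2 = min(top), max(top)
    j = min(range(i1 + 1, i2), key=lambda k: d[k])
    return curve.grid[j]


def bimodal_sample(rng, n=10_000):
    comp = rng.random(n) < 0.5
    x = np.where(comp, rng.normal(0.1, 0.05, n), rng.normal(3.0, 0.3, n))
    return np.clip(x, 0, None)


class TestEstimateDensity:
    def test_two_principal_modes_near_generating_means(self):
        rng = np.random.default_rng(0)
        curve = estimate_density(bimodal_sample(rng))
        res = find_antimode(curve)
        locs = sorted(res.mode_locations)
        assert abs(locs[0] - 0.1) < 0.15
        assert abs(locs[1] - 3.0) < 0.15

    def test_integral_close_to_one(self):
        rng = np.random.default_rng(1)
        curve = estimate_density(bimodal_sample(rng))
        assert abs(curve.integral() - 1.0) <= 0.01

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateDistributionError):
            estimate_density(np.full(500, 2.0))

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError, match="at least"):
            estimate_density(np.arange(50.0))

    def test_grid_covers_nonnegative_range(self):
        rng = np.random.default_rng(2)
        curve = estimate_density(bimodal_sample(rng))
        assert curve.grid[0] == 0.0
        assert np.all(np.diff(curve.grid) > 0)
        assert len(curve.grid) >= 512


class TestFindAntimode:
    def test_symmetric_mixture_threshold_near_zero(self):
        rng = np.random.default_rng(3)
        n = 20_000
        comp = rng.random(n) < 0.5
        x = np.where(comp, rng.normal(-1, 0.5, n), rng.normal(1, 0.5, n))
        curve = estimate_density(x)
        res = find_antimode(curve)
        assert abs(res.threshold) < 0.15
        assert res.amplitude > 0

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        curve = estimate_density(bimodal_sample(rng))
        res = find_antimode(curve)
        assert res.threshold == pytest.approx(brute_force_antimode(curve), abs=1e-12)

    def test_unimodal_raises(self):
        rng = np.random.default_rng(4)
        curve = estimate_density(rng.normal(2.0, 0.5, 5000))
        assert brute_force_antimode(curve) is None  # oracle agrees it is unimodal
        with pytest.raises(UnimodalError):
            find_antimode(curve)

    def test_low_confidence_flag_follows_amplitude_floor(self):
        rng = np.random.default_rng(7)
        curve = estimate_density(bimodal_sample(rng))
        assert not find_antimode(curve, amplitude_floor=0.05).low_confidence
        assert find_antimode(curve, amplitude_floor=1.0).low_confidence

    def test_antimode_between_modes_and_below_them(self):
        rng = np.random.default_rng(5)
        curve = estimate_density(bimodal_sample(rng))
        res = find_antimode(curve)
        lo, hi = sorted(res.mode_locations)
        assert lo < res.threshold < hi
        assert res.antimode_height <= min(res.mode_heights)
        assert 0 <= res.amplitude <= 1


class TestAssignment:
    def test_value_equal_to_threshold_is_not_expressing(self):
        nm = make_normalized([[1.0, 2.0, 3.0]], gene_names=["Ppy"])
        from isletid.gating import AntimodeResult, HormoneThresholds

        ht = HormoneThresholds(
            per_hormone={
                "Ppy": AntimodeResult(2.0, 0.5, (0.0, 3.0), (1.0, 1.0), 0.1, False)
            }
        )
        status = assign_hormone_status(nm, ["Ppy"], ht)
        assert list(status["Ppy"]) == [False, False, True]  # strict '>'

    def test_missing_hormone_gene_raises(self):
        nm = make_normalized([[1.0, 2.0]], gene_names=["Gcg"])
        from isletid.gating import HormoneThresholds

        with pytest.raises(ConfigurationError):
            assign_hormone_status(nm, ["Ppy"], HormoneThresholds())

    def test_all_16_subsets_have_distinct_labels(self):
        from itertools import combinations

        rows = []
        for k in range(5):
            for sub in combinations(HORMONES, k):
                rows.append({h: h in sub for h in HORMONES})
        status = pd.DataFrame(rows, index=[f"c{i}" for i in range(len(rows))])
        ids = assign_identity(status)
        assert ids["label"].nunique() == 16
        none_cells = ids[ids["label"] == "none"]
        assert len(none_cells) == 1
        assert not none_cells["endocrine"].iloc[0]

    def test_ppy_anchored_label(self):
        assert ppy_anchored_label(("Gcg", "Ppy")) == "Ppy+Gcg"
        assert ppy_anchored_label(()) == "none"

    def test_truth_agreement_on_simulation(self, small_sim):
        _, m, truth = small_sim
        filtered, _ = qc_filter(m)
        nm = log_normalize(filtered)
        thr = hormone_thresholds(nm, HORMONES)
        status = assign_hormone_status(nm, HORMONES, thr)
        ids = assign_identity(status)
        true_sets = truth.hormone_sets.loc[filtered.cell_ids]
        agree = np.mean(
            [
                tuple(ids.at[c, "hormones"]) == tuple(sorted(true_sets.loc[c]))
                for c in filtered.cell_ids
            ]
        )
        assert agree >= 0.99


class TestClusterConsistency:
    def _ids(self, rows):
        idx = [f"c{i}" for i in range(len(rows))]
        hsets = [tuple(sorted(r[0])) for r in rows]
        ids = pd.DataFrame(
            {
                "hormones": hsets,
                "label": ["+".join(h) if h else "none" for h in hsets],
                "n_hormones": [len(h) for h in hsets],
                "endocrine": [len(h) > 0 for h in hsets],
            },
            index=idx,
        )
        clusters = pd.Series([r[1] for r in rows], index=idx)
        return ids, clusters

    CLUSTER_MAP = {
        "alpha": "Gcg",
        "beta": "Ins2",
        "delta": "Sst",
        "gamma": "Ppy",
        "bihormonal": "bihormonal",
    }

    def test_rules(self):
        ids, clusters = self._ids(
            [
                (("Gcg",), "beta"),  # Gcg cell in the Ins cluster -> excluded
                (("Gcg", "Ppy"), "bihormonal"),  # retained
                (("Gcg", "Ppy"), "alpha"),  # bihormonal outside its cluster -> excluded
                (("Ppy",), "gamma"),  # retained
                ((), "gamma"),  # non-endocrine -> excluded
                (("Gcg", "Ins2"), "bihormonal"),  # no Ppy anchor -> excluded
            ]
        )
        out = cluster_consistency_filter(ids, clusters, self.CLUSTER_MAP)
        assert list(out["retained"]) == [False, True, False, True, False, False]
        assert out["exclusion_reason"].iloc[0] == "cluster_mismatch"
        assert out["exclusion_reason"].iloc[2] == "outside_bihormonal_cluster"
        assert out["exclusion_reason"].iloc[4] == "non_endocrine"

    def test_unmapped_cluster_raises(self):
        ids, clusters = self._ids([(("Gcg",), "mystery")])
        with pytest.raises(ConfigurationError):
            cluster_consistency_filter(ids, clusters, self.CLUSTER_MAP)

    def test_mislabel_exclusions_match_expectation(self, small_sim):
        cfg, m, truth = small_sim
        filtered, _ = qc_filter(m)
        nm = log_normalize(filtered)
        thr = hormone_thresholds(nm, HORMONES)
        ids = assign_identity(assign_hormone_status(nm, HORMONES, thr))
        out = cluster_consistency_filter(
            ids, filtered.cell_meta["cluster"], self.CLUSTER_MAP
        )
        excl = out["exclusion_reason"].isin(
            ["cluster_mismatch", "outside_bihormonal_cluster"]
        )
        n = len(out)
        expected = n * cfg.cluster_mislabel_rate
        sd = np.sqrt(n * cfg.cluster_mislabel_rate * (1 - cfg.cluster_mislabel_rate))
        assert abs(excl.sum() - expected) <= 3 * sd


class TestShiftInvariance:
    def test_antimode_shifts_with_constant_offset(self):
        rng = np.random.default_rng(6)
        x = bimodal_sample(rng)
        t0 = find_antimode(estimate_density(x)).threshold
        shift = 1.0
        t1 = find_antimode(estimate_density(x + shift)).threshold
        grid_step = (x.max() + shift) / 511
        assert abs(t1 - (t0 + shift)) < 3 * grid_step
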