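import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import methylpc as mp
from methylpc import association as assoc
from methylpc.io import SampleMeta


class TestCorrelate:
    def test_identical_vectors(self):
        res = assoc.correlate_vector_with_trait([1, 2, 3, 4], [1, 2, 3, 4])
        assert np.isclose(res.r, 1.0)

    def test_orthogonal_to_centered_trait(self):
        res = assoc.correlate_vector_with_trait([1, -1, -1, 1], [1, 2, 3, 4])
        assert abs(res.r) < 1e-10

    def test_exact_linear_scaling(self):
        res = assoc.correlate_vector_with_trait([1, 2, 3, 4], [2, 4, 6, 8])
        assert np.isclose(res.r, 1.0) and res.p_value < 0.01

    def test_constant_trait_rejected(self):
        with pytest.raises(assoc.AssociationError, match="constant"):
            assoc.correlate_vector_with_trait([1, 2, 3], [5, 5, 5])

    @settings(max_examples=30, deadline=None)
    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_affine_invariance_and_sign_flip(self, a, b):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r0 = assoc.correlate_vector_with_trait(x, y).r
        assert np.isclose(assoc.correlate_vector_with_trait(a * x + b, y).r, r0)
        assert np.isclose(assoc.correlate_vector_with_trait(-x, y).r, -r0)


class TestAssociateAllPCs:
    def test_planted_neuron_pc_tops_table(self, cohort):
        meta = cohort["meta"]
        is_brain = meta.table["tissue"].isin(("BA10", "BA20", "BA7")).to_numpy()
        table = assoc.associate_all_pcs(
            cohort["result"], meta, ["neuron_fraction"], {"brain": is_brain}
        )
        assert table.iloc[0]["pc"] == 2 and abs(table.iloc[0]["r"]) > 0.9

    def test_noise_trait_null_rate(self, cohort):
        rng = np.random.default_rng(42)
        meta = cohort["meta"]
        hits = trials = 0
        for _ in range(40):
            noise = rng.normal(size=len(meta.table))
            t = meta.table.copy()
            t["noise"] = noise
            table = assoc.associate_all_pcs(cohort["result"], SampleMeta(t), ["noise"])
            hits += int((table["p_value"] < 0.01).sum())
            trials += len(table)
        assert hits / trials < 0.04  # per-test rate near the nominal 0.01

    def test_factor_recovery_assignment(self, cohort):
        table = assoc.recover_planted_factors(cohort["result"], cohort["meta"])
        assert table["pc"].nunique() == 5
        d = dict(zip(table["factor"], table["abs_r"]))
        assert d["brain_vs_blood"] > 0.9
        assert d["neuron"] > 0.9 and d["granulo"] > 0.9
        assert d["ageA"] > 0.7 and d["ageB"] > 0.7


class TestBatchScan:
    def test_identical_distributions_not_significant(self, cohort):
        scan = assoc.batch_effect_scan(cohort["result"], cohort["meta"])
        # synthetic cohort has no planted batch structure
        assert not scan["significant"].any()

    def test_number_of_tests_contract(self, cohort):
        meta = cohort["meta"]
        scan = assoc.batch_effect_scan(cohort["result"], meta, top_k=5)
        n_levels = meta.table["chip"].nunique() + meta.table["chip_position"].nunique()
        assert len(scan) == n_levels * 5

    def test_shifted_chip_detected(self, cohort):
        res = cohort["result"]
        meta = cohort["meta"].table.copy()
        # relabel chips so that one chip coincides with extreme PC1 scores
        order = np.argsort(res.scores(1))
        labels = np.array(["chipA"] * len(meta))
        labels[order[:20]] = "chipB"
        meta["chip"] = labels
        meta["chip_position"] = "pos0"
        scan = assoc.batch_effect_scan(res, SampleMeta(meta),
                                       batch_vars=("chip",))
        assert scan[scan["batch_var"] == "chip"]["significant"].any()


class TestVarianceByTissue:
    def test_identical_tissues_split_evenly(self):
        rng = np.random.default_rng(1)
        block = rng.normal(size=(200, 4))
        X = np.hstack([block, block])
        ids = [f"a{j}" for j in range(4)] + [f"b{j}" for j in range(4)]
        m = mp.MethylationMatrix([f"p{i}" for i in range(200)], ids, X)
        meta = SampleMeta(pd.DataFrame({
            "sample_id": ids,
            "individual_id": [f"i{j}" for j in range(4)] * 2,
            "tissue": ["A"] * 4 + ["B"] * 4,
            "age": 30.0,
        }))
        variances, ks, pct = assoc.variance_by_tissue(m, meta)
        assert np.isclose(ks["ks_statistic"].iloc[0], 0.0)
        assert np.isclose(pct["A"], 50.0) and np.isclose(pct["B"], 50.0)

    def test_doubling_noise_quadruples_share(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1.0, size=(3000, 6))
        b = rng.normal(0, 2.0, size=(3000, 6))
        ids = [f"a{j}" for j in range(6)] + [f"b{j}" for j in range(6)]
        m = mp.MethylationMatrix([f"p{i}" for i in range(3000)], ids,
                                 np.hstack([a, b]))
        meta = SampleMeta(pd.DataFrame({
            "sample_id": ids,
            "individual_id": ids,
            "tissue": ["A"] * 6 + ["B"] * 6,
            "age": 30.0,
        }))
        variances, _, _ = assoc.variance_by_tissue(m, meta)
        ratio = variances["B"].sum() / variances["A"].sum()
        assert abs(ratio - 4.0) < 0.4

    def test_composition_deflation_homogenizes_brain(self, cohort):
        mat, meta, res = cohort["matrix"], cohort["meta"], cohort["result"]
        table = assoc.recover_planted_factors(res, meta)
        pcs = dict(zip(table["factor"], table["pc"]))
        _, ks0, _ = assoc.variance_by_tissue(mat, meta)
        _, ks1, _ = assoc.variance_by_tissue(
            mat, meta, deflate_result=res,
            deflate_pcs=[pcs["neuron"], pcs["granulo"]],
        )
        brain = ("BA10", "BA20", "BA7")

        def blood_vs_brain(t):
            mask = (t["tissue_a"] == "WB") | (t["tissue_b"] == "WB")
            return t[mask]["ks_statistic"].mean()

        # removing composition variance sharpens the brain/blood contrast
        assert blood_vs_brain(ks1) >= blood_vs_brain(ks0) - 0.05


@pytest.fixture(scope="module")
def blood_cohort():
    cfg = mp.default_config(seed=7, n_probes=6000)
    _, _, _, _, truth = mp.simulate_cohort(cfg)
    vmat, vmeta = mp.simulate_validation_cohort(
        cfg, truth, "WB", 48, seed=11, age_range=(19, 101)
    )
    return vmat, vmeta


class TestPower:

    def test_seeded_reproducibility(self, blood_cohort):
        vmat, vmeta = blood_cohort
        c1 = assoc.power_subsampling(vmat, vmeta, "age", [8, 16], reps=10, seed=3)
        c2 = assoc.power_subsampling(vmat, vmeta, "age", [8, 16], reps=10, seed=3)
        assert c1.detection_fraction == c2.detection_fraction

    def test_full_cohort_certain_detection(self, blood_cohort):
        vmat, vmeta = blood_cohort
        c = assoc.power_subsampling(vmat, vmeta, "age", [48], reps=10, seed=3)
        assert c.detection_fraction == [1.0]

    def test_small_subsample_rejected(self, blood_cohort):
        vmat, vmeta = blood_cohort
        with pytest.raises(assoc.AssociationError, match="< 4"):
            assoc.power_subsampling(vmat, vmeta, "age", [3], reps=2, seed=0)

    def test_null_rate_matches_screen_oracle(self):
        cfg = mp.default_config(seed=7, n_probes=2000)
        for f in cfg.factors:
            f.effect_size = 0.0
        _, _, _, _, truth = mp.simulate_cohort(cfg)
        vmat, vmeta = mp.simulate_validation_cohort(cfg, truth, "WB", 40, seed=11)
        c = assoc.power_subsampling(vmat, vmeta, "age", [16], reps=150, seed=5)
        oracle = assoc.null_screen_rate(16, c.n_pcs_tested[0], reps=3000, seed=9)
        se = np.sqrt(oracle * (1 - oracle) / 150)
        assert abs(c.detection_fraction[0] - oracle) < 3 * se + 0.02
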