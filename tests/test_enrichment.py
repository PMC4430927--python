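import numpy as np
import pandas as pd
import pytest

from methylpc import enrichment as enr
from methylpc.io import ProbeAnnotation


def annotation_for(categories):
    return ProbeAnnotation(pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(len(categories))],
        "chromosome": "1",
        "position": np.arange(1, len(categories) + 1),
        "density_class": categories,
        "region_class": "intron",
        "is_CH": False,
    }))


class TestBinomialZ:
    @pytest.mark.parametrize("n_exp,expected_z", [(10, 0.0), (16, 2.0), (4, -2.0)])
    def test_hand_fixtures(self, n_exp, expected_z):
        mu, sigma2, z = enr.binomial_z(n_exp, 100, 100, 1000)
        assert mu == 10.0 and sigma2 == 9.0
        assert np.isclose(z, expected_z)

    def test_degenerate_null_rejected(self):
        with pytest.raises(enr.EnrichmentError, match="degenerate"):
            enr.binomial_z(5, 10, 10, 10)

    def test_null_calibration_mean_zero_variance_one(self):
        rng = np.random.default_rng(0)
        n_draws, N_exp, p = 10000, 400, 0.2
        draws = rng.binomial(N_exp, p, size=n_draws)
        zs = np.array([enr.binomial_z(int(d), N_exp, 2000, 10000)[2]
                       for d in draws])
        se_mean = 1 / np.sqrt(n_draws)
        se_var = np.sqrt(2 / n_draws)
        assert abs(zs.mean()) < 3 * se_mean + 0.02
        assert abs(zs.var() - 1.0) < 3 * se_var + 0.02


class TestCategoryEnrichment:
    def test_subset_equal_background_is_flat(self):
        ann = annotation_for(["HC"] * 30 + ["LC"] * 70)
        probes = set(f"p{i}" for i in range(100))
        table = enr.category_enrichment(probes, probes, ann, "density_class")
        assert np.allclose(table["fold"], 1.0)
        assert np.allclose(table["z"], 0.0)

    def test_pure_hc_subset_fold(self):
        ann = annotation_for(["HC"] * 25 + ["LC"] * 75)
        background = set(f"p{i}" for i in range(100))
        subset = set(f"p{i}" for i in range(10))  # all HC
        table = enr.category_enrichment(subset, background, ann, "density_class")
        hc = table[table["category"] == "HC"].iloc[0]
        assert np.isclose(hc["fold"], 4.0)
        assert hc["z"] > 0

    def test_uniform_draw_is_null(self):
        rng = np.random.default_rng(1)
        ann = annotation_for(rng.choice(["HC", "IC", "LC"], size=2000))
        background = set(f"p{i}" for i in range(2000))
        zs = []
        for s in range(20):
            r2 = np.random.default_rng(s)
            subset = set(f"p{i}" for i in r2.choice(2000, 200, replace=False))
            t = enr.category_enrichment(subset, background, ann, "density_class")
            zs.extend(t["z"].tolist())
        zs = np.asarray(zs)
        assert abs(np.mean(zs)) < 0.3
        assert np.mean(np.abs(zs) > 3) < 0.05

    def test_empty_subset_rejected(self):
        ann = annotation_for(["HC", "LC"])
        with pytest.raises(enr.EnrichmentError, match="empty"):
            enr.category_enrichment(set(), {"p0", "p1"}, ann, "density_class")

    def test_planted_context_bias_detected(self, cohort):
        # ageA probes were planted with HC enrichment; the PC's selected
        # probes should show it
        from methylpc import association as assoc

        res, meta, ann = cohort["result"], cohort["meta"], cohort["annotation"]
        table = assoc.recover_planted_factors(res, meta)
        pc_a = dict(zip(table["factor"], table["pc"]))["ageA"]
        tails = res.select_probes(pc_a, 2.0, "both")
        subset = tails["positive"] | tails["negative"]
        background = set(cohort["matrix"].probe_ids)
        t = enr.category_enrichment(subset, background, ann, "density_class")
        hc = t[t["category"] == "HC"].iloc[0]
        assert hc["fold"] > 1.2 and hc["z"] > 3


class TestSpatialEnrichment:
    def uniform_map(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        dists = rng.integers(-2500, 2501, size=n)
        return {f"p{i}": ("gene", int(d)) for i, d in enumerate(dists)}

    def test_default_bin_count_is_30(self):
        pg = self.uniform_map()
        probes = set(pg)
        out = enr.tss_spatial_enrichment(probes, probes, pg)
        assert len(out.n_exp) == 30
        assert out.bin_edges[0] == -2500 and out.bin_edges[-1] == 2500

    def test_subset_equal_background_all_zero(self):
        pg = self.uniform_map()
        probes = set(pg)
        out = enr.tss_spatial_enrichment(probes, probes, pg)
        np.testing.assert_allclose(out.z[~np.isnan(out.z)], 0.0, atol=1e-12)

    def test_counts_conserved(self):
        pg = self.uniform_map()
        background = set(pg)
        subset = set(list(pg)[:500])
        out = enr.tss_spatial_enrichment(subset, background, pg)
        assert out.n_exp.sum() == out.N_exp == 500
        assert out.n_bg.sum() == out.N_bg == len(pg)

    def test_concentrated_subset_enriched_near_tss(self):
        pg = self.uniform_map()
        background = set(pg)
        near = {p for p, (_, d) in pg.items() if -100 <= d <= 0}
        out = enr.tss_spatial_enrichment(near, background, pg)
        frame = out.to_frame()
        hot = frame[(frame["bin_left"] <= -100) & (frame["bin_right"] >= 0)]
        assert (hot["z"] > 0).any()
        distal = frame[(frame["bin_right"] < -1000) | (frame["bin_left"] > 1000)]
        assert (distal.dropna(subset=["z"])["z"] <= 0).all()

    def test_edge_distance_goes_to_right_bin(self):
        pg = {"a": ("g", -2500 + 167), "b": ("g", 0)}
        out = enr.tss_spatial_enrichment({"a"}, {"a", "b"}, pg)
        assert out.n_exp[1] == 1 and out.n_exp[0] == 0

    def test_no_mapped_subset_errors(self):
        with pytest.raises(enr.EnrichmentError):
            enr.tss_spatial_enrichment({"zzz"}, {"a"}, {"a": ("g", 0)})


class TestGeneSets:
    def test_no_probes_past_threshold_empty_sets(self, cohort):
        res = cohort["result"]
        out = enr.gene_sets_from_projections(res, 1, {"p0": ("g", 0)},
                                             n_sigma=1e9)
        assert out == {"positive": set(), "negative": set()}

    def test_gene_with_probes_in_both_tails_in_both_sets(self, toy_matrix):
        import methylpc as mp

        res = mp.fit_pca(toy_matrix, remove_offset=False)
        pg = {"p1": ("gene", 10), "p2": ("gene", -10)}
        out = enr.gene_sets_from_projections(res, 1, pg, n_sigma=0.5)
        assert out["positive"] == {"gene"} and out["negative"] == {"gene"}

    def test_tissue_factor_tails_nearly_disjoint_genes(self, cohort):
        import methylpc as mp
        from methylpc import association as assoc
        from methylpc.io import assign_probes_to_lone_genes, compute_lone_genes

        res, meta = cohort["result"], cohort["meta"]
        lone = compute_lone_genes(cohort["genes"])
        pg = assign_probes_to_lone_genes(cohort["annotation"], cohort["genes"], lone)
        pc1 = dict(zip(*[assoc.recover_planted_factors(res, meta)[c]
                         for c in ("factor", "pc")]))["brain_vs_blood"]
        out = enr.gene_sets_from_projections(res, pc1, pg, n_sigma=2.0)
        genes_with_probes = {g for g, _ in pg.values()}
        obs, exp, ratio = enr.overlap_vs_expected(
            out["positive"], out["negative"], len(genes_with_probes)
        )
        assert obs <= max(4.0, 2.5 * exp)  # overlap no larger than chance-scale


class TestOverlapVsExpected:
    def test_expected_formula(self):
        a = set(range(100))
        b = set(range(50, 250))
        obs, exp, ratio = enr.overlap_vs_expected(a, b, 1000)
        assert exp == 100 * 200 / 1000 == 20.0
        assert obs == 50

    def test_identical_sets(self):
        a = set(range(40))
        obs, exp, ratio = enr.overlap_vs_expected(a, a, 400)
        assert obs == 40
        assert np.isclose(ratio, 400 / 40)

    def test_disjoint_sets(self):
        obs, exp, ratio = enr.overlap_vs_expected(set(range(10)),
                                                  set(range(10, 20)), 100)
        assert obs == 0 and ratio == 0.0

    def test_empty_universe_rejected(self):
        with pytest.raises(enr.EnrichmentError):
            enr.overlap_vs_expected(set(), set(), 0)
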