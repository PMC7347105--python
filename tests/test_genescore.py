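"""Gene-level GWAS: MAF filter, variant OLS vs oracle, gene assignment,
permutation score vs exhaustive enumeration, calibration, escalation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import drmetanet as dm
from tests.conftest import tiny_genotypes


class TestMafFilter:
    def test_strict_boundary(self):
        # 1 carrier of 20 lines = 0.05 exactly -> dropped (strict '>')
        cols = [np.r_[np.ones(1), np.zeros(19)],    # maf 0.05
                np.r_[np.ones(10), np.zeros(10)],   # maf 0.50
                np.zeros(20),                       # monomorphic
                np.r_[np.ones(2), np.zeros(18)]]    # maf 0.10
        g = tiny_genotypes(20, cols)
        out = dm.maf_filter(g, 0.05)
        assert out.n_variants == 2
        assert set(out.variants["pos"]) == {g.variants["pos"][1],
                                            g.variants["pos"][3]}


class TestVariantAssociation:
    def test_exact_relation(self):
        d = np.r_[np.ones(4), np.zeros(4)]
        g = tiny_genotypes(8, [d])
        res = dm.variant_association(g, d.astype(float), None)
        assert np.isclose(res["beta"][0], 1.0)
        assert res["p"][0] == 0.0

    def test_constant_variant_skipped(self):
        g = tiny_genotypes(8, [np.ones(8), np.r_[np.ones(4), np.zeros(4)]])
        y = np.random.default_rng(0).normal(size=8)
        res = dm.variant_association(g, y, None)
        assert np.isnan(res["p"][0])
        assert np.isfinite(res["p"][1])

    def test_constant_phenotype_is_error(self):
        g = tiny_genotypes(8, [np.r_[np.ones(4), np.zeros(4)]])
        with pytest.raises(ValueError, match="constant"):
            dm.variant_association(g, np.ones(8), None)

    def test_matches_statsmodels_on_8_line_instances(self):
        """Vectorized FWL path equals textbook OLS (criterion for both the
        complete-data fast path and the missing-dosage slow path)."""
        rng = np.random.default_rng(9)
        for trial in range(20):
            d1 = rng.integers(0, 2, 8).astype(float)
            d2 = rng.integers(0, 2, 8).astype(float)
            while d1.std() == 0 or d2.std() == 0:
                d1 = rng.integers(0, 2, 8).astype(float)
                d2 = rng.integers(0, 2, 8).astype(float)
            if trial % 2:
                d2[rng.integers(0, 8)] = np.nan   # exercise slow path
                if np.nanstd(d2) == 0:
                    continue
            g = tiny_genotypes(8, [d1, d2])
            y = rng.normal(size=8)
            cov = pd.DataFrame({"w": rng.integers(0, 2, 8)})
            res = dm.variant_association(g, y, cov)
            for j, d in enumerate((d1, d2)):
                mask = ~np.isnan(d)
                if d[mask].std() == 0:
                    continue
                X = sm.add_constant(np.column_stack(
                    [d[mask], cov["w"].to_numpy()[mask]]))
                if np.linalg.matrix_rank(X) < X.shape[1]:
                    assert np.isnan(res["p"][j])  # collinear -> skipped
                    continue
                fit = sm.OLS(y[mask], X).fit()
                assert abs(res["beta"][j] - fit.params[1]) < 1e-10
                assert abs(res["se"][j] - fit.bse[1]) < 1e-10
                assert abs(res["p"][j] - fit.pvalues[1]) < 1e-10

    def test_null_p_uniform(self):
        g = dm.simulate_genotypes(178, 2000, seed=40)
        rng = np.random.default_rng(41)
        y = rng.normal(size=178)
        cov = pd.DataFrame({"w": rng.integers(0, 2, 178)})
        res = dm.variant_association(g, y, cov)
        p = res["p"].dropna()
        assert stats.kstest(p, "uniform").pvalue > 0.001


class TestAssignVariants:
    def test_window_boundaries_inclusive(self):
        g = tiny_genotypes(10, [np.r_[np.ones(5), np.zeros(5)]] * 4)
        g.variants["pos"] = [4000, 5000 - 1001, 5000 - 1000, 6000]
        ann = dm.GeneAnnotation(pd.DataFrame([
            {"gene_id": "gA", "chrom": "2R", "start": 5000, "end": 6000}]),
            window_bp=1000)
        gmap = dm.assign_variants(g, ann)
        pos = set(g.variants["pos"][gmap["gA"]])
        assert pos == {4000, 6000}  # start-1000 and inside; start-1001 is out

    def test_overlapping_genes_share_variant(self):
        g = tiny_genotypes(10, [np.r_[np.ones(5), np.zeros(5)]])
        g.variants["pos"] = [5500]
        ann = dm.GeneAnnotation(pd.DataFrame([
            {"gene_id": "gA", "chrom": "2R", "start": 5000, "end": 6000},
            {"gene_id": "gB", "chrom": "2R", "start": 5400, "end": 7000},
            {"gene_id": "gC", "chrom": "3L", "start": 5000, "end": 6000}]),
            window_bp=0)
        gmap = dm.assign_variants(g, ann)
        assert set(gmap) == {"gA", "gB"}  # chrom must match; gC empty


class TestGeneMinP:
    def test_minimum_and_absence(self):
        p = pd.DataFrame({"p": [0.3, 0.01, 0.2, np.nan]})
        gmap = {"gA": np.array([0, 1, 2]), "gB": np.array([3]),
                "gC": np.array([2])}
        mp = dm.gene_min_p(p, gmap)
        assert mp["gA"] == 0.01
        assert mp["gC"] == 0.2
        assert "gB" not in mp.index  # only-NaN gene absent


def four_line_fixture(seed=0):
    rng = np.random.default_rng(seed)
    cols = [np.array([1, 0, 0, 1.0]), np.array([0, 1, 0, 0.0]),
            np.array([1, 1, 0, 0.0])]
    g = tiny_genotypes(4, cols)
    y = rng.normal(size=4)
    gmap = {"gA": np.array([0, 1]), "gB": np.array([2])}
    return g, y, gmap


class TestPermutationGeneScore:
    def test_exhaustive_mode_matches_bruteforce_oracle(self):
        """All 4! = 24 relabelings: the fast FWL path and the lstsq oracle
        must count exactly the same hits."""
        for seed in range(3):
            g, y, gmap = four_line_fixture(seed)
            fast = dm.permutation_gene_score(g, y, None, gmap,
                                             exhaustive=True)
            oracle = dm.exhaustive_gene_score(g, y, None, gmap)
            assert (fast["n_perm"] == 24).all()
            merged = fast.merge(oracle, on="gene_id", suffixes=("_f", "_o"))
            assert (merged["n_hits_f"] == merged["n_hits_o"]).all()
            assert np.allclose(merged["observed_min_p_f"],
                               merged["observed_min_p_o"], atol=1e-10)

    def test_sampled_score_converges_to_exhaustive(self):
        """On a 6-line fixture the sampled add-one score approaches the
        exact enumeration probability."""
        rng = np.random.default_rng(3)
        cols = [rng.integers(0, 2, 6).astype(float) for _ in range(3)]
        cols = [c if c.std() > 0 else np.array([1, 0, 0, 0, 0, 0.0])
                for c in cols]
        g = tiny_genotypes(6, cols)
        y = rng.normal(size=6)
        gmap = {"gA": np.array([0, 1]), "gB": np.array([2])}
        exact = dm.exhaustive_gene_score(g, y, None, gmap).set_index("gene_id")
        sampled = dm.permutation_gene_score(
            g, y, None, gmap, n_init=4000, n_max=4000, escalate_p=0.0,
            seed=5).set_index("gene_id")
        for gene in ("gA", "gB"):
            p_exact = exact.loc[gene, "score"]
            se = np.sqrt(p_exact * (1 - p_exact) / 4000)
            assert abs(sampled.loc[gene, "score"] - p_exact) < 4 * se + 1e-3

    def test_addone_floor_when_observed_is_best(self):
        # phenotype equals a variant: no permutation beats it except those
        # reproducing the same split, so the score is near 1/(n_perm+1)
        d = np.r_[np.ones(10), np.zeros(10)]
        g = tiny_genotypes(20, [d])
        gmap = {"gA": np.array([0])}
        res = dm.permutation_gene_score(g, d + 0.01 * np.arange(20), None,
                                        gmap, n_init=100, n_max=100, seed=7)
        assert res["score"][0] == pytest.approx(1 / 101)

    def test_score_decreases_with_stronger_signal(self):
        """Exhaustive scoring: sharpening the phenotype-variant relation
        never increases the gene score (monotonicity in observed min-P)."""
        d = np.array([1, 1, 0, 0, 0, 0.0])
        g = tiny_genotypes(6, [d])
        gmap = {"gA": np.array([0])}
        rng = np.random.default_rng(8)
        noise = rng.normal(size=6)
        weak = dm.permutation_gene_score(
            g, d + 2.0 * noise, None, gmap, exhaustive=True)
        strong = dm.permutation_gene_score(
            g, d + 0.05 * noise, None, gmap, exhaustive=True)
        assert (strong["observed_min_p"][0] <= weak["observed_min_p"][0])
        assert strong["score"][0] <= weak["score"][0]

    def test_null_scores_approximately_uniform(self):
        g = dm.simulate_genotypes(40, 400, seed=50)
        ann = dm.make_gene_annotation(g, 40)
        gmap = dm.assign_variants(g, ann)
        y = np.random.default_rng(51).normal(size=40)
        res = dm.permutation_gene_score(g, y, None, gmap, n_init=400,
                                        n_max=400, escalate_p=0.0, seed=52)
        s = res["score"].to_numpy()
        assert abs((s <= 0.5).mean() - 0.5) < 0.15
        assert stats.kstest(s, "uniform").pvalue > 0.01

    def test_escalation_bookkeeping(self):
        d = np.r_[np.ones(10), np.zeros(10)]
        g = tiny_genotypes(20, [d, np.roll(d, 3)])
        gmap = {"gA": np.array([0]), "gB": np.array([1])}
        y = d + 0.01 * np.arange(20)
        res = dm.permutation_gene_score(
            g, y, None, gmap, n_init=200, n_max=2000, escalate_p=5e-2,
            seed=9).set_index("gene_id")
        assert res.loc["gA", "escalated"]
        assert res.loc["gA", "n_perm"] == 2000
        assert (res["n_hits"] <= res["n_perm"]).all()
        assert ((res["score"] > 0) & (res["score"] <= 1)).all()

    def test_parameter_validation(self):
        g, y, gmap = four_line_fixture()
        with pytest.raises(ValueError, match="n_max"):
            dm.permutation_gene_score(g, y, None, gmap, n_init=100, n_max=10)
        with pytest.raises(ValueError, match="constant"):
            dm.permutation_gene_score(g, np.ones(4), None, gmap)

    def test_seed_determinism(self):
        g = dm.simulate_genotypes(30, 100, seed=60)
        gmap = dm.assign_variants(g, dm.make_gene_annotation(g, 10))
        y = np.random.default_rng(61).normal(size=30)
        a = dm.permutation_gene_score(g, y, None, gmap, n_init=300,
                                      n_max=300, seed=62)
        b = dm.permutation_gene_score(g, y, None, gmap, n_init=300,
                                      n_max=300, seed=62)
        pd.testing.assert_frame_equal(a, b)
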