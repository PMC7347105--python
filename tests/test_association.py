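"""Metabolite-trait association: OLS oracle equivalence, FDR behavior,
paired diet tests, PCA summaries, and planted-effect recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import drmetanet as dm
from tests.test_preprocess import make_matrix


def by_stepup_reference(p):
    """Independent brute-force BY step-up: q_(i) = min_{j>=i} min(1,
    m c(m) p_(j) / j), c(m) = sum_{k<=m} 1/k."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    c = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(1.0, m * c * p[order[j]] / (j + 1)) for j in range(i, m))
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestByAdjust:
    def test_single_p(self):
        assert np.allclose(dm.by_adjust([0.01]), [0.01])

    def test_all_ones(self):
        assert np.allclose(dm.by_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_stepup_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 30))
            assert np.allclose(dm.by_adjust(p), by_stepup_reference(p),
                               atol=1e-12)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_by_dominates_bh_dominates_p(self, p):
        p = np.asarray(p)
        q_by = dm.by_adjust(p)
        q_bh = multipletests(p, method="fdr_bh")[1]
        assert (q_by >= q_bh - 1e-12).all()
        assert (q_bh >= p - 1e-12).all()


class TestFitTraitOnMetabolite:
    def test_exact_fit_with_constant_mass(self):
        idx = [f"l{i}" for i in range(6)]
        met = pd.Series(np.arange(6.0), index=idx, name="met_x")
        trait = 2.0 * met
        mass = pd.Series(1.0, index=idx)
        with pytest.warns(UserWarning, match="constant"):
            res = dm.fit_trait_on_metabolite(trait, met, body_mass=mass)
        assert np.isclose(res.beta_hat, 2.0)
        assert res.p == 0.0

    def test_collinear_covariate_is_error(self):
        idx = [f"l{i}" for i in range(6)]
        met = pd.Series(np.arange(6.0), index=idx, name="m")
        with pytest.raises(ValueError, match="collinear"):
            dm.fit_trait_on_metabolite(met * 1.5, met,
                                       body_mass=2 * met + 1)

    def test_missing_mass_drops_line(self):
        idx = [f"l{i}" for i in range(7)]
        rng = np.random.default_rng(0)
        met = pd.Series(rng.normal(size=7), index=idx, name="m")
        trait = pd.Series(rng.normal(size=7), index=idx)
        mass = pd.Series(rng.normal(1.2, 0.1, 7), index=idx)
        mass.iloc[3] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            res = dm.fit_trait_on_metabolite(trait, met, body_mass=mass)
        assert res.n == 6

    def test_matches_statsmodels_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = 6
            idx = [f"l{i}" for i in range(n)]
            met = pd.Series(rng.normal(size=n), index=idx, name="m")
            mass = pd.Series(rng.normal(1, 0.2, n), index=idx)
            trait = pd.Series(rng.normal(size=n), index=idx)
            res = dm.fit_trait_on_metabolite(trait, met, body_mass=mass)
            X = sm.add_constant(np.column_stack([met, mass]))
            fit = sm.OLS(trait.to_numpy(), X).fit()
            assert abs(res.beta_hat - fit.params[1]) < 1e-10
            assert abs(res.se_beta - fit.bse[1]) < 1e-10
            assert abs(res.p - fit.pvalues[1]) < 1e-10

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(8)
        n = 178
        idx = [f"l{i}" for i in range(n)]
        ps = []
        for _ in range(1000):
            met = pd.Series(rng.normal(size=n), index=idx, name="m")
            trait = pd.Series(rng.normal(size=n), index=idx)
            ps.append(dm.fit_trait_on_metabolite(trait, met).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.001


class TestDietEffectTests:
    @staticmethod
    def paired_matrix(al, dr, mets=None):
        al, dr = np.asarray(al, float), np.asarray(dr, float)
        n, m = al.shape
        mets = mets or [f"met_{j:03d}" for j in range(m)]
        lines = [f"line_{i:03d}" for i in range(n)]
        idx = pd.MultiIndex.from_arrays(
            [lines * 2, ["AL"] * n + ["DR"] * n], names=["line_id", "diet"])
        data = pd.DataFrame(np.vstack([al, dr]), index=idx, columns=mets)
        return dm.MetaboliteMatrix(data, stage="batch_corrected",
                                   normalization_mode="across_diet")

    def test_identical_columns_give_t0_p1(self):
        x = np.random.default_rng(0).normal(size=(10, 2))
        res = dm.diet_effect_tests(self.paired_matrix(x, x))
        assert np.allclose(res["t"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_exact_shift_flagged_significant(self):
        x = np.random.default_rng(1).normal(size=(10, 2))
        res = dm.diet_effect_tests(self.paired_matrix(x, x + 1.0))
        assert (res["p"] < 1e-100).all()
        assert res["exact_shift"].all()
        assert np.allclose(res["mean_delta"], 1.0)

    def test_power_at_half_sd_shift(self):
        # d = 0.5 SD at n = 178 lines: noncentral-t power is essentially 1
        rng = np.random.default_rng(2)
        al = rng.normal(size=(178, 100))
        dr = al + rng.normal(0.5, 1.0, size=(178, 100))
        res = dm.diet_effect_tests(self.paired_matrix(al, dr))
        ncp = 0.5 / np.sqrt(2) * np.sqrt(178)  # paired diff SD = sqrt(2)
        assert stats.nct.sf(stats.t.isf(0.025, 177), 177, ncp) > 0.99
        assert (res["q"] < 0.01).mean() > 0.99


class TestPcaSummary:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        mm = make_matrix(np.column_stack([x, 2 * x + 1]), stage="scaled")
        s = dm.pca_summary(mm)
        assert np.isclose(s.variance_fraction[0], 1.0)

    def test_isotropic_noise_splits_evenly(self):
        rng = np.random.default_rng(4)
        mm = make_matrix(rng.normal(size=(4000, 2)), stage="scaled")
        s = dm.pca_summary(mm)
        assert np.allclose(s.variance_fraction, [0.5, 0.5], atol=0.05)

    def test_fractions_non_increasing_and_bounded(self, desk_processed):
        s = dm.pca_summary(desk_processed)
        vf = s.variance_fraction
        assert (np.diff(vf) <= 1e-12).all()
        assert vf.sum() <= 1 + 1e-8


class TestAssociateAll:
    def test_null_cohort_has_no_signal(self):
        coh = dm.simulate_cohort(dm.SimConfig(seed=21, n_lines=60))
        proc = dm.preprocess(coh.metabolome_raw)
        tt = dm.lifespan_traits(coh.lifespans)
        assoc = dm.associate_all(tt, proc,
                                 body_mass=coh.covariates["body_mass"])
        assert assoc["significant"].sum() == 0

    def test_q_monotone_in_p_within_family(self, desk_cohort,
                                           desk_processed, desk_traits):
        assoc = dm.associate_all(desk_traits, desk_processed)
        for _, fam in assoc.groupby(["trait_name", "diet_of_measurement"]):
            fam = fam.sort_values("p")
            assert (np.diff(fam["q"]) >= -1e-12).all()
            assert (fam["q"] >= fam["p"] - 1e-12).all()

    def test_planted_metabolite_found_in_correct_diet(self):
        cfg = dm.SimConfig(seed=22, n_lines=178, planted_effects=[
            dm.PlantedEffect("gene_000", 5, "met_007", "AL",
                             beta_gm=0.0, beta_m_rls=5.0)])
        coh = dm.simulate_cohort(cfg)
        proc = dm.preprocess(coh.metabolome_raw)
        tt = dm.lifespan_traits(coh.lifespans)
        assoc = dm.associate_all(tt, proc,
                                 body_mass=coh.covariates["body_mass"])
        assert "met_007" in dm.rls_associated_metabolites(assoc, "AL")

    def test_sensitivity_and_false_positives_over_seeds(self):
        """One strong planted metabolite -> rLS path per cohort: the planted
        metabolite is flagged in >= 80% of seeds and false positives stay at
        the conservative BY level."""
        hits, fps = 0, 0
        n_seeds = 50
        for seed in range(n_seeds):
            cfg = dm.SimConfig(seed=100 + seed, n_lines=100, n_variants=20,
                               n_metabolites=20, n_flies_per_cell=50,
                               planted_effects=[dm.PlantedEffect(
                                   "gene_000", 5, "met_003", "AL",
                                   beta_gm=0.0, beta_m_rls=5.0)])
            coh = dm.simulate_cohort(cfg)
            proc = dm.preprocess(coh.metabolome_raw)
            tt = dm.lifespan_traits(coh.lifespans)
            assoc = dm.associate_all(
                tt, proc, body_mass=coh.covariates["body_mass"],
                traits=("rLS",))
            found = dm.rls_associated_metabolites(assoc, "AL")
            hits += "met_003" in found
            fps += len([m for m in found if m != "met_003"])
            fps += len(dm.rls_associated_metabolites(assoc, "DR"))
        assert hits / n_seeds >= 0.8
        assert fps / n_seeds <= 0.1


class TestAssociateDelta:
    def test_delta_matrix_definition(self, desk_processed):
        d = dm.delta_metabolites(desk_processed)
        al = desk_processed.diet_slice("AL").loc[d.index]
        dr = desk_processed.diet_slice("DR").loc[d.index]
        assert np.allclose(d.to_numpy(), dr.to_numpy() - al.to_numpy())

    def test_planted_delta_association(self):
        cfg = dm.SimConfig(seed=23, n_lines=178, planted_effects=[
            dm.PlantedEffect("gene_000", 5, "met_002", "DR",
                             beta_gm=0.0, beta_m_rls=4.0)])
        coh = dm.simulate_cohort(cfg)
        proc = dm.preprocess(coh.metabolome_raw)
        tt = dm.lifespan_traits(coh.lifespans)
        delta = dm.delta_metabolites(proc)
        res = dm.associate_delta(tt["rLS"], delta,
                                 body_mass=coh.covariates["body_mass"])
        # the DR-only planted metabolite moves its DR-AL difference
        assert res.loc[res["metabolite_id"] == "met_002",
                       "significant"].item()
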