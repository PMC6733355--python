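import numpy as np
import pytest
from scipy import stats

from admixscan import fst, syndata
from admixscan.syndata import (AncestryEnrichment, PhenotypeModel, SimConfig,
                               Sweep)


class TestConfigValidation:
    def test_defaults_are_valid(self):
        SimConfig()

    @pytest.mark.parametrize("kwargs", [
        {"theta_na": 1.5},
        {"drift": {"EAS": 0.0, "MA": 0.03, "ANDES": 0.03, "SPN": 0.12}},
        {"drift": {"EAS": 1.0, "MA": 0.03, "ANDES": 0.03, "SPN": 0.12}},
        {"panel_sizes": {"EAS": 1, "MA": 50, "ANDES": 50, "SPN": 100}},
        {"sweeps": [Sweep(site=10, target=1.5)]},
        {"sweeps": [Sweep(site=-1, target=0.5)]},
        {"ancestry_enrichments": [AncestryEnrichment(0, 10, 1.2)]},
        {"ancestry_enrichments": [AncestryEnrichment(50, 10, 0.6)]},
        {"ancestry_enrichments": [AncestryEnrichment(0, 10, 0.6, "cases")]},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(n_sites=100, **kwargs)


class TestSimulatePanels:
    def test_zero_drift_limit_tracks_ancestral(self):
        cfg = SimConfig(seed=1, n_sites=3000,
                        drift={"EAS": 1e-6, "MA": 1e-6, "ANDES": 1e-6,
                               "SPN": 1e-6})
        panels = syndata.simulate_panels(cfg, genotypes=False)
        for pop in syndata.POPULATIONS:
            np.testing.assert_allclose(panels["true_freq"][pop],
                                       panels["ancestral"], atol=0.02)

    def test_sweep_overwrites_focal_frequency(self):
        cfg = SimConfig(seed=2, n_sites=100,
                        sweeps=[Sweep(site=7, target=0.95, ancestral=0.2)])
        panels = syndata.simulate_panels(cfg, genotypes=False)
        assert panels["true_freq"]["ANDES"][7] == 0.95
        assert panels["ancestral"][7] == 0.2

    def test_genotypes_consistent_with_observed_freqs(self):
        cfg = SimConfig(seed=3, n_sites=200)
        panels = syndata.simulate_panels(cfg)
        for pop in syndata.POPULATIONS:
            g = panels["genotypes"][pop]
            assert g.shape == (cfg.panel_sizes[pop], cfg.n_sites)
            np.testing.assert_allclose(panels["obs_freq"][pop],
                                       g.mean(axis=0) / 2)

    def test_differentiation_ordering_over_seeds(self):
        # the drift defaults produce the study's FST ordering:
        # FST(ANDES, MA) < FST(MA, EAS) < FST(corrected-focal, EAS)
        wins = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_sites=20_000)
            rng = np.random.default_rng(seed)
            panels = syndata.simulate_panels(cfg, rng=rng, genotypes=False)
            cohort = syndata.simulate_admixed_cohort(cfg, panels, rng=rng,
                                                     individuals=False)
            from admixscan import pbs
            f_corr, _ = pbs.correct_frequency(cohort["cohort_freq"],
                                              cohort["alpha_true"],
                                              panels["obs_freq"]["SPN"])
            n = panels["n_chrom"]
            n_eff = round(2 * cfg.cohort_size * (1 - cohort["alpha_true"].mean()))
            f1 = fst.hudson_fst_global(panels["obs_freq"]["ANDES"], n["ANDES"],
                                       panels["obs_freq"]["MA"], n["MA"])
            f2 = fst.hudson_fst_global(panels["obs_freq"]["MA"], n["MA"],
                                       panels["obs_freq"]["EAS"], n["EAS"])
            f3 = fst.hudson_fst_global(f_corr, n_eff,
                                       panels["obs_freq"]["EAS"], n["EAS"])
            wins += f1 < f2 < f3
        assert wins == 10

    def test_seed_determinism(self):
        a = syndata.simulate_panels(SimConfig(seed=5, n_sites=50))
        b = syndata.simulate_panels(SimConfig(seed=5, n_sites=50))
        for pop in syndata.POPULATIONS:
            np.testing.assert_array_equal(a["genotypes"][pop],
                                          b["genotypes"][pop])


class TestSimulateCohort:
    def panels(self, n_sites, f_andes=0.5, f_spn=0.5):
        return {"true_freq": {"ANDES": np.full(n_sites, f_andes),
                              "SPN": np.full(n_sites, f_spn)}}

    def test_single_ancestry_limit(self):
        cfg = SimConfig(seed=6, n_sites=500, cohort_size=100, theta_na=1.0)
        cohort = syndata.simulate_admixed_cohort(
            cfg, self.panels(500, f_andes=0.9, f_spn=0.1))
        assert (cohort["ancestry"].X == 2).all()
        # cohort frequencies converge to the focal panel's frequency
        assert cohort["cohort_freq"].mean() == pytest.approx(0.9, abs=0.01)

    def test_theta_concentration_over_seeds(self):
        means = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_sites=20_000, cohort_size=200)
            cohort = syndata.simulate_admixed_cohort(
                cfg, self.panels(20_000),
                rng=np.random.default_rng(seed), individuals=False)
            means.append(1 - cohort["alpha_true"].mean())
        assert np.allclose(means, 0.44, atol=0.01)

    def test_controls_only_enrichment_direction(self):
        # control-group ancestry exceeds case-group ancestry inside the
        # enriched window in nearly every seed
        wins = 0
        for seed in range(100):
            cfg = SimConfig(
                seed=seed, n_sites=200, cohort_size=100,
                ancestry_enrichments=[AncestryEnrichment(100, 130, 0.60,
                                                         "controls_only")])
            cohort = syndata.simulate_admixed_cohort(
                cfg, self.panels(200), rng=np.random.default_rng(seed))
            X = cohort["ancestry"].X
            ctrl = cohort["groups"] == "control"
            wins += (X[ctrl, 100:130].mean() > X[~ctrl, 100:130].mean())
        assert wins >= 95

    def test_enrichment_bounds_validated(self):
        with pytest.raises(ValueError):
            SimConfig(n_sites=100,
                      ancestry_enrichments=[AncestryEnrichment(0, 10, -0.1)])

    def test_site_level_path_matches_individual_moments(self):
        cfg = SimConfig(seed=8, n_sites=5000, cohort_size=200)
        rng1, rng2 = np.random.default_rng(8), np.random.default_rng(9)
        a = syndata.simulate_admixed_cohort(cfg, self.panels(5000), rng=rng1)
        b = syndata.simulate_admixed_cohort(cfg, self.panels(5000), rng=rng2,
                                            individuals=False)
        assert a["cohort_freq"].mean() == pytest.approx(
            b["cohort_freq"].mean(), abs=0.005)
        assert a["alpha_true"].mean() == pytest.approx(
            b["alpha_true"].mean(), abs=0.005)


class TestSimulatePhenotype:
    def test_null_model_independence(self):
        # beta = 0 and no covariate effects: case status independent of
        # dosage (chi-square non-significant in most seeds)
        nonsig = 0
        for seed in range(100):
            cfg = SimConfig(seed=seed, n_sites=20, cohort_size=800,
                            phenotype=PhenotypeModel(
                                risk_site=5, beta=0.0, intercept=0.0,
                                beta_age=0.0, beta_sex=0.0,
                                beta_smoking=0.0, beta_orf=0.0))
            sim_panels = {"true_freq": {"ANDES": np.full(20, 0.5),
                                        "SPN": np.full(20, 0.5)}}
            rng = np.random.default_rng(seed)
            cohort = syndata.simulate_admixed_cohort(cfg, sim_panels, rng=rng)
            pheno = syndata.simulate_phenotype(cfg, cohort["genotypes"],
                                               rng=rng)
            table = np.zeros((3, 2))
            dosage = cohort["genotypes"].dosage[:, 5]
            for d in (0, 1, 2):
                for c in (0, 1):
                    table[d, c] = ((dosage == d)
                                   & (pheno["case"] == c)).sum()
            table = table[table.sum(axis=1) > 0]
            p = stats.chi2_contingency(table)[1]
            nonsig += p > 0.05
        assert nonsig >= 94

    def test_design_labels_override_model(self):
        cfg = SimConfig(seed=9, n_sites=50, cohort_size=60)
        panels = {"true_freq": {"ANDES": np.full(50, 0.5),
                                "SPN": np.full(50, 0.5)}}
        cohort = syndata.simulate_admixed_cohort(cfg, panels)
        groups = np.array(["case"] * 30 + ["control"] * 30, dtype=object)
        pheno = syndata.simulate_phenotype(cfg, cohort["genotypes"],
                                           groups=groups)
        np.testing.assert_array_equal(pheno["case"].to_numpy()[:30], 1)
        np.testing.assert_array_equal(pheno["case"].to_numpy()[30:], 0)

    def test_saturated_intercept_degenerates_downstream(self):
        from admixscan import assoc
        cfg = SimConfig(seed=10, n_sites=20, cohort_size=80,
                        phenotype=PhenotypeModel(risk_site=3, beta=0.0,
                                                 intercept=-40.0))
        panels = {"true_freq": {"ANDES": np.full(20, 0.5),
                                "SPN": np.full(20, 0.5)}}
        cohort = syndata.simulate_admixed_cohort(cfg, panels)
        pheno = syndata.simulate_phenotype(cfg, cohort["genotypes"])
        assert (pheno["case"] == 0).all()
        with pytest.raises(assoc.DegeneratePhenotypeError):
            assoc.fit_logistic_additive(
                cohort["genotypes"].dosage[:, 3].astype(float),
                pheno["case"].to_numpy())

    def test_fixed_seed_bit_identical(self):
        cfg = SimConfig(seed=12, n_sites=100, cohort_size=50)
        a = syndata.simulate_all(cfg)
        b = syndata.simulate_all(cfg)
        np.testing.assert_array_equal(a["cohort"]["genotypes"].dosage,
                                      b["cohort"]["genotypes"].dosage)
        np.testing.assert_array_equal(a["phenotype"].to_numpy(),
                                      b["phenotype"].to_numpy())
        np.testing.assert_array_equal(
            a["annotations"]["recomb_rate"].to_numpy(),
            b["annotations"]["recomb_rate"].to_numpy())
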