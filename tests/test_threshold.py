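import numpy as np
import pytest

from pedeval.editing import with_cg
from pedeval.mixed_model import ModelError, ModelSpec, VarianceComponents
from pedeval.simulate import SimulationConfig, simulate_records
from pedeval.threshold import (LATENT_RESIDUAL_VARIANCE, fit_threshold_model,
                               inv_logit, logit, threshold_genetic_parameters)

from conftest import no_fixed_effects, small_sim_config


def ordinal_dataset(seed=5, **kw):
    defaults = dict(
        trait_scale="ordinal-9", residual_law="logistic",
        sigma_a2=0.6, sigma_pe2=0.8, sigma_cg2=0.0,
        sigma_e2=LATENT_RESIDUAL_VARIANCE,
        thresholds=tuple(np.linspace(-2.5, 2.5, 8)),
        fixed_effects=no_fixed_effects(), dam_age_coeffs=(0.0, 0.0),
        n_founders=40, n_offspring=150, n_generations=2, n_herds=3,
        records_per_cow=(0.4, 0.3, 0.2, 0.1),
    )
    defaults.update(kw)
    ds = simulate_records(config=small_sim_config(seed=seed, **defaults))
    return with_cg(ds.records), ds.pedigree


SPEC = ModelSpec("trait", (), (), cg_role="excluded", scale="threshold")


class TestLogit:
    def test_half_maps_to_zero(self):
        assert logit(0.5) == pytest.approx(0.0)
        assert inv_logit(0.0) == pytest.approx(0.5)

    def test_round_trip(self):
        assert inv_logit(logit(0.73)) == pytest.approx(0.73, abs=1e-12)
        x = np.linspace(0.01, 0.99, 23)
        np.testing.assert_allclose(inv_logit(logit(x)), x, atol=1e-12)

    def test_domain_enforced(self):
        for bad in (0.0, 1.0, -0.2, 1.7):
            with pytest.raises(ModelError):
                logit(bad)

    def test_residual_constant(self):
        assert LATENT_RESIDUAL_VARIANCE == pytest.approx(np.pi ** 2 / 3)
        assert round(LATENT_RESIDUAL_VARIANCE, 2) == 3.29


class TestThresholdGeneticParameters:
    def test_milking_ease_m1_worked_example(self):
        vc = VarianceComponents(sigma_a2=0.90, sigma_pe2=1.24,
                                sigma_e2=LATENT_RESIDUAL_VARIANCE)
        gp = threshold_genetic_parameters(vc, "fixed")
        assert round(gp.h2, 2) == 0.17

    def test_milking_temperament_m3_worked_example(self):
        vc = VarianceComponents(sigma_a2=0.52, sigma_pe2=1.02,
                                sigma_e2=LATENT_RESIDUAL_VARIANCE,
                                sigma_cg2=1.21)
        gp = threshold_genetic_parameters(vc, "random")
        assert round(gp.h2, 2) == 0.09
        assert round(gp.r, 2) == 0.25

    def test_zero_components_zero_parameters(self):
        vc = VarianceComponents(sigma_a2=0.0, sigma_pe2=0.0,
                                sigma_e2=LATENT_RESIDUAL_VARIANCE)
        gp = threshold_genetic_parameters(vc, "fixed")
        assert gp.h2 == 0.0 and gp.r == 0.0


class TestPqlFit:
    def test_residual_fixed_at_logistic_constant(self):
        rec, ped = ordinal_dataset(seed=11)
        fit = fit_threshold_model(rec, SPEC, ped, method="pql", max_outer=8)
        assert fit.varcomp.sigma_e2 == LATENT_RESIDUAL_VARIANCE

    def test_null_variances_cutpoints_match_logit_cumfreq(self):
        rec, ped = ordinal_dataset(seed=13, sigma_a2=0.005, sigma_pe2=0.005,
                                   n_offspring=400)
        fit = fit_threshold_model(rec, SPEC, ped, method="pql", max_outer=12)
        y = rec["value"].to_numpy()
        obs = np.unique(y)
        freqs = np.array([(y == c).mean() for c in obs])
        cum = np.clip(np.cumsum(freqs)[:-1], 1e-9, 1 - 1e-9)
        expected = np.log(cum / (1 - cum))
        np.testing.assert_allclose(fit.cutpoints, expected, atol=0.05)
        var_z = np.var(fit.fitted) + 1.0
        assert fit.varcomp.sigma_a2 < 0.05
        assert fit.varcomp.sigma_pe2 < 0.05

    def test_monotone_relabel_invariance(self):
        # coarse scale (5 observed categories) so a non-trivial strictly
        # increasing relabelling inside 1..9 exists
        rec, ped = ordinal_dataset(
            seed=17, thresholds=(-1.6, -0.5, 0.5, 1.6, 12.0, 13.0, 14.0, 15.0))
        assert rec["value"].nunique() <= 5
        fit1 = fit_threshold_model(rec, SPEC, ped, method="pql", max_outer=8)
        mapping = {1: 2, 2: 4, 3: 5, 4: 7, 5: 9}
        relabeled = rec.copy()
        relabeled["value"] = relabeled["value"].map(mapping)
        fit2 = fit_threshold_model(relabeled, SPEC, ped, method="pql",
                                   max_outer=8)
        assert fit1.varcomp.sigma_a2 == pytest.approx(fit2.varcomp.sigma_a2,
                                                      rel=1e-6)
        np.testing.assert_allclose(fit1.cutpoints, fit2.cutpoints, atol=1e-6)

    def test_single_category_rejected(self):
        rec, ped = ordinal_dataset(seed=19)
        rec = rec.copy()
        rec["value"] = 5.0
        with pytest.raises(ModelError, match="2 observed"):
            fit_threshold_model(rec, SPEC, ped, method="pql")

    def test_non_score_response_rejected(self):
        rec, ped = ordinal_dataset(seed=19)
        rec = rec.copy()
        rec["value"] = rec["value"] + 0.5
        with pytest.raises(ModelError, match="integer scores"):
            fit_threshold_model(rec, SPEC, ped, method="pql")

    def test_unobserved_interior_categories_merged(self, caplog):
        rec, ped = ordinal_dataset(seed=23)
        rec = rec.copy()
        rec.loc[rec["value"].isin([4.0]), "value"] = 5.0  # empty category 4
        with caplog.at_level("INFO", logger="pedeval.threshold"):
            fit = fit_threshold_model(rec, SPEC, ped, method="pql", max_outer=5)
        assert any("merged" in r.message for r in caplog.records)
        assert fit.cutpoints.size == np.unique(rec["value"]).size - 1


class TestGibbsFit:
    def test_deterministic_given_seed(self):
        rec, ped = ordinal_dataset(seed=29, n_offspring=80)
        f1 = fit_threshold_model(rec, SPEC, ped, seed=7, n_iter=200, burn=80)
        f2 = fit_threshold_model(rec, SPEC, ped, seed=7, n_iter=200, burn=80)
        assert f1.varcomp.sigma_a2 == f2.varcomp.sigma_a2
        np.testing.assert_array_equal(f1.ebv.to_numpy(), f2.ebv.to_numpy())

    def test_residual_fixed_and_se_positive(self):
        rec, ped = ordinal_dataset(seed=31, n_offspring=80)
        fit = fit_threshold_model(rec, SPEC, ped, seed=3, n_iter=250, burn=100)
        assert fit.varcomp.sigma_e2 == LATENT_RESIDUAL_VARIANCE
        assert (fit.se_prediction.to_numpy() > 0).all()
        assert np.all(np.diff(fit.cutpoints) > 0)

    def test_location_anchoring_cutpoint_differences(self):
        # shifting the latent location (via the simulated trait mean) moves
        # the cutpoints but leaves their differences essentially unchanged
        rec1, ped1 = ordinal_dataset(seed=37, n_offspring=300)
        rec2, ped2 = ordinal_dataset(seed=37, n_offspring=300, trait_mean=0.8,
                                     thresholds=tuple(np.linspace(-2.5, 2.5, 8)))
        f1 = fit_threshold_model(rec1, SPEC, ped1, method="pql", max_outer=8)
        f2 = fit_threshold_model(rec2, SPEC, ped2, method="pql", max_outer=8)
        d1 = np.diff(f1.cutpoints)
        d2 = np.diff(f2.cutpoints)
        assert d1.size == d2.size
        np.testing.assert_allclose(d1, d2, atol=0.25)
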