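import numpy as np
import pandas as pd
import pytest

from pedeval.editing import with_cg
from pedeval.mixed_model import (ModelError, ModelSpec, VarianceComponents,
                                 assemble_and_solve_mme, build_design,
                                 genetic_parameters, model_spec,
                                 reml_estimate, screen_fixed_effects)
from pedeval.pedigree import (a_inverse, mendelian_sampling_variances,
                              relationship_matrix)
from pedeval.simulate import SimulationConfig, simulate_records

from conftest import no_fixed_effects, small_sim_config


def dataset(seed=7, **kw):
    ds = simulate_records(config=small_sim_config(seed=seed, **kw))
    return with_cg(ds.records), ds.pedigree


def dense_gls(design, A, sigma):
    """Brute-force GLS/BLUP oracle on small systems."""
    X = design.X.toarray()
    Z = design.Z.toarray()
    W = design.W.toarray()
    n = design.n
    v = design.weights if design.weights is not None else np.ones(n)
    V = (sigma["sigma_a2"] * Z @ A @ Z.T
         + sigma["sigma_pe2"] * W @ W.T
         + sigma["sigma_e2"] * np.diag(v))
    if design.S is not None:
        S = design.S.toarray()
        V += sigma["sigma_cg2"] * S @ S.T
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ design.y)
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    a = sigma["sigma_a2"] * A @ Z.T @ P @ design.y
    pev = sigma["sigma_a2"] * A - sigma["sigma_a2"] ** 2 * A @ Z.T @ P @ Z @ A
    return beta, a, P, np.diag(pev)


class TestModelSpec:
    def test_cg_random_excludes_cg_fixed(self):
        with pytest.raises(ModelError):
            ModelSpec("t", ("cg",), (), cg_role="random")

    def test_quadratic_requires_linear(self):
        with pytest.raises(ModelError, match="linear"):
            ModelSpec("t", (), ("Q",), cg_role="excluded")

    def test_roster_construction(self):
        m2 = model_spec("M2", "t")
        assert m2.cg_role == "fixed" and "cg" in m2.fixed_effects
        m4 = model_spec("M4", "t")
        assert m4.cg_role == "random" and "cg" not in m4.fixed_effects
        m1 = model_spec("M1", "t", screened=("season", "L"))
        assert m1.cg_role == "excluded"
        m3 = model_spec("M3", "t", screened=("cg", "season", "L", "Q"))
        assert m3.cg_role == "random"
        assert m3.fixed_effects == ("season",)


class TestBuildDesign:
    def test_single_record_intercept_only(self):
        rec, ped = dataset()
        one = rec.iloc[[0]]
        des = build_design(one, ModelSpec("trait", (), (), cg_role="excluded"),
                           ped)
        assert des.X.shape == (1, 1)
        assert des.X.toarray()[0, 0] == 1.0

    def test_repeated_records_duplicate_z_rows(self):
        rec, ped = dataset()
        counts = rec.groupby("cow").size()
        cow = counts[counts == 3].index[0]
        des = build_design(rec, ModelSpec("trait", (), (), cg_role="excluded"),
                           ped)
        rows = rec.index[rec["cow"] == cow]
        Z = des.Z.toarray()
        sel = Z[rec.index.get_indexer(rows)]
        assert (sel == sel[0]).all()
        assert sel[0].sum() == 1.0

    def test_z_spans_whole_pedigree(self):
        rec, ped = dataset()
        des = build_design(rec, ModelSpec("trait", (), (), cg_role="excluded"),
                           ped)
        assert des.Z.shape[1] == len(ped)

    def test_cg_fixed_vs_random_same_total_columns(self):
        rec, ped = dataset()
        fixed = build_design(rec, ModelSpec("trait", ("cg",), (), "fixed"), ped)
        rand = build_design(rec, ModelSpec("trait", (), (), "random"), ped)
        n_cg = rec["cg"].nunique()
        # reference coding drops one CG column in X; S keeps all levels
        assert rand.S.shape[1] == n_cg
        assert fixed.X.shape[1] - fixed.X.shape[1] + rand.X.shape[1] + n_cg \
            == fixed.X.shape[1] + 1

    def test_missing_animal_rejected(self):
        rec, ped = dataset()
        bad = rec.copy()
        bad.loc[bad.index[0], "cow"] = "NOT_IN_PEDIGREE"
        with pytest.raises(ModelError, match="NOT_IN_PEDIGREE"):
            build_design(bad, ModelSpec("trait", (), (), cg_role="excluded"),
                         ped)


class TestMmeSolutions:
    @pytest.mark.parametrize("cg_role", ["excluded", "random"])
    def test_matches_dense_gls(self, cg_role):
        rec, ped = dataset(seed=13, n_founders=15, n_offspring=25)
        spec = ModelSpec("trait", ("season", "diet"), ("L",), cg_role=cg_role)
        des = build_design(rec, spec, ped)
        sigma = {"sigma_a2": 6.0, "sigma_pe2": 3.0, "sigma_e2": 2.0,
                 "sigma_cg2": 1.5}
        sol = assemble_and_solve_mme(des, a_inverse(ped), sigma)
        beta, a, _, pev = dense_gls(des, relationship_matrix(ped), sigma)
        np.testing.assert_allclose(sol["beta"], beta, atol=1e-9)
        np.testing.assert_allclose(sol["a"], a, atol=1e-9)
        np.testing.assert_allclose(sol["pev_a"], pev, atol=1e-8)

    def test_parents_without_records_get_ebvs(self):
        rec, ped = dataset(seed=13)
        spec = ModelSpec("trait", (), (), cg_role="excluded")
        des = build_design(rec, spec, ped)
        sigma = {"sigma_a2": 6.0, "sigma_pe2": 3.0, "sigma_e2": 2.0}
        sol = assemble_and_solve_mme(des, a_inverse(ped), sigma)
        recorded = set(rec["cow"])
        unrecorded = [i for i, t in enumerate(ped.ids) if t not in recorded]
        # ancestors with recorded descendants receive nonzero EBVs
        assert np.abs(sol["a"][unrecorded]).max() > 0
        _, a_oracle, _, _ = dense_gls(des, relationship_matrix(ped), sigma)
        np.testing.assert_allclose(sol["a"][unrecorded], a_oracle[unrecorded],
                                   atol=1e-9)

    def test_huge_sigma_a_approaches_saturated_fit(self):
        rec, ped = dataset(seed=17)
        spec = ModelSpec("trait", (), (), cg_role="excluded")
        des = build_design(rec, spec, ped)
        sigma = {"sigma_a2": 1e8, "sigma_pe2": 1e-6, "sigma_e2": 1.0}
        sol = assemble_and_solve_mme(des, a_inverse(ped), sigma)
        fitted = sol["fitted"]
        # with lambda_a -> 0 each cow's prediction approaches its own record mean
        cow_mean = rec.groupby("cow")["value"].transform("mean").to_numpy()
        assert np.abs(fitted - cow_mean).max() < 1e-3

    def test_duplicated_records_leave_intercept_unchanged(self):
        rec, ped = dataset(seed=19)
        spec = ModelSpec("trait", (), (), cg_role="excluded")
        sigma = {"sigma_a2": 4.0, "sigma_pe2": 2.0, "sigma_e2": 1.0}
        des1 = build_design(rec, spec, ped)
        sol1 = assemble_and_solve_mme(des1, a_inverse(ped), sigma)
        doubled = pd.concat([rec, rec], ignore_index=True)
        des2 = build_design(doubled, spec, ped)
        # halve the residual weight so the doubled system carries the same
        # total information per original record
        des2.weights = np.full(des2.n, 2.0)
        sol2 = assemble_and_solve_mme(des2, a_inverse(ped), sigma)
        assert sol1["beta"][0] == pytest.approx(sol2["beta"][0], abs=1e-9)

    def test_nonpositive_variance_rejected(self):
        rec, ped = dataset()
        des = build_design(rec, ModelSpec("trait", (), (), cg_role="excluded"),
                           ped)
        with pytest.raises(ModelError, match="positive"):
            assemble_and_solve_mme(des, a_inverse(ped),
                                   {"sigma_a2": 0.0, "sigma_pe2": 1.0,
                                    "sigma_e2": 1.0})


class TestRemlGradientOracle:
    def test_gradient_matches_dense_p_matrix(self):
        # engine trace identities vs brute-force tr(P V_k) on a small system
        rec, ped = dataset(seed=23, n_founders=12, n_offspring=20)
        spec = ModelSpec("trait", ("season",), (), cg_role="random")
        des = build_design(rec, spec, ped)
        sigma = {"sigma_a2": 5.0, "sigma_pe2": 2.0, "sigma_cg2": 1.0,
                 "sigma_e2": 3.0}
        Ainv = a_inverse(ped)
        A = relationship_matrix(ped)
        sol = assemble_and_solve_mme(des, Ainv, sigma)
        sys_ = sol["system"]
        tr = sys_.trace_quantities(Ainv)
        _, _, P, _ = dense_gls(des, A, sigma)
        y = des.y
        Z, W, S = des.Z.toarray(), des.W.toarray(), des.S.toarray()
        checks = [
            ("sigma_a2", Z @ A @ Z.T, tr["t_a"], sol["a"] @ (Ainv @ sol["a"])),
            ("sigma_pe2", W @ W.T, tr["t_pe"], sol["pe"] @ sol["pe"]),
            ("sigma_cg2", S @ S.T, tr["t_cg"], sol["cg"] @ sol["cg"]),
        ]
        for name, Vk, t_k, uGu in checks:
            s2 = sigma[name]
            q = {"sigma_a2": Z.shape[1], "sigma_pe2": W.shape[1],
                 "sigma_cg2": S.shape[1]}[name]
            grad_engine = -0.5 * ((q - t_k / s2) / s2 - uGu / s2 ** 2)
            grad_oracle = -0.5 * (np.trace(P @ Vk) - y @ P @ Vk @ P @ y)
            assert grad_engine == pytest.approx(grad_oracle, abs=1e-8), name


class TestRemlEstimate:
    def test_balanced_design_matches_anova_reml(self):
        # unrelated cows, k records each, intercept-only: REML equals the
        # ANOVA estimators; only the sum sigma_a2+sigma_pe2 is identified
        rng = np.random.default_rng(42)
        n_cows, k = 200, 3
        sigma_b, sigma_e = 4.0, 2.0
        from pedeval.pedigree import PedigreeTable
        ped = PedigreeTable(ids=tuple(f"C{i}" for i in range(n_cows)),
                            sire=np.full(n_cows, -1), dam=np.full(n_cows, -1))
        u = rng.normal(0, np.sqrt(sigma_b), n_cows)
        rows = []
        for i in range(n_cows):
            for _ in range(k):
                rows.append({"cow": f"C{i}", "herd": "H1", "year": 2000,
                             "season": "dry", "evaluator": "E1", "diet": "D1",
                             "dam_age": 1800.0, "trait": "t",
                             "value": u[i] + rng.normal(0, np.sqrt(sigma_e))})
        rec = with_cg(pd.DataFrame(rows))
        spec = ModelSpec("t", (), (), cg_role="excluded")
        des = build_design(rec, spec, ped)
        fit = reml_estimate(des, a_inverse(ped), logdet_a=0.0, spec=spec)
        y = rec["value"].to_numpy().reshape(n_cows, k)
        msw = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum() / (n_cows * (k - 1))
        msb = k * ((y.mean(axis=1) - y.mean()) ** 2).sum() / (n_cows - 1)
        sigma_b_hat = (msb - msw) / k
        assert fit.varcomp.sigma_e2 == pytest.approx(msw, rel=1e-4)
        assert fit.varcomp.sigma_a2 + fit.varcomp.sigma_pe2 == pytest.approx(
            sigma_b_hat, rel=1e-3)

    def test_loglik_non_decreasing(self):
        rec, ped = dataset(seed=29)
        spec = ModelSpec("trait", ("season",), (), cg_role="excluded")
        des = build_design(rec, spec, ped)
        fit = reml_estimate(des, a_inverse(ped), spec=spec)
        diffs = np.diff(fit.ll_trace)
        assert (diffs > -1e-7).all()

    def test_translation_invariance(self):
        rec, ped = dataset(seed=31)
        spec = ModelSpec("trait", ("season",), (), cg_role="excluded")
        des1 = build_design(rec, spec, ped)
        fit1 = reml_estimate(des1, a_inverse(ped), spec=spec)
        shifted = rec.copy()
        shifted["value"] = shifted["value"] + 100.0
        des2 = build_design(shifted, spec, ped)
        fit2 = reml_estimate(des2, a_inverse(ped), spec=spec)
        # REML convergence noise differs slightly between the two runs, so
        # compare at the level the estimates are meaningful
        for key in ("sigma_a2", "sigma_pe2", "sigma_e2"):
            assert fit1.varcomp.as_dict()[key] == pytest.approx(
                fit2.varcomp.as_dict()[key], rel=1e-3, abs=1e-5)
        np.testing.assert_allclose(fit1.ebv.to_numpy(), fit2.ebv.to_numpy(),
                                   atol=1e-3)
        assert fit2.beta["intercept"] - fit1.beta["intercept"] == pytest.approx(
            100.0, abs=1e-3)

    def test_zero_additive_variance_pinned_at_floor(self):
        cfg = small_sim_config(seed=37, sigma_a2=0.0, sigma_pe2=2.0,
                               sigma_e2=1.0, n_offspring=120,
                               fixed_effects=no_fixed_effects(),
                               dam_age_coeffs=(0.0, 0.0))
        ds = simulate_records(config=cfg)
        rec = with_cg(ds.records)
        spec = ModelSpec("trait", (), (), cg_role="excluded")
        des = build_design(rec, spec, ds.pedigree)
        fit = reml_estimate(des, a_inverse(ds.pedigree), spec=spec)
        var_y = np.var(des.y)
        assert fit.varcomp.sigma_a2 < 0.02 * var_y

    def test_h2_r_bounds_hold(self):
        rec, ped = dataset(seed=41)
        spec = ModelSpec("trait", ("season",), (), cg_role="random")
        des = build_design(rec, spec, ped)
        fit = reml_estimate(des, a_inverse(ped), spec=spec)
        gp = genetic_parameters(fit.varcomp, "random")
        assert 0.0 <= gp.h2 <= gp.r <= 1.0


class TestGeneticParameters:
    def test_stature_m1_worked_example(self):
        vc = VarianceComponents(sigma_a2=8.54, sigma_pe2=5.00, sigma_e2=3.54)
        gp = genetic_parameters(vc, "fixed")
        assert round(gp.h2, 2) == 0.50
        assert round(gp.r, 2) == 0.79

    def test_stature_m3_worked_example(self):
        vc = VarianceComponents(sigma_a2=8.90, sigma_pe2=4.87, sigma_e2=3.54,
                                sigma_cg2=3.29)
        gp = genetic_parameters(vc, "random")
        assert round(gp.h2, 2) == 0.43

    def test_degenerate_limits(self):
        vc = VarianceComponents(sigma_a2=2.0, sigma_pe2=0.0, sigma_e2=0.0)
        gp = genetic_parameters(vc, "fixed")
        assert gp.h2 == pytest.approx(1.0) and gp.r == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        vc = VarianceComponents(sigma_a2=0.0, sigma_pe2=0.0, sigma_e2=0.0)
        with pytest.raises(ModelError):
            genetic_parameters(vc, "fixed")

    def test_cg_in_denominator_only_when_random(self):
        vc = VarianceComponents(sigma_a2=2.0, sigma_pe2=1.0, sigma_e2=1.0,
                                sigma_cg2=4.0)
        assert genetic_parameters(vc, "fixed").h2 == pytest.approx(0.5)
        assert genetic_parameters(vc, "random").h2 == pytest.approx(0.25)


class TestScreening:
    def test_strong_effect_retained_null_effect_mostly_dropped(self):
        kept_signal = kept_null = 0
        reps = 30
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            n = 400
            season = rng.integers(0, 2, n)
            diet = rng.integers(0, 3, n)          # pure noise factor
            y = 2.0 * season + rng.normal(size=n)
            rec = pd.DataFrame({
                "cow": [f"C{i}" for i in range(n)],
                "herd": "H1", "year": 2000,
                "season": np.where(season == 0, "dry", "rainy"),
                "evaluator": "E1",
                "diet": [f"D{d}" for d in diet],
                "dam_age": 1800.0, "trait": "t", "value": y})
            sel = screen_fixed_effects(rec, candidate_effects=("season", "diet"),
                                       covariates=())
            kept_signal += "season" in sel
            kept_null += "diet" in sel
        assert kept_signal == reps
        assert kept_null <= 0.25 * reps

    def test_zero_variance_factor_dropped(self):
        rng = np.random.default_rng(5)
        rec = pd.DataFrame({
            "cow": [f"C{i}" for i in range(50)], "herd": "H1", "year": 2000,
            "season": "dry", "evaluator": "E1", "diet": "D1",
            "dam_age": 1800.0, "trait": "t", "value": rng.normal(size=50)})
        sel = screen_fixed_effects(rec, candidate_effects=("season",),
                                   covariates=())
        assert "season" not in sel

    def test_quadratic_pulls_in_linear(self):
        rng = np.random.default_rng(8)
        n = 600
        age = rng.uniform(244, 3396, n)
        c = age - 1820.0
        y = 5e-7 * c ** 2 + rng.normal(size=n) * 0.3
        rec = pd.DataFrame({
            "cow": [f"C{i}" for i in range(n)], "herd": "H1", "year": 2000,
            "season": "dry", "evaluator": "E1", "diet": "D1",
            "dam_age": age, "trait": "t", "value": y})
        sel = screen_fixed_effects(rec, candidate_effects=(),
                                   covariates=("L", "Q"))
        assert "Q" in sel and "L" in sel
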