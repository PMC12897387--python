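"""Validation studies: oracle sweeps, parameter recovery, calibration.

These routines re-run the package's core machinery under controlled
synthetic conditions and summarise how well it behaves:

- formula consistency of the published Dairy Gir worked examples,
- A-inverse against the tabular relationship matrix on random pedigrees,
- MME solutions against a dense generalised-least-squares oracle,
- REML and threshold-model parameter recovery over replicated simulations,
- F-test screening calibration under the null,
- the qualitative CG-fixed vs CG-random pattern (goodness of fit up,
  heritability down when the CG variance moves into the denominator).

Problem sizes default to compact study conditions (hundreds of cows,
tens of replicates) so a full sweep completes on a laptop; every routine
is deterministic given its seed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import published_estimates as pub
from .editing import with_cg
from .evaluation import adjusted_r2
from .mixed_model import (ModelSpec, assemble_and_solve_mme, build_design,
                          genetic_parameters, model_spec, reml_estimate,
                          screen_fixed_effects)
from .pedigree import (PedigreeTable, a_inverse, mendelian_sampling_variances,
                       relationship_matrix, topological_sort)
from .simulate import FactorConfig, SimulationConfig, simulate_records
from .threshold import (LATENT_RESIDUAL_VARIANCE, fit_threshold_model,
                        threshold_genetic_parameters)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# worked-example formula consistency

def formula_consistency() -> pd.DataFrame:
    """h2/r recomputed from the published variance components vs printed.

    Returns one row per trait x model x parameter with the recomputed
    value, the published value and their absolute deviation.  The printed
    components are rounded to two decimals, which propagates into the
    recomputed ratios; deviations stay within ~0.015.
    """
    rows = []
    for trait, model, vc, (h2p, rp) in pub.iter_worked_examples():
        role = "random" if model.endswith(("M3", "M4")) else "fixed"
        if model.startswith("threshold"):
            gp = threshold_genetic_parameters(vc, role)
        else:
            gp = genetic_parameters(vc, role)
        for name, comp, printed in (("h2", gp.h2, h2p), ("r", gp.r, rp)):
            dec = 3 if 0 < abs(printed) < 0.01 else 2
            rows.append({
                "trait": trait, "model": model, "parameter": name,
                "computed": comp, "published": printed,
                "abs_dev": abs(comp - printed),
                "match_at_printed_precision":
                    round(comp, dec) == round(printed, dec)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# oracle sweeps

def _random_pedigree(rng, n_animals):
    n_founders = max(4, n_animals // 8)
    entries = [(f"F{i}", "0", "0") for i in range(n_founders)]
    ids = [e[0] for e in entries]
    for k in range(n_animals - n_founders):
        i, j = rng.choice(len(ids), size=2, replace=False)
        entries.append((f"X{k}", ids[i], ids[j]))
        ids.append(f"X{k}")
    return topological_sort(PedigreeTable.from_entries(entries))


def a_inverse_identity_sweep(n_pedigrees: int = 100, max_animals: int = 500,
                             seed: int = 0) -> float:
    """max |A^-1 A - I| over random pedigrees with inbreeding loops."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pedigrees):
        n = int(rng.integers(20, max_animals + 1))
        ped = _random_pedigree(rng, n)
        A = relationship_matrix(ped)
        err = np.abs(a_inverse(ped).toarray() @ A - np.eye(len(ped))).max()
        worst = max(worst, float(err))
    return worst


def mme_gls_equivalence(n_fixtures: int = 12, seed: int = 0) -> float:
    """max |MME - dense GLS| over random small fixtures (<= 200 equations)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in range(n_fixtures):
        cfg = SimulationConfig(
            n_founders=int(rng.integers(8, 16)),
            n_offspring=int(rng.integers(15, 40)), n_generations=2,
            n_herds=2, years=(2000, 2002), seed=int(rng.integers(2 ** 31)),
            records_per_cow=(0.4, 0.3, 0.2, 0.1))
        ds = simulate_records(config=cfg)
        rec = with_cg(ds.records)
        cg_role = "random" if k % 2 else "excluded"
        spec = ModelSpec("trait", ("season",), ("L",), cg_role=cg_role)
        des = build_design(rec, spec, ds.pedigree)
        A = relationship_matrix(ds.pedigree)
        sigma = {"sigma_a2": float(rng.uniform(1, 10)),
                 "sigma_pe2": float(rng.uniform(0.5, 5)),
                 "sigma_cg2": float(rng.uniform(0.5, 5)),
                 "sigma_e2": float(rng.uniform(0.5, 5))}
        sol = assemble_and_solve_mme(des, a_inverse(ds.pedigree), sigma)
        X, Z, W = des.X.toarray(), des.Z.toarray(), des.W.toarray()
        V = (sigma["sigma_a2"] * Z @ A @ Z.T + sigma["sigma_pe2"] * W @ W.T
             + sigma["sigma_e2"] * np.eye(des.n))
        if des.S is not None:
            S = des.S.toarray()
            V += sigma["sigma_cg2"] * S @ S.T
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ des.y)
        P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
        a = sigma["sigma_a2"] * A @ Z.T @ P @ des.y
        err = max(np.abs(sol["beta"] - beta).max(), np.abs(sol["a"] - a).max())
        worst = max(worst, float(err))
    return worst


# ---------------------------------------------------------------------------
# parameter recovery

#: Linear-recovery truth: the published stature variance components.
LINEAR_TRUTH = {"sigma_a2": 8.5, "sigma_pe2": 5.0, "sigma_e2": 3.5}
#: Threshold-recovery truth on the latent (logit) scale.
THRESHOLD_TRUTH = {"sigma_a2": 0.9, "sigma_pe2": 1.2}


def linear_recovery(n_replicates: int = 20, seed: int = 0,
                    n_offspring: int = 400) -> dict:
    """Mean REML estimates over replicates vs the simulated truth.

    Each replicate simulates a herdbook at the generator's study-condition
    defaults (cows with one to four records, most once; herd-year CGs with
    their own variance absorbed by the fixed CG effect of the M2 model)
    with (sigma_a2, sigma_pe2, sigma_e2) = (8.5, 5.0, 3.5), then refits by
    AI-REML under the full model with CG fixed.
    """
    rng = np.random.default_rng(seed)
    est = []
    for _ in range(n_replicates):
        cfg = SimulationConfig(seed=int(rng.integers(2 ** 31)),
                               n_offspring=n_offspring,
                               **{k: v for k, v in LINEAR_TRUTH.items()})
        ds = simulate_records(config=cfg)
        rec = with_cg(ds.records)
        spec = model_spec("M2", "trait")
        des = build_design(rec, spec, ds.pedigree)
        lda = float(np.sum(np.log(mendelian_sampling_variances(ds.pedigree))))
        fit = reml_estimate(des, a_inverse(ds.pedigree), logdet_a=lda,
                            spec=spec)
        est.append([fit.varcomp.sigma_a2, fit.varcomp.sigma_pe2,
                    fit.varcomp.sigma_e2])
    est = np.asarray(est)
    means = est.mean(axis=0)
    names = ("sigma_a2", "sigma_pe2", "sigma_e2")
    return {
        "mean": dict(zip(names, map(float, means))),
        "truth": dict(LINEAR_TRUTH),
        "rel_err": {k: float(abs(m - LINEAR_TRUTH[k]) / LINEAR_TRUTH[k])
                    for k, m in zip(names, means)},
        "n_replicates": n_replicates,
    }


def threshold_recovery(n_replicates: int = 20, seed: int = 0,
                       n_founders: int = 80, n_offspring: int = 400,
                       n_iter: int = 1500, burn: int = 500) -> dict:
    """Mean threshold-model estimates over replicates vs the latent truth.

    Scores are generated from the cumulative-logit liability model itself
    (logistic residual, variance pi^2/3) with latent (sigma_a2, sigma_pe2)
    = (0.9, 1.2), and refitted with the Gibbs estimator.
    """
    rng = np.random.default_rng(seed)
    nofx = {"season": FactorConfig(2, 0.0), "evaluator": FactorConfig(0, 0.0),
            "diet": FactorConfig(3, 0.0)}
    spec = ModelSpec("trait", (), (), cg_role="excluded", scale="threshold")
    est = []
    for _ in range(n_replicates):
        cfg = SimulationConfig(
            seed=int(rng.integers(2 ** 31)), trait_scale="ordinal-9",
            residual_law="logistic", sigma_cg2=0.0,
            sigma_e2=LATENT_RESIDUAL_VARIANCE,
            thresholds=tuple(np.linspace(-3.0, 3.0, 8)),
            fixed_effects=nofx, dam_age_coeffs=(0.0, 0.0),
            n_founders=n_founders, n_offspring=n_offspring,
            n_generations=2, n_herds=4,
            **THRESHOLD_TRUTH)
        ds = simulate_records(config=cfg)
        rec = with_cg(ds.records)
        fit = fit_threshold_model(rec, spec, ds.pedigree,
                                  seed=int(rng.integers(2 ** 31)),
                                  n_iter=n_iter, burn=burn)
        est.append([fit.varcomp.sigma_a2, fit.varcomp.sigma_pe2])
    est = np.asarray(est)
    means = est.mean(axis=0)
    names = ("sigma_a2", "sigma_pe2")
    return {
        "mean": dict(zip(names, map(float, means))),
        "truth": dict(THRESHOLD_TRUTH),
        "rel_err": {k: float(abs(m - THRESHOLD_TRUTH[k]) / THRESHOLD_TRUTH[k])
                    for k, m in zip(names, means)},
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# screening calibration

def screening_calibration(n_replicates: int = 1000, alpha: float = 0.05,
                          seed: int = 0, n_records: int = 200) -> dict:
    """Retention rate of a pure-noise factor at the given alpha.

    Each replicate draws Gaussian phenotypes with a real season effect and
    a 3-level diet factor carrying no effect; the diet retention rate
    should match alpha.
    """
    rng = np.random.default_rng(seed)
    kept = 0
    for _ in range(n_replicates):
        season = rng.integers(0, 2, n_records)
        diet = rng.integers(0, 3, n_records)
        y = 1.0 * season + rng.normal(size=n_records)
        rec = pd.DataFrame({
            "cow": [f"C{i}" for i in range(n_records)],
            "herd": "H1", "year": 2000,
            "season": np.where(season == 0, "dry", "rainy"),
            "evaluator": "E1", "diet": [f"D{d}" for d in diet],
            "dam_age": 1800.0, "trait": "t", "value": y})
        sel = screen_fixed_effects(rec, candidate_effects=("season", "diet"),
                                   covariates=(), alpha=alpha)
        kept += "diet" in sel
    return {"retention_rate": kept / n_replicates, "alpha": alpha,
            "n_replicates": n_replicates}


# ---------------------------------------------------------------------------
# CG fixed vs random qualitative pattern

def cg_random_pattern(n_replicates: int = 20, seed: int = 0,
                      n_offspring: int = 250) -> dict:
    """How often M3 (CG random) beats M1 (CG fixed) in fit while lowering h2.

    With a positive CG variance the model with CG random should show a
    goodness of fit at least as high (adjusted R-squared over fitted values
    including random effects) and a heritability no larger (the CG
    variance enters the phenotypic variance).
    """
    rng = np.random.default_rng(seed)
    r2_ok = h2_ok = 0
    for _ in range(n_replicates):
        cfg = SimulationConfig(seed=int(rng.integers(2 ** 31)),
                               n_offspring=n_offspring, n_herds=8)
        ds = simulate_records(config=cfg)
        rec = with_cg(ds.records)
        lda = float(np.sum(np.log(mendelian_sampling_variances(ds.pedigree))))
        Ainv = a_inverse(ds.pedigree)
        results = {}
        for label, spec in (
                ("M1", ModelSpec("trait", ("cg", "season", "evaluator", "diet"),
                                 ("L", "Q"), cg_role="fixed")),
                ("M3", ModelSpec("trait", ("season", "evaluator", "diet"),
                                 ("L", "Q"), cg_role="random"))):
            des = build_design(rec, spec, ds.pedigree)
            fit = reml_estimate(des, Ainv, logdet_a=lda, spec=spec)
            gp = genetic_parameters(fit.varcomp, spec.cg_role)
            results[label] = (
                adjusted_r2(des.y, fit.fitted, fit.rank_x), gp.h2)
        r2_ok += results["M3"][0] >= results["M1"][0] - 1e-9
        h2_ok += results["M3"][1] <= results["M1"][1] + 1e-9
    return {"r2_pattern_rate": r2_ok / n_replicates,
            "h2_pattern_rate": h2_ok / n_replicates,
            "n_replicates": n_replicates}
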