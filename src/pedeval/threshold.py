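"""Liability-threshold model for 9-point score traits.

Scores are modelled as a censoring of a latent liability on the logit
scale: category k is observed when tau_{k-1} < l <= tau_k, with

    l = Xb + Za + W pe (+ S d) + e,   e ~ logistic,  Var(e) = pi^2/3.

The residual variance is a property of the logistic link and is never
estimated.  Two estimators are provided:

``method='gibbs'`` (default) — a Gibbs sampler with liability
augmentation.  The logistic residual is represented through its Student-t
scale-mixture approximation (t with nu = 7.3 scaled to variance pi^2/3,
whose CDF differs from the logistic by < 1e-3), making every conditional
Gaussian: truncated-normal liabilities, a joint effects draw through the
absorbed mixed-model equations, uniform cutpoint updates, and scaled
inverse-chi-squared variance draws under flat priors.  Reported estimates
are posterior means; EBV standard errors are posterior standard
deviations.  Penalised quasi-likelihood tends to attenuate latent-scale
variance components when most cows have a single record, which is why the
sampler is the default.

``method='pql'`` — penalised quasi-likelihood (Laplace family):
Fisher-scoring working variates linearise the cumulative-logit likelihood
around the current linear predictor and the shared AI-REML engine
estimates the variance components on the weighted working model with the
residual scale fixed.  Fast, and used to warm-start the sampler.

Identifiability is anchored by omitting the intercept; the cutpoints
absorb location.  Threshold-scale heritability and repeatability use
pi^2/3 as the residual term in the phenotypic variance.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .mixed_model import (DesignMatrices, FitResult, ModelError, ModelSpec,
                          VarianceComponents, build_design, genetic_parameters,
                          reml_estimate)
from .pedigree import PedigreeTable

logger = logging.getLogger(__name__)

#: Residual variance on the logit liability scale.
LATENT_RESIDUAL_VARIANCE = np.pi ** 2 / 3.0


def logit(mu):
    """eta = log(mu / (1 - mu)) for mu in (0, 1)."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ModelError("logit requires 0 < mu < 1")
    out = np.log(mu / (1.0 - mu))
    return float(out) if out.ndim == 0 else out


def inv_logit(eta):
    """mu = 1 / (1 + exp(-eta)); exact inverse of :func:`logit`."""
    eta = np.asarray(eta, dtype=float)
    out = 1.0 / (1.0 + np.exp(-eta))
    return float(out) if out.ndim == 0 else out


def _logistic_cdf(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logistic_pdf(x):
    c = _logistic_cdf(x)
    return c * (1.0 - c)


def _category_codes(values: np.ndarray):
    """Map observed scores to consecutive 0..K-1 codes.

    Scores must lie in {1..9}; unobserved interior categories are merged
    away (logged): only the order of the observed categories matters.
    """
    vals = np.asarray(values, dtype=float)
    if np.any(vals != np.round(vals)) or vals.min() < 1 or vals.max() > 9:
        raise ModelError("threshold response must be integer scores in 1..9")
    observed = np.unique(vals)
    if observed.size < 2:
        raise ModelError("threshold model needs at least 2 observed categories")
    full = np.arange(vals.min(), vals.max() + 1)
    merged = [c for c in full if c not in observed]
    if merged:
        logger.info("unobserved interior categories merged: %s", merged)
    codes = np.searchsorted(observed, vals)
    return codes, observed


def _cutpoint_update(tau, eta, codes, n_cat, max_iter=50, tol=1e-10):
    """Newton steps on the interval log-likelihood in tau, eta held fixed."""
    tau = tau.copy()
    for _ in range(max_iter):
        grad = np.zeros(n_cat - 1)
        hess = np.zeros(n_cat - 1)
        a = np.where(codes > 0, tau[np.maximum(codes - 1, 0)] - eta, -np.inf)
        b = np.where(codes < n_cat - 1, tau[np.minimum(codes, n_cat - 2)] - eta, np.inf)
        Fa, Fb = _logistic_cdf(a), _logistic_cdf(b)
        P = np.maximum(Fb - Fa, 1e-12)
        fa, fb = _logistic_pdf(a), _logistic_pdf(b)
        dfb = fb * (1.0 - 2.0 * _logistic_cdf(b))
        dfa = fa * (1.0 - 2.0 * _logistic_cdf(a))
        # tau_j is the upper bound of category j and lower bound of j+1
        for j in range(n_cat - 1):
            up = codes == j       # tau_j enters as b
            lo = codes == j + 1   # tau_j enters as a
            grad[j] = np.sum(fb[up] / P[up]) - np.sum(fa[lo] / P[lo])
            hess[j] = (np.sum(dfb[up] / P[up] - (fb[up] / P[up]) ** 2)
                       + np.sum(-dfa[lo] / P[lo] - (fa[lo] / P[lo]) ** 2))
        step = grad / np.where(np.abs(hess) > 1e-12, -hess, 1.0)
        step = np.clip(step, -1.0, 1.0)
        tau_new = tau + step
        # keep strictly increasing
        for j in range(1, n_cat - 1):
            tau_new[j] = max(tau_new[j], tau_new[j - 1] + 1e-6)
        if np.max(np.abs(tau_new - tau)) < tol:
            tau = tau_new
            break
        tau = tau_new
    return tau


def _working_variates(tau, eta, codes, n_cat, w_floor=1e-3):
    """Fisher-scoring score and weight per record for the working model."""
    a = np.where(codes > 0, tau[np.maximum(codes - 1, 0)] - eta, -np.inf)
    b = np.where(codes < n_cat - 1, tau[np.minimum(codes, n_cat - 2)] - eta, np.inf)
    Fa, Fb = _logistic_cdf(a), _logistic_cdf(b)
    P = np.maximum(Fb - Fa, 1e-12)
    fa, fb = _logistic_pdf(a), _logistic_pdf(b)
    score = (fa - fb) / P                  # d log P / d eta
    dfa = fa * (1.0 - 2.0 * Fa)
    dfb = fb * (1.0 - 2.0 * Fb)
    hess = (dfb - dfa) / P - score ** 2    # d2 log P / d eta2 (a, b shift with -eta)
    w = np.maximum(-hess, w_floor)
    z = eta + score / w
    return z, w


def fit_threshold_model(records: pd.DataFrame, spec: ModelSpec,
                        pedigree: PedigreeTable, response: str = "value",
                        method: str = "gibbs", seed: int = 2024,
                        n_iter: int = 1800, burn: int = 600,
                        start: dict = None, max_outer: int = 40,
                        tol: float = 1e-4, dense_guard: int = 8000) -> FitResult:
    """Fit the cumulative-logit liability repeatability model.

    Returns a :class:`FitResult` whose variance components are on the
    latent (logit) scale with ``sigma_e2`` fixed at pi^2/3, plus the fitted
    cutpoints.  EBVs, permanent-environment and CG solutions are latent-
    scale.  ``method`` selects the estimator ('gibbs' default, 'pql');
    the sampler uses ``seed``, ``n_iter`` and ``burn``.
    """
    if spec.scale != "threshold":
        spec = replace(spec, scale="threshold")
    if method == "gibbs":
        return _fit_gibbs(records, spec, pedigree, response=response,
                          seed=seed, n_iter=n_iter, burn=burn,
                          dense_guard=dense_guard)
    if method != "pql":
        raise ModelError(f"unknown threshold method {method!r}")
    design = build_design(records, spec, pedigree, response=response)
    codes, observed = _category_codes(design.y)
    n_cat = observed.size

    # cutpoints initialised at the logit of the cumulative frequencies
    freqs = np.bincount(codes, minlength=n_cat) / codes.size
    tau = logit(np.clip(np.cumsum(freqs)[:-1], 1e-6, 1 - 1e-6))
    tau = np.maximum.accumulate(tau + np.arange(n_cat - 1) * 1e-9)

    from .pedigree import a_inverse, mendelian_sampling_variances
    ped = pedigree
    Ainv = a_inverse(ped)
    logdet_a = float(np.sum(np.log(mendelian_sampling_variances(ped))))

    eta = np.zeros(design.n)
    sigma = {"sigma_a2": 0.5, "sigma_pe2": 0.5}
    if spec.cg_role == "random":
        sigma["sigma_cg2"] = 0.3
    if start:
        sigma.update(start)

    fit = None
    for outer in range(1, max_outer + 1):
        tau_new = _cutpoint_update(tau, eta, codes, n_cat)
        z, w = _working_variates(tau_new, eta, codes, n_cat)
        wdesign = replace_y_weights(design, z, 1.0 / w)
        fit = reml_estimate(wdesign, Ainv, logdet_a=logdet_a,
                            start=sigma, sigma_e_fixed=1.0,
                            max_iter=50, dense_guard=dense_guard, spec=spec)
        eta_new = fit.fitted
        sig_new = {k: v for k, v in fit.varcomp.as_dict().items() if k != "sigma_e2"}
        d_tau = float(np.max(np.abs(tau_new - tau)))
        d_eta = float(np.max(np.abs(eta_new - eta))) if outer > 1 else np.inf
        d_sig = max(abs(sig_new[k] - sigma[k]) / (sigma[k] + 1e-8) for k in sig_new)
        tau, eta, sigma = tau_new, eta_new, sig_new
        logger.debug("threshold outer %d: dtau=%.2e deta=%.2e dsig=%.2e",
                     outer, d_tau, d_eta, d_sig)
        if d_tau < tol and d_sig < tol and d_eta < 10 * tol:
            break
    converged = outer < max_outer or (d_tau < tol and d_sig < tol)

    # the working-model residual scale is the linearised logistic noise; on
    # the liability scale the residual variance is the logistic constant
    vc = fit.varcomp
    vc = VarianceComponents(
        sigma_a2=vc.sigma_a2, sigma_pe2=vc.sigma_pe2,
        sigma_e2=LATENT_RESIDUAL_VARIANCE, sigma_cg2=vc.sigma_cg2,
        se=vc.se, cov=vc.cov, free_names=vc.free_names)

    # cutpoints reported on the full 1..9 labelling where possible
    return FitResult(
        spec=spec, varcomp=vc, beta=fit.beta, ebv=fit.ebv, pe=fit.pe,
        cg=fit.cg, se_prediction=fit.se_prediction, loglik=fit.loglik,
        iterations=outer, converged=converged, rank_x=fit.rank_x,
        fitted=eta, n_records=design.n, cutpoints=tau)


def replace_y_weights(design: DesignMatrices, y: np.ndarray,
                      weights: np.ndarray) -> DesignMatrices:
    """Shallow copy of a design with new response and residual weights."""
    from dataclasses import replace as dreplace
    return dreplace(design, y=np.asarray(y, dtype=float),
                    weights=np.asarray(weights, dtype=float))


def threshold_genetic_parameters(varcomp: VarianceComponents, cg_role: str):
    """h2 and r with the fixed logistic residual pi^2/3 in the denominator."""
    return genetic_parameters(varcomp, cg_role,
                              latent_residual=LATENT_RESIDUAL_VARIANCE)


# ---------------------------------------------------------------------------
# Gibbs sampler

#: Student-t approximation of the standard logistic: t(nu) scaled so the
#: residual variance equals pi^2/3.
_T_NU = 7.3
_T_SCALE2 = np.pi ** 2 * (_T_NU - 2) / (3.0 * _T_NU)


def _fit_gibbs(records, spec, pedigree, response="value", seed=2024,
               n_iter=1800, burn=600, dense_guard=8000) -> FitResult:
    from scipy.linalg import lapack
    from scipy.special import ndtr, ndtri

    from .mixed_model import MMESystem
    from .pedigree import a_inverse

    if burn >= n_iter:
        raise ModelError("burn must be smaller than n_iter")
    # PQL warm start keeps the burn-in short
    warm = fit_threshold_model(records, spec, pedigree, response=response,
                               method="pql", max_outer=4,
                               dense_guard=dense_guard)
    rng = np.random.default_rng(seed)
    design = build_design(records, spec, pedigree, response=response)
    Ainv = a_inverse(pedigree)
    ainv_dense = Ainv.toarray()
    codes, observed = _category_codes(design.y)
    K = observed.size
    n = design.n
    qa = design.Z.shape[1]
    qpe = design.W.shape[1]
    qcg = design.S.shape[1] if design.S is not None else 0

    tau = warm.cutpoints.copy()
    eta = warm.fitted.copy()
    lam = np.ones(n)
    sa = max(warm.varcomp.sigma_a2, 0.05)
    spe = max(warm.varcomp.sigma_pe2, 0.05)
    scg = max(warm.varcomp.sigma_cg2 or 0.05, 0.05) if qcg else None

    kept = 0
    sums = {"a": np.zeros(qa), "a2": np.zeros(qa), "pe": np.zeros(qpe),
            "cg": np.zeros(qcg), "beta": None, "tau": np.zeros(K - 1),
            "eta": np.zeros(n)}
    chains = {"sigma_a2": [], "sigma_pe2": []}
    if qcg:
        chains["sigma_cg2"] = []

    for it in range(n_iter):
        # 1. liabilities: truncated normal given category, eta, mixture scale
        sd_i = np.sqrt(_T_SCALE2 * lam)
        lo = np.where(codes > 0, tau[np.maximum(codes - 1, 0)], -np.inf)
        hi = np.where(codes < K - 1, tau[np.minimum(codes, K - 2)], np.inf)
        za = ndtr((lo - eta) / sd_i)
        zb = ndtr((hi - eta) / sd_i)
        u = rng.uniform(za + 1e-12, np.maximum(zb - 1e-12, za + 2e-12))
        liab = eta + sd_i * ndtri(u)
        # 2. mixture scales (t represented as inverse-gamma mixture)
        e = liab - eta
        g = rng.gamma((_T_NU + 1) / 2.0, 2.0 / (_T_NU + e ** 2 / _T_SCALE2),
                      size=n)
        lam = 1.0 / g
        # 3. joint effects draw through the absorbed MME
        sig = {"sigma_a2": sa, "sigma_pe2": spe, "sigma_e2": 1.0}
        if qcg:
            sig["sigma_cg2"] = scg
        wdes = replace_y_weights(design, liab, _T_SCALE2 * lam)
        sys_ = MMESystem(wdes, Ainv, sig, dense_guard=dense_guard,
                         ainv_dense=ainv_dense)
        to, _tp = sys_.solve_data(liab)
        z1 = rng.standard_normal(to.shape[0])
        to_draw = to + lapack.dtrtrs(sys_._chol, z1, lower=1, trans=1)[0]
        rhs_p = np.asarray(design.W.T @ (liab / (_T_SCALE2 * lam)))
        mean_p = (rhs_p - np.asarray(sys_.Cop.T @ to_draw)) / sys_.dpp
        tp_draw = mean_p + rng.standard_normal(qpe) / np.sqrt(sys_.dpp)
        eta = np.asarray(sys_.Mo @ to_draw) + np.asarray(design.W @ tp_draw)
        # 4. cutpoints: uniform between adjacent liability extremes
        for j in range(K - 1):
            a_max = liab[codes == j].max() if np.any(codes == j) else tau[j] - 0.1
            b_min = liab[codes == j + 1].min() if np.any(codes == j + 1) else tau[j] + 0.1
            tau[j] = rng.uniform(a_max, b_min)
        # 5. variances: scaled inverse-chi-squared with flat priors
        p = sys_.p
        a_vec = to_draw[p:p + qa]
        sa = float(a_vec @ (Ainv @ a_vec)) / rng.chisquare(max(qa - 2, 2))
        spe = float(tp_draw @ tp_draw) / rng.chisquare(max(qpe - 2, 2))
        if qcg:
            cg_vec = to_draw[p + qa:p + qa + qcg]
            scg = float(cg_vec @ cg_vec) / rng.chisquare(max(qcg - 2, 2))
        if it >= burn:
            kept += 1
            chains["sigma_a2"].append(sa)
            chains["sigma_pe2"].append(spe)
            if qcg:
                chains["sigma_cg2"].append(scg)
            sums["a"] += a_vec
            sums["a2"] += a_vec ** 2
            sums["pe"] += tp_draw
            if qcg:
                sums["cg"] += cg_vec
            sums["tau"] += tau
            sums["eta"] += eta
            b = to_draw[:p]
            sums["beta"] = b if sums["beta"] is None else sums["beta"] + b

    draws = np.column_stack([chains[k] for k in chains])
    cov = np.cov(draws.T) if draws.shape[1] > 1 else np.atleast_2d(np.var(draws))
    names = tuple(chains)
    se = {k: float(np.std(chains[k])) for k in chains}
    vc = VarianceComponents(
        sigma_a2=float(np.mean(chains["sigma_a2"])),
        sigma_pe2=float(np.mean(chains["sigma_pe2"])),
        sigma_e2=LATENT_RESIDUAL_VARIANCE,
        sigma_cg2=float(np.mean(chains["sigma_cg2"])) if qcg else None,
        se=se, cov=np.atleast_2d(cov), free_names=names)

    a_mean = sums["a"] / kept
    a_sd = np.sqrt(np.maximum(sums["a2"] / kept - a_mean ** 2, 0.0))
    beta = pd.Series(sums["beta"] / kept if sums["beta"] is not None else [],
                     index=design.fixed_names, name="beta")
    return FitResult(
        spec=spec, varcomp=vc,
        beta=beta,
        ebv=pd.Series(a_mean, index=list(design.animal_ids), name="ebv"),
        pe=pd.Series(sums["pe"] / kept, index=list(design.pe_ids), name="pe"),
        cg=pd.Series(sums["cg"] / kept, index=list(design.cg_ids), name="cg"),
        se_prediction=pd.Series(a_sd, index=list(design.animal_ids),
                                name="se_prediction"),
        loglik=float("nan"), iterations=n_iter, converged=True,
        rank_x=design.rank_x, fitted=sums["eta"] / kept, n_records=n,
        cutpoints=sums["tau"] / kept)
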