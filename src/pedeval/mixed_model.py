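"""Linear repeatability animal models: design, MME, AI-REML, parameters.

The model is Henderson's animal model with repeated records,

    y = Xb + Za + W pe + S d + e,

with a ~ N(0, A sigma_a2) over all pedigree animals, pe ~ N(0, I sigma_pe2)
over animals with records, optionally d ~ N(0, I sigma_cg2) over herd-year
contemporary groups, and e ~ N(0, D sigma_e2) with known diagonal weights D
(identity for ordinary linear fits; the threshold module supplies working
weights).  Variance components are estimated by restricted maximum
likelihood with average-information (AI) updates and expectation-
maximisation fallback steps, all expressed through the mixed-model
equations (MME).

Numerical strategy.  The MME coefficient matrix C is assembled sparse; the
permanent-environment equations couple only to their own animal, so they
are absorbed exactly (their block is diagonal), leaving a
fixed + animal + CG core that is factorised densely under a size guard.
One Cholesky per iteration provides solutions, log|C| and - via the
inverse of the absorbed core - the selected inverse entries needed for the
REML trace terms, prediction-error variances and EBV standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import stats
from scipy.linalg import lapack

from .pedigree import PedigreeTable

logger = logging.getLogger(__name__)

#: Effect codes: contemporary group, year, season, evaluator, diet.
FACTOR_COLUMNS = {"cg": "cg", "year": "year", "season": "season",
                  "evaluator": "evaluator", "diet": "diet"}
#: Dam-age covariates: linear (L) and quadratic (Q).
COVARIATES = ("L", "Q")


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one fitted model.

    ``fixed_effects`` is an ordered subset of {cg, year, season, evaluator,
    diet}; ``covariates`` of {L, Q} (dam age linear / quadratic).
    ``cg_role`` is 'fixed', 'random' or 'excluded'.
    """

    trait: str
    fixed_effects: tuple
    covariates: tuple = ()
    cg_role: str = "fixed"
    scale: str = "linear"        # 'linear' | 'threshold'
    name: str = ""

    def __post_init__(self):
        if self.cg_role not in ("fixed", "random", "excluded"):
            raise ModelError(f"bad cg_role {self.cg_role!r}")
        if self.cg_role == "random" and "cg" in self.fixed_effects:
            raise ModelError("cg cannot be both random and a fixed effect")
        if self.cg_role == "fixed" and "cg" not in self.fixed_effects:
            raise ModelError("cg_role='fixed' requires 'cg' among fixed_effects")
        unknown = set(self.fixed_effects) - set(FACTOR_COLUMNS)
        if unknown:
            raise ModelError(f"unknown fixed effects: {sorted(unknown)}")
        if set(self.covariates) - set(COVARIATES):
            raise ModelError("covariates must be a subset of ('L', 'Q')")
        if "Q" in self.covariates and "L" not in self.covariates:
            raise ModelError("quadratic dam age requires the linear term")
        if self.scale not in ("linear", "threshold"):
            raise ModelError(f"bad scale {self.scale!r}")

    @property
    def has_cg(self) -> bool:
        return self.cg_role != "excluded"


FULL_EFFECTS = ("season", "evaluator", "diet")


def model_spec(model: str, trait: str, screened=None, scale: str = "linear",
               covariates=("L", "Q")) -> ModelSpec:
    """Standard four-model roster.

    M2: all effects, CG fixed.  M4: all effects, CG random.  M1: screened
    effects only (CG/year kept only if screened in).  M3: screened effects
    with CG always random (herd/year factors removed from the fixed list).
    """
    model = model.upper()
    if model in ("M2", "M4"):
        fixed = FULL_EFFECTS
        cov = tuple(covariates)
        if model == "M2":
            return ModelSpec(trait, ("cg",) + fixed, cov, "fixed", scale, name="M2")
        return ModelSpec(trait, fixed, cov, "random", scale, name="M4")
    if screened is None:
        raise ModelError(f"{model} requires the screened effect list")
    screened = tuple(screened)
    cov = tuple(c for c in ("L", "Q") if c in screened)
    factors = tuple(e for e in screened if e in FACTOR_COLUMNS)
    if model == "M1":
        role = "fixed" if "cg" in factors else "excluded"
        return ModelSpec(trait, factors, cov, role, scale, name="M1")
    if model == "M3":
        factors = tuple(e for e in factors if e not in ("cg", "year"))
        return ModelSpec(trait, factors, cov, "random", scale, name="M3")
    raise ModelError(f"unknown model {model!r}")


@dataclass
class DesignMatrices:
    """Incidence matrices and level dictionaries for one model fit."""

    y: np.ndarray
    X: sp.csr_matrix
    Z: sp.csr_matrix                 # records -> all pedigree animals
    W: sp.csr_matrix                 # records -> animals with records
    S: sp.csr_matrix = None          # records -> CG (cg_role='random' only)
    fixed_names: list = field(default_factory=list)
    animal_ids: tuple = ()
    pe_ids: tuple = ()
    cg_ids: tuple = ()
    weights: np.ndarray = None       # residual variance multipliers (v_i)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def rank_x(self) -> int:
        return self.X.shape[1]


def _factor_dummies(values: pd.Series, name: str, drop_first: bool):
    levels = sorted(pd.unique(values.astype(str)))
    used = levels[1:] if drop_first else levels
    cols = []
    mats = []
    idx = pd.Categorical(values.astype(str), categories=levels).codes
    n = len(values)
    for j, lev in enumerate(levels):
        if drop_first and j == 0:
            continue
        v = sp.csr_matrix((np.ones(np.sum(idx == j)),
                           (np.flatnonzero(idx == j), np.zeros(np.sum(idx == j), dtype=int))),
                          shape=(n, 1))
        mats.append(v)
        cols.append(f"{name}[{lev}]")
    return mats, cols


def _incidence(values: pd.Series, levels) -> sp.csr_matrix:
    lookup = {lev: j for j, lev in enumerate(levels)}
    idx = np.asarray([lookup[v] for v in values])
    n = len(values)
    return sp.csr_matrix((np.ones(n), (np.arange(n), idx)), shape=(n, len(levels)))


def build_design(records: pd.DataFrame, spec: ModelSpec,
                 pedigree: PedigreeTable, response: str = "value") -> DesignMatrices:
    """Build X, Z, W (and S) from edited records.

    X uses reference-level coding with an intercept (threshold-scale models
    omit the intercept: the cutpoints absorb location).  Aliased columns
    are dropped by pivoted QR with a log entry.  Z spans all pedigree
    animals so ancestors without records receive EBVs.
    """
    if len(records) == 0:
        raise ModelError("no records to fit (did editing remove everything?)")
    if "cg" not in records.columns:
        from .editing import with_cg
        records = with_cg(records)
    missing = sorted(set(records["cow"]) - set(pedigree.ids))
    if missing:
        raise ModelError(f"record animals missing from pedigree: {missing[:10]}")

    n = len(records)
    mats, names = [], []
    if spec.scale == "linear":
        mats.append(sp.csr_matrix(np.ones((n, 1))))
        names.append("intercept")
    for eff in spec.fixed_effects:
        col = FACTOR_COLUMNS[eff]
        m, c = _factor_dummies(records[col], eff, drop_first=True)
        mats += m
        names += c
    if spec.covariates:
        from .simulate import DAM_AGE_MEAN
        age_c = records["dam_age"].astype(float).to_numpy() - DAM_AGE_MEAN
        if "L" in spec.covariates:
            mats.append(sp.csr_matrix(age_c.reshape(-1, 1)))
            names.append("dam_age_L")
        if "Q" in spec.covariates:
            mats.append(sp.csr_matrix((age_c ** 2).reshape(-1, 1) / 1.0e3))
            names.append("dam_age_Q(/1e3)")
    X = sp.hstack(mats, format="csr") if mats else sp.csr_matrix((n, 0))

    # drop aliased columns (pivoted QR on the dense fixed-effect matrix)
    if X.shape[1] > 1:
        Xd = X.toarray()
        _, R, piv = sla.qr(Xd, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        rank = int(np.sum(diag > tol))
        if rank < X.shape[1]:
            keep = np.sort(piv[:rank])
            dropped = [names[j] for j in piv[rank:]]
            logger.info("dropped %d aliased fixed-effect columns: %s",
                        len(dropped), dropped[:8])
            X = sp.csr_matrix(Xd[:, keep])
            names = [names[j] for j in keep]

    animal_ids = tuple(pedigree.ids)
    Z = _incidence(records["cow"].astype(str), animal_ids)
    pe_ids = tuple(sorted(pd.unique(records["cow"].astype(str))))
    W = _incidence(records["cow"].astype(str), pe_ids)
    S, cg_ids = None, ()
    if spec.cg_role == "random":
        cg_ids = tuple(sorted(pd.unique(records["cg"].astype(str))))
        S = _incidence(records["cg"].astype(str), cg_ids)
    y = records[response].astype(float).to_numpy()
    return DesignMatrices(y=y, X=X, Z=Z, W=W, S=S, fixed_names=names,
                          animal_ids=animal_ids, pe_ids=pe_ids, cg_ids=cg_ids)


# ---------------------------------------------------------------------------
# Fixed-effect screening (preliminary fixed-effects-only linear model)

def screen_fixed_effects(records: pd.DataFrame, candidate_effects=None,
                         covariates=("L", "Q"), alpha: float = 0.05,
                         response: str = "value") -> list:
    """Marginal F-tests of each candidate effect in an all-fixed model.

    Each effect is tested adjusted for all others (drop-one F-test at
    ``alpha``).  The dam-age hierarchy is honoured: the quadratic term is
    retained only together with the linear one, and a significant quadratic
    pulls the linear term in.  Aliased columns are dropped silently by the
    least-squares rank machinery (logged).
    """
    if candidate_effects is None:
        candidate_effects = ("cg", "season", "evaluator", "diet")
    if "cg" not in records.columns and "cg" in candidate_effects:
        from .editing import with_cg
        records = with_cg(records)
    y = records[response].astype(float).to_numpy()
    n = len(y)

    blocks = {"_intercept": np.ones((n, 1))}
    for eff in candidate_effects:
        col = FACTOR_COLUMNS[eff]
        vals = records[col].astype(str)
        levels = sorted(vals.unique())
        if len(levels) < 2:
            logger.info("screening: factor %s has a single level, dropped as aliased", eff)
            continue
        d = pd.get_dummies(pd.Categorical(vals, categories=levels), drop_first=True)
        blocks[eff] = d.to_numpy(dtype=float)
    from .simulate import DAM_AGE_MEAN
    if "L" in covariates:
        age_c = records["dam_age"].astype(float).to_numpy() - DAM_AGE_MEAN
        blocks["L"] = age_c.reshape(-1, 1)
        if "Q" in covariates:
            blocks["Q"] = (age_c ** 2).reshape(-1, 1) / 1.0e3

    def rss_of(keys):
        Xf = np.hstack([blocks[k] for k in keys])
        coef, res, rank, _ = np.linalg.lstsq(Xf, y, rcond=None)
        fit = Xf @ coef
        return float(np.sum((y - fit) ** 2)), rank

    all_keys = list(blocks)
    rss_full, rank_full = rss_of(all_keys)
    df_resid = n - rank_full
    selected = []
    pvals = {}
    for eff in [k for k in all_keys if k != "_intercept"]:
        keys = [k for k in all_keys if k != eff]
        rss_red, rank_red = rss_of(keys)
        df_eff = rank_full - rank_red
        if df_eff <= 0 or df_resid <= 0:
            pvals[eff] = 1.0
            continue
        F = ((rss_red - rss_full) / df_eff) / (rss_full / df_resid)
        pvals[eff] = float(stats.f.sf(F, df_eff, df_resid))
        if pvals[eff] < alpha:
            selected.append(eff)
    if "Q" in selected and "L" not in selected:
        selected.append("L")
    order = list(candidate_effects) + ["L", "Q"]
    selected.sort(key=order.index)
    logger.info("screening p-values: %s -> selected %s",
                {k: round(v, 4) for k, v in pvals.items()}, selected)
    return selected


# ---------------------------------------------------------------------------
# Variance components and fit results

@dataclass
class VarianceComponents:
    """REML variance components (trait units squared) with SEs."""

    sigma_a2: float
    sigma_pe2: float
    sigma_e2: float
    sigma_cg2: float = None
    se: dict = field(default_factory=dict)
    cov: np.ndarray = None          # asymptotic covariance of free components
    free_names: tuple = ()          # order of rows of ``cov``

    def as_dict(self) -> dict:
        d = {"sigma_a2": self.sigma_a2, "sigma_pe2": self.sigma_pe2,
             "sigma_e2": self.sigma_e2}
        if self.sigma_cg2 is not None:
            d["sigma_cg2"] = self.sigma_cg2
        return d


@dataclass
class GeneticParameters:
    h2: float
    r: float
    se_h2: float = np.nan
    se_r: float = np.nan


@dataclass
class FitResult:
    """Solutions, variance components and diagnostics of one REML fit."""

    spec: ModelSpec
    varcomp: VarianceComponents
    beta: pd.Series
    ebv: pd.Series                   # full-pedigree breeding values
    pe: pd.Series
    cg: pd.Series                    # empty unless cg_role='random'
    se_prediction: pd.Series         # per-animal SE of the EBV
    loglik: float
    iterations: int
    converged: bool
    rank_x: int
    fitted: np.ndarray               # Xb + Za + Wpe (+ Sd)
    n_records: int
    cutpoints: np.ndarray = None     # threshold-scale fits only
    ll_trace: list = field(default_factory=list)   # accepted REML iterations


# ---------------------------------------------------------------------------
# MME assembly, absorption of the pe block, dense core factorisation

class MMESystem:
    """One assembled MME at fixed variance ratios.

    Absorbs the (diagonal) permanent-environment block and factorises the
    fixed + animal + CG core densely.  Provides solutions, log|C|, multi-RHS
    solves and the selected-inverse quantities used by REML and by the EBV
    standard errors.  ``dense_guard`` bounds the core size.
    """

    def __init__(self, design: DesignMatrices, a_inv: sp.spmatrix,
                 sigma: dict, dense_guard: int = 8000,
                 ainv_dense: np.ndarray = None):
        self.design = design
        self.sigma = dict(sigma)
        v = design.weights if design.weights is not None else np.ones(design.n)
        rinv = 1.0 / (v * sigma["sigma_e2"])
        self.rinv = rinv
        X, Z, W, S = design.X, design.Z, design.W, design.S
        self.p = X.shape[1]
        self.qa = Z.shape[1]
        self.qpe = W.shape[1] if W is not None else 0
        self.qcg = S.shape[1] if S is not None else 0
        parts = [X, Z] + ([S] if S is not None else [])
        self.Mo = sp.hstack(parts, format="csr")
        self.W = W
        n_core = self.Mo.shape[1]
        if n_core > dense_guard:
            raise ModelError(
                f"MME core of {n_core} equations exceeds the dense guard "
                f"({dense_guard}); reduce the problem or raise the guard")
        Rinv = sp.diags(rinv)
        Coo = (self.Mo.T @ Rinv @ self.Mo).toarray()
        ga = slice(self.p, self.p + self.qa)
        if ainv_dense is not None:
            # repeated-assembly fast path (samplers): caller keeps A^-1 dense
            Coo[ga, ga] += ainv_dense * (1.0 / sigma["sigma_a2"])
        else:
            Coo[ga, ga] += (a_inv / sigma["sigma_a2"]).toarray()
        if self.qcg:
            gc = slice(self.p + self.qa, self.p + self.qa + self.qcg)
            Coo[gc, gc] += np.eye(self.qcg) / sigma["sigma_cg2"]
        if self.qpe:
            self.Cop = (self.Mo.T @ Rinv @ W).tocsc()
            self.dpp = np.asarray((W.T @ Rinv @ W).diagonal()) + 1.0 / sigma["sigma_pe2"]
            Coo -= (self.Cop @ sp.diags(1.0 / self.dpp) @ self.Cop.T).toarray()
        else:
            self.Cop, self.dpp = None, np.zeros(0)
        cf, info = lapack.dpotrf(Coo, lower=1, overwrite_a=1)
        if info != 0:
            raise ModelError(f"MME core not positive definite (dpotrf info={info})")
        self._chol = cf
        self.logdet = 2.0 * float(np.sum(np.log(np.diag(cf)))) + \
            float(np.sum(np.log(self.dpp)))
        self._inv_core = None

    # -- solving --------------------------------------------------------
    def solve_data(self, f: np.ndarray):
        """Solve the MME with data vector(s) f; returns (theta_o, theta_pe)."""
        f = np.asarray(f)
        one_d = f.ndim == 1
        F = f.reshape(-1, 1) if one_d else f
        RF = F * self.rinv[:, None]
        rhs_o = np.asarray(self.Mo.T @ RF)
        if self.qpe:
            rhs_p = np.asarray(self.W.T @ RF)
            rhs_o = rhs_o - self.Cop @ (rhs_p / self.dpp[:, None])
        to = lapack.dpotrs(self._chol, rhs_o, lower=1)[0]
        if self.qpe:
            tp = (rhs_p - np.asarray((self.Cop.T @ to))) / self.dpp[:, None]
        else:
            tp = np.zeros((0, F.shape[1]))
        if one_d:
            return to[:, 0], tp[:, 0]
        return to, tp

    def predict(self, theta_o, theta_p):
        out = np.asarray(self.Mo @ theta_o)
        if self.qpe:
            out = out + np.asarray(self.W @ theta_p)
        return out

    # -- selected inverse -----------------------------------------------
    def core_inverse(self) -> np.ndarray:
        if self._inv_core is None:
            inv, info = lapack.dpotri(self._chol, lower=1)
            if info != 0:
                raise ModelError(f"dpotri failed (info={info})")
            inv = np.tril(inv) + np.tril(inv, -1).T
            self._inv_core = inv
        return self._inv_core

    def trace_quantities(self, a_inv: sp.spmatrix) -> dict:
        """tr(A^-1 C^aa), tr(C^pepe), tr(C^cgcg) and diag(C^aa)."""
        inv = self.core_inverse()
        ga = slice(self.p, self.p + self.qa)
        Caa = inv[ga, ga]
        ai = a_inv.tocoo()
        t_a = float(np.sum(ai.data * Caa[ai.row, ai.col]))
        out = {"t_a": t_a, "diag_a": np.diag(Caa).copy()}
        if self.qcg:
            gc = slice(self.p + self.qa, self.p + self.qa + self.qcg)
            out["t_cg"] = float(np.trace(inv[gc, gc]))
        if self.qpe:
            # C^pepe_ii = 1/d_i + (c_i' S^-1 c_i) / d_i^2 with c_i the
            # coupling column of pe equation i into the absorbed core
            Cop = self.Cop.toarray()
            quad = np.einsum("ij,ij->j", Cop, inv @ Cop)
            out["t_pe"] = float(np.sum(1.0 / self.dpp) + np.sum(quad / self.dpp ** 2))
        return out


def assemble_and_solve_mme(design: DesignMatrices, a_inv: sp.spmatrix,
                           varcomp, dense_guard: int = 8000) -> dict:
    """Solve the MME at fixed variance components.

    Returns solutions (beta, a, pe, cg), the prediction-error variances of
    the animal equations (diagonal of the inverse coefficient matrix on the
    observed scale) and the system log-determinant.
    """
    sigma = varcomp.as_dict() if isinstance(varcomp, VarianceComponents) else dict(varcomp)
    for k, val in sigma.items():
        if val is not None and val <= 0:
            raise ModelError(f"{k} must be strictly positive in the MME (got {val})")
    sys_ = MMESystem(design, a_inv, sigma, dense_guard=dense_guard)
    to, tp = sys_.solve_data(design.y)
    p, qa = sys_.p, sys_.qa
    out = {
        "beta": to[:p],
        "a": to[p:p + qa],
        "pe": tp,
        "cg": to[p + qa:] if sys_.qcg else np.zeros(0),
        "fitted": sys_.predict(to, tp),
        "logdet": sys_.logdet,
        "pev_a": sys_.trace_quantities(a_inv)["diag_a"],
        "system": sys_,
    }
    return out


# ---------------------------------------------------------------------------
# AI-REML

@dataclass
class _RemlState:
    sigma: dict
    loglik: float
    system: MMESystem
    theta_o: np.ndarray
    theta_p: np.ndarray
    ehat: np.ndarray
    yPy: float
    traces: dict
    grad: np.ndarray
    ai: np.ndarray
    uGu: dict


def _reml_loglik_terms(design, sys_: MMESystem, logdet_a: float, sigma, free_cg):
    v = design.weights if design.weights is not None else np.ones(design.n)
    to, tp = sys_.solve_data(design.y)
    fitted = sys_.predict(to, tp)
    ehat = design.y - fitted
    yRy = float(np.sum(design.y * design.y * sys_.rinv))
    rhs_dot = float(np.sum(design.y * sys_.rinv * fitted))
    yPy = yRy - rhs_dot
    n = design.n
    ll = -0.5 * (sys_.logdet
                 + sys_.qa * np.log(sigma["sigma_a2"]) + logdet_a
                 + sys_.qpe * np.log(sigma["sigma_pe2"])
                 + (sys_.qcg * np.log(sigma["sigma_cg2"]) if free_cg else 0.0)
                 + n * np.log(sigma["sigma_e2"]) + float(np.sum(np.log(v)))
                 + yPy)
    return to, tp, ehat, yPy, ll


def reml_estimate(design: DesignMatrices, a_inv: sp.spmatrix,
                  logdet_a: float = None, start: dict = None,
                  sigma_e_fixed: float = None,
                  max_iter: int = 200, tol_ll: float = 1e-8,
                  tol_par: float = 1e-6, dense_guard: int = 8000,
                  spec: ModelSpec = None) -> FitResult:
    """AI-REML with EM fallback for the repeatability animal model.

    Components estimated: sigma_a2, sigma_pe2, (sigma_cg2 when the design
    carries S), and sigma_e2 unless ``sigma_e_fixed`` is given (threshold
    working models fix it).  Convergence when the relative change of the
    REML log-likelihood is < ``tol_ll`` and of every component < ``tol_par``;
    components are floored at 1e-8 of the phenotypic variance.  Non-
    convergence flags the result instead of raising.
    """
    y = design.y
    var_y = float(np.var(y))
    if var_y == 0:
        raise ModelError("response has zero variance")
    floor = 1e-8 * var_y
    has_cg = design.S is not None
    free = ["sigma_a2", "sigma_pe2"] + (["sigma_cg2"] if has_cg else [])
    e_free = sigma_e_fixed is None
    if e_free:
        free.append("sigma_e2")

    if logdet_a is None:
        lu = sp.linalg.splu(a_inv.tocsc())
        logdet_a = -float(np.sum(np.log(np.abs(lu.U.diagonal()))))

    sigma = {"sigma_a2": 0.3 * var_y, "sigma_pe2": 0.2 * var_y,
             "sigma_e2": sigma_e_fixed if not e_free else 0.4 * var_y}
    if has_cg:
        sigma["sigma_cg2"] = 0.1 * var_y
    if start:
        sigma.update({k: float(v) for k, v in start.items() if v is not None})

    q = {"sigma_a2": design.Z.shape[1], "sigma_pe2": design.W.shape[1]}
    if has_cg:
        q["sigma_cg2"] = design.S.shape[1]
    t_key = {"sigma_a2": "t_a", "sigma_pe2": "t_pe", "sigma_cg2": "t_cg"}

    def evaluate(sig) -> _RemlState:
        sys_ = MMESystem(design, a_inv, sig, dense_guard=dense_guard)
        to, tp, ehat, yPy, ll = _reml_loglik_terms(
            design, sys_, logdet_a, sig, free_cg=has_cg)
        traces = sys_.trace_quantities(a_inv)
        p, qa, qcg = sys_.p, sys_.qa, sys_.qcg
        u = {"sigma_a2": to[p:p + qa], "sigma_pe2": tp}
        if has_cg:
            u["sigma_cg2"] = to[p + qa:p + qa + qcg]
        uGu = {"sigma_a2": float(u["sigma_a2"] @ (a_inv @ u["sigma_a2"])),
               "sigma_pe2": float(u["sigma_pe2"] @ u["sigma_pe2"])}
        if has_cg:
            uGu["sigma_cg2"] = float(u["sigma_cg2"] @ u["sigma_cg2"])

        # gradient
        grad = []
        sum_trPV = 0.0
        for k in ["sigma_a2", "sigma_pe2"] + (["sigma_cg2"] if has_cg else []):
            s2 = sig[k]
            t_k = traces[t_key[k]]
            trPV = (q[k] - t_k / s2) / s2
            sum_trPV += s2 * trPV
            grad_k = -0.5 * (trPV - uGu[k] / s2 ** 2)
            grad.append(grad_k)
        if e_free:
            v = design.weights if design.weights is not None else np.ones(design.n)
            se2 = sig["sigma_e2"]
            trPD = (design.n - design.rank_x - sum_trPV) / se2
            yPDPy = float(np.sum(ehat ** 2 / v)) / se2 ** 2
            grad.append(-0.5 * (trPD - yPDPy))
        grad = np.asarray(grad)

        # average information
        Zmats = {"sigma_a2": design.Z, "sigma_pe2": design.W}
        if has_cg:
            Zmats["sigma_cg2"] = design.S
        cols = []
        for k in free:
            if k == "sigma_e2":
                cols.append(ehat / sig["sigma_e2"])
            else:
                cols.append(np.asarray(Zmats[k] @ u[k]) / sig[k])
        F = np.column_stack(cols)
        to_f, tp_f = sys_.solve_data(F)
        PF = (F - sys_.predict(to_f, tp_f)) * sys_.rinv[:, None]
        ai = 0.5 * (F.T @ PF)
        ai = 0.5 * (ai + ai.T)
        return _RemlState(sigma=dict(sig), loglik=ll, system=sys_, theta_o=to,
                          theta_p=tp, ehat=ehat, yPy=yPy, traces=traces,
                          grad=grad, ai=ai, uGu=uGu)

    # components heading for the boundary are snapped to the floor (the
    # usual boundary fix): a vanishing component otherwise decays only
    # geometrically under EM and never meets the parameter tolerance
    snap = 1e-5 * var_y

    def bound(k, value):
        if k != "sigma_e2" and value < snap:
            return floor
        return max(value, floor)

    def em_step(state: _RemlState) -> dict:
        sig = dict(state.sigma)
        for k in free:
            if k == "sigma_e2":
                sig[k] = state.sigma[k] * state.yPy / (design.n - design.rank_x)
            else:
                sig[k] = (state.uGu[k] + state.traces[t_key[k]]) / q[k]
            sig[k] = bound(k, sig[k])
        return sig

    state = evaluate(sigma)
    ll_trace = [state.loglik]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # AI (Newton) proposal with step halving into the parameter space
        try:
            delta = np.linalg.solve(state.ai, state.grad)
        except np.linalg.LinAlgError:
            delta = None
        proposal = None
        if delta is not None:
            step = 1.0
            for _ in range(8):
                cand = {k: state.sigma[k] + step * d for k, d in zip(free, delta)}
                if all(cand[k] > 0 for k in free) or \
                        all(cand[k] > 0 or state.sigma[k] <= snap for k in free):
                    proposal = {**state.sigma,
                                **{k: bound(k, cand[k]) for k in free}}
                    break
                step *= 0.5
        if proposal is None:
            proposal = em_step(state)
            used = "EM"
        else:
            used = "AI"
        new_state = evaluate(proposal)
        if new_state.loglik < state.loglik - 1e-10 and used == "AI":
            proposal = em_step(state)
            new_state = evaluate(proposal)
            used = "EM(fallback)"
        rel_ll = abs(new_state.loglik - state.loglik) / (abs(state.loglik) + 1.0)
        rel_par = max(abs(new_state.sigma[k] - state.sigma[k])
                      / (abs(state.sigma[k]) + floor) for k in free)
        logger.debug("REML iter %d [%s]: ll=%.6f sigma=%s", it, used,
                     new_state.loglik,
                     {k: round(new_state.sigma[k], 5) for k in free})
        at_floor_move = all(
            new_state.sigma[k] <= floor * 1.0001 or
            abs(new_state.sigma[k] - state.sigma[k]) / (abs(state.sigma[k]) + floor) < tol_par
            for k in free)
        state = new_state
        ll_trace.append(state.loglik)
        if rel_ll < tol_ll and (rel_par < tol_par or at_floor_move):
            converged = True
            break
    if not converged:
        logger.warning("REML did not converge in %d iterations", max_iter)

    # covariance of the free components from the final AI matrix
    try:
        cov = np.linalg.inv(state.ai)
        se = {k: float(np.sqrt(max(cov[i, i], 0.0))) for i, k in enumerate(free)}
    except np.linalg.LinAlgError:
        cov, se = None, {}

    vc = VarianceComponents(
        sigma_a2=state.sigma["sigma_a2"], sigma_pe2=state.sigma["sigma_pe2"],
        sigma_e2=state.sigma["sigma_e2"],
        sigma_cg2=state.sigma.get("sigma_cg2"),
        se=se, cov=cov, free_names=tuple(free))

    sys_ = state.system
    p, qa = sys_.p, sys_.qa
    diag_a = state.traces["diag_a"]
    beta = pd.Series(state.theta_o[:p], index=design.fixed_names, name="beta")
    ebv = pd.Series(state.theta_o[p:p + qa], index=list(design.animal_ids), name="ebv")
    pe = pd.Series(state.theta_p, index=list(design.pe_ids), name="pe")
    cg = pd.Series(state.theta_o[p + qa:p + qa + sys_.qcg],
                   index=list(design.cg_ids), name="cg")
    sep = pd.Series(np.sqrt(np.maximum(diag_a, 0.0)),
                    index=list(design.animal_ids), name="se_prediction")
    return FitResult(
        spec=spec, varcomp=vc, beta=beta, ebv=ebv, pe=pe, cg=cg,
        se_prediction=sep, loglik=state.loglik, iterations=it,
        converged=converged, rank_x=design.rank_x,
        fitted=sys_.predict(state.theta_o, state.theta_p),
        n_records=design.n, ll_trace=ll_trace)


# ---------------------------------------------------------------------------
# Genetic parameters

def genetic_parameters(varcomp: VarianceComponents, cg_role: str,
                       latent_residual: float = None) -> GeneticParameters:
    """Heritability and repeatability with delta-method standard errors.

    h2 = sa2 / T and r = (sa2 + spe2) / T with T = sa2 + spe2 + se2, plus
    scg2 in T iff ``cg_role == 'random'``.  ``latent_residual`` replaces
    se2 for threshold-scale fits (pi^2/3).
    """
    sa, spe = varcomp.sigma_a2, varcomp.sigma_pe2
    se2 = latent_residual if latent_residual is not None else varcomp.sigma_e2
    parts = [sa, spe, se2]
    if cg_role == "random":
        if varcomp.sigma_cg2 is None:
            raise ModelError("cg_role='random' but no sigma_cg2 estimate")
        parts.append(varcomp.sigma_cg2)
    T = float(sum(parts))
    if T == 0:
        raise ModelError("zero phenotypic variance")
    h2 = sa / T
    r = (sa + spe) / T

    se_h2 = se_r = np.nan
    if varcomp.cov is not None and len(varcomp.free_names):
        names = list(varcomp.free_names)
        gh = np.zeros(len(names))
        gr = np.zeros(len(names))
        for i, nm in enumerate(names):
            in_T = nm in ("sigma_a2", "sigma_pe2", "sigma_e2", "sigma_cg2") and \
                (nm != "sigma_cg2" or cg_role == "random") and \
                (nm != "sigma_e2" or latent_residual is None)
            dT = 1.0 if in_T else 0.0
            d_num_h = 1.0 if nm == "sigma_a2" else 0.0
            d_num_r = 1.0 if nm in ("sigma_a2", "sigma_pe2") else 0.0
            gh[i] = (d_num_h * T - sa * dT) / T ** 2
            gr[i] = (d_num_r * T - (sa + spe) * dT) / T ** 2
        se_h2 = float(np.sqrt(max(gh @ varcomp.cov @ gh, 0.0)))
        se_r = float(np.sqrt(max(gr @ varcomp.cov @ gr, 0.0)))
    return GeneticParameters(h2=float(h2), r=float(r), se_h2=se_h2, se_r=se_r)
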