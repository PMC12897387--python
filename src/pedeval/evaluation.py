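"""Model comparison: goodness of fit, EBV accuracy, re-ranking of bulls.

Models that differ in their fixed-effect structure cannot be compared by
their restricted likelihoods, so goodness of fit is summarised by the
adjusted R-squared of observed vs fitted values (fitted values include the
random-effect predictions).  The impact of model choice on selection
decisions is measured on proven bulls (>= 20 phenotyped daughters): EBV
accuracies from prediction-error variances with an inbreeding correction,
paired t-tests of the per-bull accuracies between models, and Spearman
rank correlations between the bulls' EBVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import PedigreeTable

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


def adjusted_r2(y, y_hat, r_x: int, n: int = None) -> float:
    """R2_adj = 1 - (N-1)(1-R2)/(N-r_x) with R2 = cor(y, y_hat)^2.

    ``r_x`` is the fixed-effect degrees of freedom (rank of X, including
    the intercept); ``y_hat`` should include random-effect predictions so
    that models moving effects between X and the random side stay
    comparable.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) != len(y_hat):
        raise EvaluationError("y and y_hat must have equal length")
    n = len(y) if n is None else int(n)
    if not (n > r_x >= 1):
        raise EvaluationError(f"need n > r_x >= 1 (n={n}, r_x={r_x})")
    if np.std(y) == 0 or np.std(y_hat) == 0:
        raise EvaluationError("zero variance in y or y_hat")
    r2 = float(np.corrcoef(y, y_hat)[0, 1] ** 2)
    return 1.0 - (n - 1) * (1.0 - r2) / (n - r_x)


def ebv_accuracy(se_i, f_i, sigma_a2: float, tol: float = 1e-8):
    """acc_i = sqrt(1 - SE_i^2 / ((1 + f_i) sigma_a2)).

    SE_i is the standard error of prediction of the EBV (the square root of
    the prediction-error variance) and f_i the animal's inbreeding
    coefficient.  Values pushed outside [0, 1] by less than ``tol`` are
    clipped with a warning; larger violations signal inconsistent inputs
    and raise.
    """
    if sigma_a2 <= 0:
        raise EvaluationError("sigma_a2 must be > 0")
    se_i = np.asarray(se_i, dtype=float)
    f_i = np.asarray(f_i, dtype=float)
    denom = (1.0 + f_i) * sigma_a2
    ratio = se_i ** 2 / denom
    if np.any(ratio > 1.0 + tol):
        worst = float(np.max(ratio))
        raise EvaluationError(
            f"SE_i^2 exceeds (1+f_i) sigma_a2 (ratio {worst:.6f}); "
            "prediction-error variance inconsistent with sigma_a2")
    if np.any(ratio > 1.0):
        logger.warning("accuracy clipped to 0 for %d animals (|excess| < %g)",
                       int(np.sum(ratio > 1.0)), tol)
    acc = np.sqrt(np.maximum(1.0 - ratio, 0.0))
    return float(acc) if acc.ndim == 0 else acc


def select_proven_bulls(records: pd.DataFrame, pedigree: PedigreeTable,
                        min_daughters: int = 20) -> list:
    """Bulls with at least ``min_daughters`` distinct phenotyped daughters."""
    sire_of = {}
    for i, animal in enumerate(pedigree.ids):
        s = pedigree.sire[i]
        if s >= 0:
            sire_of[animal] = pedigree.ids[s]
    cows = pd.unique(records["cow"].astype(str))
    counts = {}
    for cow in cows:
        s = sire_of.get(cow)
        if s is not None:
            counts[s] = counts.get(s, 0) + 1
    return sorted(b for b, c in counts.items() if c >= min_daughters)


def paired_t_test(acc_a, acc_b) -> tuple:
    """Two-sided paired t-test; returns (t, p).

    All-zero differences are reported as no difference (t=0, p=1); zero
    variance with nonzero mean is an exact separation (p reported 0).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise EvaluationError("paired vectors of equal length >= 2 required")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d.mean(), 0):
            return 0.0, 1.0
        logger.warning("paired t-test: zero variance with nonzero mean difference")
        return np.inf if d.mean() > 0 else -np.inf, 0.0
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), d.size - 1)
    return float(t), float(p)


def spearman_rank_correlation(ebv_a, ebv_b) -> float:
    """Pearson correlation of average-for-ties ranks."""
    a = np.asarray(ebv_a, dtype=float)
    b = np.asarray(ebv_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise EvaluationError("vectors of equal length >= 2 required")
    if np.std(a) == 0 or np.std(b) == 0:
        raise EvaluationError("constant vector: rank correlation undefined")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    return float(np.corrcoef(ra, rb)[0, 1])


#: Model pairs compared: fixed-effect structure (M1 vs M2), CG fixed vs
#: random (M1 vs M3, M2 vs M4), and linear vs threshold for score traits.
COMPARISON_PAIRS = [
    ("linear:M1", "linear:M2"),
    ("linear:M1", "linear:M3"),
    ("linear:M2", "linear:M4"),
    ("linear:M3", "threshold:M3"),
    ("linear:M4", "threshold:M4"),
]


@dataclass
class ComparisonReport:
    """Comparison tables for one trait across fitted models."""

    trait: str
    n_bulls: int
    bulls: list
    r2_adj: pd.Series                  # per model label
    accuracy: pd.DataFrame             # bulls x models
    mean_accuracy: pd.Series
    pairwise: pd.DataFrame             # t, p, spearman per compared pair

    def tables(self) -> dict:
        return {
            "fit": self.r2_adj.rename("r2_adj").to_frame(),
            "accuracy": self.mean_accuracy.rename("mean_accuracy").to_frame(),
            "ranking": self.pairwise,
        }


def build_comparison_report(fits: dict, records: pd.DataFrame,
                            pedigree: PedigreeTable, inbreeding: pd.Series,
                            min_daughters: int = 20,
                            pairs=None) -> ComparisonReport:
    """Assemble the comparison tables from fitted models.

    ``fits`` maps labels like 'linear:M1' or 'threshold:M3' to
    :class:`~pedeval.mixed_model.FitResult`.  Linear fits contribute
    adjusted R-squared; all fits contribute bull accuracies and EBVs.
    Requested pairs with a missing fit raise, naming the model.
    """
    if not fits:
        raise EvaluationError("no fits supplied")
    if len(fits) < 2:
        raise EvaluationError("comparison needs at least 2 fits")
    trait = next(iter(fits.values())).spec.trait
    if pairs is None:
        # default comparison families, restricted to the fitted roster
        pairs = [(a, b) for a, b in COMPARISON_PAIRS
                 if a in fits and b in fits]
    else:
        for a, b in pairs:
            for label in (a, b):
                if label not in fits:
                    raise EvaluationError(f"missing fit for model {label!r}")

    bulls = select_proven_bulls(records, pedigree, min_daughters)
    r2 = {}
    acc = {}
    for label, fit in fits.items():
        if fit.spec.scale == "linear":
            y = records[records["trait"] == trait]["value"].astype(float).to_numpy() \
                if "trait" in records.columns else records["value"].astype(float).to_numpy()
            if len(y) == fit.n_records:
                r2[label] = adjusted_r2(y, fit.fitted, fit.rank_x)
        if bulls:
            se = fit.se_prediction.reindex(bulls).to_numpy()
            f = inbreeding.reindex(bulls).fillna(0.0).to_numpy()
            acc[label] = ebv_accuracy(se, f, fit.varcomp.sigma_a2)
    accuracy = pd.DataFrame(acc, index=bulls)
    rows = []
    for a, b in pairs:
        fa, fb = fits[a], fits[b]
        ebv_a = fa.ebv.reindex(bulls).to_numpy()
        ebv_b = fb.ebv.reindex(bulls).to_numpy()
        if len(bulls) >= 2:
            t, p = paired_t_test(accuracy[a].to_numpy(), accuracy[b].to_numpy())
            rho = spearman_rank_correlation(ebv_a, ebv_b)
        else:
            t, p, rho = np.nan, np.nan, np.nan
        rows.append({"pair": f"{a} vs {b}", "t": t, "p": p, "spearman": rho})
    return ComparisonReport(
        trait=trait, n_bulls=len(bulls), bulls=bulls,
        r2_adj=pd.Series(r2), accuracy=accuracy,
        mean_accuracy=accuracy.mean(axis=0) if len(bulls) else pd.Series(dtype=float),
        pairwise=pd.DataFrame(rows))
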