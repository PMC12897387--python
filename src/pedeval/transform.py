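"""Distribution diagnostics and normalising transforms for score traits.

Score traits (9-point scales) deviate strongly from normality; before they
enter a linear mixed model they are transformed.  Candidate transforms are
log, square root, cube root, Yeo-Johnson (maximum-likelihood lambda) and
ordered quantile normalisation (rank-based inverse normal); the winner is
the one whose output has moments closest to a Gaussian, scored by
|skewness| + |kurtosis - 3|.  Threshold-model analyses always use the raw
scores; the transform applies to the linear route only (enforced by the
pipeline, not here).

Skewness and kurtosis follow plain moment conventions: g1 = m3 / m2^1.5 and
(non-excess) kurtosis m4 / m2^2, so a Gaussian has skewness 0, kurtosis 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class TransformError(ValueError):
    pass


def _moments(x: np.ndarray):
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise TransformError("need at least 3 observations")
    m = x - x.mean()
    m2 = np.mean(m ** 2)
    if m2 == 0:
        raise TransformError("constant vector: moments undefined")
    return m2, np.mean(m ** 3), np.mean(m ** 4)


def skewness(x) -> float:
    """Moment skewness g1 = m3 / m2^1.5."""
    m2, m3, _ = _moments(x)
    return float(m3 / m2 ** 1.5)


def kurtosis(x) -> float:
    """Moment (non-excess) kurtosis m4 / m2^2; Gaussian -> 3."""
    m2, _, m4 = _moments(x)
    return float(m4 / m2 ** 2)


@dataclass
class TransformResult:
    method: str
    values: np.ndarray
    skewness_before: float
    kurtosis_before: float
    skewness_after: float
    kurtosis_after: float
    note: str = ""

    @property
    def normality_score(self) -> float:
        return abs(self.skewness_after) + abs(self.kurtosis_after - 3.0)


def _safe_moments(v):
    try:
        return skewness(v), kurtosis(v)
    except TransformError:
        return np.nan, np.nan


def _result(name: str, x, z, note: str = "") -> TransformResult:
    sb, kb = _safe_moments(x)
    sa, ka = _safe_moments(z)
    return TransformResult(
        method=name, values=np.asarray(z, dtype=float),
        skewness_before=sb, kurtosis_before=kb,
        skewness_after=sa, kurtosis_after=ka, note=note,
    )


def orq_transform(x) -> TransformResult:
    """Ordered quantile normalisation: z_i = Phi^-1((r_i - 0.5) / n).

    Ranks are average-for-ties, so tied inputs map to a common quantile and
    the mapping is monotone non-decreasing.  Tie-free output is exactly a
    Gaussian quantile grid (skewness ~ 0).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise TransformError("need at least 3 observations")
    r = stats.rankdata(x, method="average")
    z = stats.norm.ppf((r - 0.5) / x.size)
    n_ties = x.size - np.unique(x).size
    return _result("orq", x, z, note=f"{n_ties} tied values (average ranks)")


def yeo_johnson_transform(x, lmbda=None) -> TransformResult:
    """Yeo-Johnson power transform; lambda by maximum likelihood if omitted."""
    x = np.asarray(x, dtype=float)
    if lmbda is None:
        z, lmbda = stats.yeojohnson(x)
    else:
        z = stats.yeojohnson(x, lmbda=lmbda)
    return _result("yeo-johnson", x, z, note=f"lambda={float(lmbda):.4f}")


_CANDIDATES = ("log", "sqrt", "cube-root", "yeo-johnson", "orq")


def select_transformation(x, candidates=_CANDIDATES, scorer=None,
                          log=None) -> TransformResult:
    """Pick the candidate transform with the best post-transform normality.

    Candidates with inadmissible domains (log needs strictly positive input,
    sqrt non-negative) are skipped with a log entry.  The default scorer is
    |skewness| + |kurtosis - 3|; a custom ``scorer(TransformResult) -> float``
    (lower is better) may be supplied.
    """
    import logging

    logger = log or logging.getLogger(__name__)
    x = np.asarray(x, dtype=float)
    scorer = scorer or (lambda res: res.normality_score)
    results = []
    for name in candidates:
        if name == "log":
            if np.any(x <= 0):
                logger.info("transform 'log' skipped: non-positive values present")
                continue
            results.append(_result("log", x, np.log(x)))
        elif name == "sqrt":
            if np.any(x < 0):
                logger.info("transform 'sqrt' skipped: negative values present")
                continue
            results.append(_result("sqrt", x, np.sqrt(x)))
        elif name == "cube-root":
            results.append(_result("cube-root", x, np.cbrt(x)))
        elif name == "yeo-johnson":
            results.append(yeo_johnson_transform(x))
        elif name == "orq":
            results.append(orq_transform(x))
        else:
            raise TransformError(f"unknown transform candidate {name!r}")
    results = [r for r in results if np.isfinite(r.normality_score)]
    if not results:
        raise TransformError("no admissible transformation candidate")
    return min(results, key=scorer)
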