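"""Age-regression models for breast composition features.

Two single-regressor families are supported, matching how breast composition
evolves with age in screening cohorts:

* logarithmic, ``y = a*ln(age) + b`` — breast tissue volume grows roughly
  logarithmically with age;
* multiplicative inverse, ``y = a/age + b`` — gland volume and percent
  density decay roughly like 1/age.

Both reduce to ordinary (optionally count-weighted) least squares on a
transformed regressor, solved in closed form from the normal equations.
Goodness of fit is summarised by the residual standard error
``RSE = sqrt(SSE / (n - p - 1))`` with a single regressor (p = 1), i.e.
``sqrt(SSE / (n - 2))``, in the units of the response.

When only grouped summaries are available (per-group n, mean, SD — the usual
form in which cohort demographics are published), the within/between
decomposition

    SSE = sum_g [ (n_g - 1) * SD_g^2 + n_g * (mean_g - yhat(age_g))^2 ]

recovers the individual-level SSE exactly whenever ages are constant within
a group, which lets the RSE of a published fit be reconstructed from a
demographics table alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

FAMILIES = ("log", "inverse")


def _transform(ages: np.ndarray, family: str) -> np.ndarray:
    ages = np.asarray(ages, dtype=float)
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")
    if family == "log":
        return np.log(ages)
    if family == "inverse":
        return 1.0 / ages
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


@dataclass
class RegressionFit:
    """Fitted single-regressor age model ``y = a*f(age) + b``.

    ``se_*``/``p_*`` come from standard linear-model theory with
    ``df = n - 2`` degrees of freedom, where for count-weighted fits
    ``n = sum(weights)`` (frequency-weight convention: a weighted fit is
    identical, SEs included, to the fit on the row-replicated data).
    """

    family: str
    a: float
    b: float
    se_a: float
    se_b: float
    p_a: float
    p_b: float
    rse: float
    df: int
    n: int
    weighted: bool = False

    def predict(self, ages) -> np.ndarray:
        """Evaluate the fitted curve at the given ages (must be > 0)."""
        return self.a * _transform(np.atleast_1d(ages), self.family) + self.b


def predict(fit: RegressionFit, ages) -> np.ndarray:
    """Functional alias for :meth:`RegressionFit.predict`."""
    return fit.predict(ages)


def fit_age_model(ages, y, family: str, weights=None) -> RegressionFit:
    """Fit ``y = a*f(age) + b`` by (count-weighted) least squares.

    Parameters
    ----------
    ages, y : array-like
        Ages in years (> 0) and the response values.
    family : {"log", "inverse"}
        Regressor transform.
    weights : array-like, optional
        Non-negative frequency weights (e.g. group counts when fitting
        group means). ``df = sum(weights) - 2`` in that case.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    if ages.shape != y.shape or ages.ndim != 1:
        raise ValueError("ages and y must be 1D arrays of equal length")
    if ages.size < 3:
        raise ValueError(f"need at least 3 points, got {ages.size}")
    x = _transform(ages, family)
    if weights is None:
        w = np.ones_like(x)
        weighted = False
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative, same length as ages, not all zero")
        weighted = True
    if np.ptp(x[w > 0]) == 0:
        raise ValueError("degenerate design: all (weighted) ages identical")

    # Closed-form weighted normal equations for [a, b].
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    a = sxy / sxx
    b = ybar - a * xbar

    resid = y - (a * x + b)
    n_eff = sw if weighted else float(ages.size)
    df = int(round(n_eff)) - 2
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    sse = (w * resid**2).sum()
    sigma2 = sse / df
    rse = float(np.sqrt(sigma2))
    se_a = float(np.sqrt(sigma2 / sxx))
    se_b = float(np.sqrt(sigma2 * (1.0 / sw + xbar**2 / sxx)))

    def pval(est, se):
        if se == 0:
            return 0.0 if est != 0 else 1.0
        return float(2.0 * stats.t.sf(abs(est / se), df))

    return RegressionFit(
        family=family,
        a=float(a),
        b=float(b),
        se_a=se_a,
        se_b=se_b,
        p_a=pval(a, se_a),
        p_b=pval(b, se_b),
        rse=rse,
        df=df,
        n=int(round(n_eff)),
        weighted=weighted,
    )


def residual_standard_error(fit: RegressionFit, ages, y) -> float:
    """RSE of ``fit`` on raw data: ``sqrt(sum((y - yhat)^2) / (n - 2))``."""
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    if ages.shape != y.shape:
        raise ValueError("ages and y must have equal shape")
    n = ages.size
    if n <= 2:
        raise ValueError(f"need n > 2 points for the RSE, got {n}")
    sse = float(np.sum((y - fit.predict(ages)) ** 2))
    return float(np.sqrt(sse / (n - 2)))


def rse_from_group_stats(group_ns, group_ages, group_means, group_sds, fit: RegressionFit) -> float:
    """Reconstruct the raw-data RSE of ``fit`` from grouped statistics.

    Uses ``SSE = sum_g [(n_g - 1) SD_g^2 + n_g (mean_g - yhat(age_g))^2]``
    and ``RSE = sqrt(SSE / (sum n_g - 2))``. Exact when ages are constant
    within each group; otherwise it evaluates the curve at the group mean
    age, the standard approximation for published demographics tables.

    ``group_sds`` are sample SDs (n-1 denominator).
    """
    ns = np.asarray(group_ns, dtype=float)
    ages = np.asarray(group_ages, dtype=float)
    means = np.asarray(group_means, dtype=float)
    sds = np.asarray(group_sds, dtype=float)
    if not (ns.shape == ages.shape == means.shape == sds.shape):
        raise ValueError("group vectors must have equal length")
    if np.any(ns < 1):
        raise ValueError("every group must have n_g >= 1")
    yhat = fit.predict(ages)
    sse = float(np.sum((ns - 1) * sds**2 + ns * (means - yhat) ** 2))
    n_total = ns.sum()
    if n_total <= 2:
        raise ValueError("total n must exceed 2")
    return float(np.sqrt(sse / (n_total - 2)))
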