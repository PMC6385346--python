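"""Greening sensitivity estimation and per-pixel trend classification.

The greening sensitivity is the slope of annual LAI_max regressed on the
proxy driver ω. The regression error model is deliberately explicit: the
residual scale s² uses divisor N−2, and the slope standard error is
σ_b = s / (σ_x √N) with σ_x the population (divisor-N) standard deviation
of the regressor — consistent with the 1/n covariance convention of the
driver PCA. A divisor switch is exposed for the sample convention.

Greening/browning maps use the non-parametric Mann-Kendall trend test on
summer-mean LAI with a two-sided p < 0.1 criterion.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .containers import AnnualSeries

__all__ = [
    "LinearFit",
    "fit_linear",
    "TrendClass",
    "mann_kendall",
    "mann_kendall_classify",
    "classify_trend_field",
]


@dataclass(frozen=True)
class LinearFit:
    """OLS fit y = a + b x with the explicit error model.

    slope/intercept are b' and a; ``resid_scale`` is s (divisor N−2);
    ``slope_se`` = s/(σ_x√N) and ``intercept_se`` = s·√(1/N + x̄²/(σ_x²N)).
    """

    slope: float
    intercept: float
    resid_scale: float
    slope_se: float
    intercept_se: float
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, AnnualSeries) and isinstance(y, AnnualSeries):
        _, xv, yv = x.align(y)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        if xv.shape != yv.shape:
            raise ValueError("x and y must have equal length")
    keep = np.isfinite(xv) & np.isfinite(yv)
    return xv[keep], yv[keep]


def fit_linear(x, y, sx_divisor: str = "n") -> LinearFit:
    """Ordinary least squares with the population-σ_x standard errors.

    Accepts aligned arrays or two AnnualSeries (aligned on common years,
    pairwise-missing dropped). Requires N ≥ 3 (s² has divisor N−2) and a
    non-constant regressor.
    """
    xv, yv = _as_xy(x, y)
    n = xv.size
    if n < 3:
        raise ValueError(f"need at least 3 points for a fit with errors, got {n}")
    dx = xv - xv.mean()
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise ValueError("regressor is constant")
    slope = float(dx @ (yv - yv.mean()) / sxx)
    intercept = float(yv.mean() - slope * xv.mean())
    resid = yv - (intercept + slope * xv)
    s2 = float(resid @ resid) / (n - 2)
    s = float(np.sqrt(max(s2, 0.0)))
    ddof = 0 if sx_divisor == "n" else 1
    sigma_x = float(np.std(xv, ddof=ddof))
    slope_se = float(s / (sigma_x * np.sqrt(n)))
    intercept_se = s * float(np.sqrt(1.0 / n + xv.mean() ** 2 / (sigma_x**2 * n)))
    return LinearFit(slope, intercept, s, slope_se, intercept_se, n)


# ---------------------------------------------------------------------------
# Mann-Kendall


def _mk_exact_p(s_obs: int, n: int) -> float:
    # Exact two-sided p from the null distribution of Kendall S (no ties):
    # S = n(n-1)/2 - 2*inv, where the inversion count has generating
    # function prod_{k=1}^{n-1} (1 + x + ... + x^k).
    counts = np.array([1.0])
    for k in range(1, n):
        counts = np.convolve(counts, np.ones(k + 1))
    counts /= counts.sum()
    total = n * (n - 1) // 2
    s_abs = abs(s_obs)
    if s_abs == 0:
        return 1.0
    # S >= s_abs  <=>  inv <= (total - s_abs)/2
    imax = (total - s_abs) // 2
    p_one = float(counts[: imax + 1].sum())
    return min(1.0, 2.0 * p_one)


def mann_kendall(values: np.ndarray) -> tuple[int, float, float, float]:
    """Mann-Kendall trend statistics: (S, var_S, z, two-sided p).

    Tie-corrected variance; exact null distribution of S for n < 10
    without ties, else the continuity-corrected normal approximation.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 values for a Mann-Kendall test")
    diff_sign = np.sign(v[None, :] - v[:, None])
    s = int(np.triu(diff_sign, 1).sum())
    _, tie_counts = np.unique(v, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    var_s = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0
    if var_s <= 0:  # all values equal
        return s, 0.0, 0.0, 1.0
    if n < 10 and ties.size == 0:
        p = _mk_exact_p(s, n)
        z = (s - np.sign(s)) / np.sqrt(var_s)
        return s, float(var_s), float(z), p
    z = (s - np.sign(s)) / np.sqrt(var_s)  # continuity correction
    p = 2.0 * float(_stats.norm.sf(abs(z)))
    return s, float(var_s), float(z), min(1.0, p)


@dataclass(frozen=True)
class TrendClass:
    """Per-pixel greening/browning classification."""

    label: str  # greening | browning | none | barren
    p_value: float
    s_statistic: int
    threshold: float


def mann_kendall_classify(
    series,
    p_threshold: float = 0.1,
    lai_floor: float | None = None,
) -> TrendClass:
    """Classify a summer-LAI pixel series as greening/browning/none/barren.

    Significant (two-sided p < threshold) positive Kendall S is greening,
    negative is browning. A pixel whose series is entirely missing — or
    never exceeds ``lai_floor`` if one is configured — is barren.
    """
    v = series.values if isinstance(series, AnnualSeries) else np.asarray(series, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size == 0 or (lai_floor is not None and np.max(finite) < lai_floor):
        return TrendClass("barren", 1.0, 0, p_threshold)
    if np.all(finite == finite[0]):
        return TrendClass("none", 1.0, 0, p_threshold)
    s, _, _, p = mann_kendall(finite)
    if p < p_threshold:
        label = "greening" if s > 0 else "browning"
    else:
        label = "none"
    return TrendClass(label, p, s, p_threshold)


_TREND_CODES = {"barren": 0, "browning": 1, "none": 2, "greening": 3}


def classify_trend_field(
    annual: np.ndarray,
    p_threshold: float = 0.1,
    lai_floor: float | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Classify every pixel of an (n_years, n_lat, n_lon) summer-LAI stack.

    Returns an integer code map (0 barren, 1 browning, 2 none, 3 greening)
    and the label fractions over non-barren (vegetated) pixels.
    """
    annual = np.asarray(annual, dtype=float)
    ny, nlat, nlon = annual.shape
    codes = np.zeros((nlat, nlon), dtype=np.int8)
    for i in range(nlat):
        for j in range(nlon):
            tc = mann_kendall_classify(annual[:, i, j], p_threshold, lai_floor)
            codes[i, j] = _TREND_CODES[tc.label]
    veg = codes > 0
    n_veg = int(veg.sum())
    fractions = {}
    for label, code in _TREND_CODES.items():
        if label == "barren":
            continue
        fractions[label] = float((codes == code).sum() / n_veg) if n_veg else 0.0
    return codes, fractions
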