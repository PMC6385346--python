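"""Emergent-constraint inference across a model ensemble.

The emergent relationship is an unweighted OLS fit of projected ΔGPP at
2×CO2 (y) on each member's historical LAI_max sensitivity (x). Its
uncertainty is quantified by case resampling: pairs are bootstrap-resampled
with replacement, a line fitted per resample, and the 68% confidence
contour σ_f(x) taken as half the central 16th-84th percentile spread of the
bootstrap-line predictions at each x. Resampling continues (m ≥ 100) until
the median best-fit line — the line of median slope and median intercept —
changes by less than a relative tolerance between consecutive m.

The constrained PDF follows the standard emergent-constraint calculus:

    P(y) = ∫ P(y|x) P(x) dx

with P(x) the Gaussian observation PDF of the observed sensitivity
(mean b', sd σ_b) and P(y|x) Gaussian around the best-fit line with scale
σ_f(x). The integral is evaluated by trapezoidal quadrature on an x-grid
spanning ±5 observation sd. The GPP→NPP conversion rescales the constrained
flux by the fractional CO2 increase over the inversion-record period and a
GPP:NPP factor of 0.5 (10% relative uncertainty), errors combined in
quadrature.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as _stats

from .sensitivity import LinearFit

__all__ = [
    "EnsemblePoint",
    "EmergentRelation",
    "ObservationPDF",
    "ConstraintResult",
    "GaussianPDF",
    "NppScaling",
    "fit_emergent_line",
    "bootstrap_contours",
    "observation_pdf",
    "constrain",
    "ensemble_gaussian_pdf",
    "scale_gpp_to_npp",
]


@dataclass(frozen=True)
class EnsemblePoint:
    """One ensemble member: (historical sensitivity ± se, ΔGPP at 2×CO2 ± sd)."""

    member: str
    sensitivity: float
    sensitivity_se: float
    dgpp: float
    dgpp_sd: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.sensitivity):
            raise ValueError(f"{self.member}: sensitivity must be finite")
        if self.sensitivity_se < 0 or self.dgpp_sd < 0:
            raise ValueError(f"{self.member}: errors must be >= 0")


@dataclass
class EmergentRelation:
    """Best-fit cross-ensemble line plus its bootstrap confidence contour.

    ``sigma_f(x)`` is half the pointwise 16-84 percentile spread of the
    retained bootstrap lines evaluated at x; alternatively a constant band
    half-width ``sigma_const`` may stand in (used for analytic checks and
    degenerate ensembles).
    """

    slope: float
    intercept: float
    r_value: float
    p_value: float
    n_points: int
    boot_slopes: np.ndarray | None = None
    boot_intercepts: np.ndarray | None = None
    n_boot: int = 0
    seed: int | None = None
    sigma_const: float | None = None

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def sigma_f(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.boot_slopes is not None and self.boot_slopes.size:
            preds = self.boot_intercepts[:, None] + self.boot_slopes[:, None] * x[None, :]
            lo, hi = np.percentile(preds, [16.0, 84.0], axis=0)
            return 0.5 * (hi - lo)
        if self.sigma_const is not None:
            return np.full(x.shape, float(self.sigma_const))
        raise ValueError("relation carries no uncertainty band (run bootstrap_contours)")


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    dx = x - x.mean()
    sxx = dx @ dx
    slope = dx @ (y - y.mean()) / sxx
    return float(slope), float(y.mean() - slope * x.mean())


def _check_points(points: Sequence[EnsemblePoint]) -> tuple[np.ndarray, np.ndarray]:
    if len(points) < 3:
        raise ValueError("need at least 3 ensemble members")
    x = np.array([p.sensitivity for p in points], dtype=float)
    y = np.array([p.dgpp for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("ensemble sensitivities are constant; no emergent relation")
    return x, y


def fit_emergent_line(
    points: Sequence[EnsemblePoint], weighted: bool = False
) -> EmergentRelation:
    """Unweighted OLS of ΔGPP on sensitivity across members, with Pearson r/p.

    Per-member sensitivity standard errors are carried for display but not
    propagated into the fit by default; ``weighted`` switches to
    inverse-variance weights on x errors (off by default).
    """
    x, y = _check_points(points)
    res = _stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    if weighted:
        se = np.array([p.sensitivity_se for p in points], dtype=float)
        if np.any(se <= 0):
            raise ValueError("weighted fit requires positive sensitivity_se")
        w = 1.0 / se**2
        wm_x = np.average(x, weights=w)
        wm_y = np.average(y, weights=w)
        slope = float(np.sum(w * (x - wm_x) * (y - wm_y)) / np.sum(w * (x - wm_x) ** 2))
        intercept = float(wm_y - slope * wm_x)
    return EmergentRelation(
        slope, intercept, float(res.rvalue), float(res.pvalue), len(points)
    )


def bootstrap_contours(
    points: Sequence[EnsemblePoint],
    m_min: int = 100,
    tol: float = 0.01,
    m_max: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    weighted: bool = False,
) -> EmergentRelation:
    """Bootstrap the emergent line to obtain the 68% confidence contour.

    Members are resampled with replacement at the original sample size; a
    resample with fewer than two distinct x values is redrawn. After each
    fit beyond m_min the median-slope/median-intercept line is compared with
    the previous one; the loop stops once both change by less than ``tol``
    relative. Fails loudly if m_max resamples do not converge.
    """
    x, y = _check_points(points)
    n = x.size
    if rng is None:
        rng = np.random.default_rng(seed)
    relation = fit_emergent_line(points, weighted=weighted)
    slopes: list[float] = []
    icpts: list[float] = []
    prev_med: tuple[float, float] | None = None
    last_change = np.inf
    converged = False
    for m in range(1, m_max + 1):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            if np.unique(x[idx]).size >= 2:
                break
        else:  # pragma: no cover - needs pathological x
            raise RuntimeError("could not draw a non-degenerate resample")
        b, a = _ols(x[idx], y[idx])
        slopes.append(b)
        icpts.append(a)
        if m >= m_min - 1:
            med = (float(np.median(slopes)), float(np.median(icpts)))
            if prev_med is not None and m >= m_min:
                denom_b = max(abs(prev_med[0]), 1e-12)
                denom_a = max(abs(prev_med[1]), 1e-12)
                last_change = max(
                    abs(med[0] - prev_med[0]) / denom_b,
                    abs(med[1] - prev_med[1]) / denom_a,
                )
                if last_change < tol:
                    converged = True
            prev_med = med
        if converged:
            break
    if not converged:
        raise RuntimeError(
            f"bootstrap median line did not converge within {m_max} resamples "
            f"(last relative change {last_change:.3g})"
        )
    relation.boot_slopes = np.asarray(slopes)
    relation.boot_intercepts = np.asarray(icpts)
    relation.n_boot = len(slopes)
    relation.seed = seed
    return relation


@dataclass(frozen=True)
class ObservationPDF:
    """Gaussian PDF of the observed sensitivity b' (point mass if sd = 0)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def is_point_mass(self) -> bool:
        return self.sd == 0.0

    def pdf(self, x) -> np.ndarray:
        if self.is_point_mass:
            raise ValueError("point-mass observation has no density")
        return _stats.norm.pdf(np.asarray(x, dtype=float), self.mean, self.sd)


def observation_pdf(fit: LinearFit) -> ObservationPDF:
    """Observation PDF from a sensitivity fit: Gaussian(b', σ_b)."""
    return ObservationPDF(fit.slope, fit.slope_se)


@dataclass
class ConstraintResult:
    """Discretized constrained PDF with moment summaries.

    The posterior is normalized on its y-grid; ``raw_integral`` records the
    quadrature mass before normalization as a grid-adequacy diagnostic.
    ``ensemble_mean``/``ensemble_sd`` (the unconstrained multi-model
    Gaussian) are attached by the pipeline when available.
    """

    y_grid: np.ndarray
    posterior: np.ndarray
    posterior_mean: float
    posterior_sd: float
    observation: ObservationPDF
    raw_integral: float
    ensemble_mean: float | None = None
    ensemble_sd: float | None = None

    def ensemble_pdf(self, y) -> np.ndarray:
        if self.ensemble_mean is None or not self.ensemble_sd:
            raise ValueError("no ensemble Gaussian attached")
        return _stats.norm.pdf(np.asarray(y, dtype=float), self.ensemble_mean, self.ensemble_sd)


def _moments(y: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    mean = float(np.trapezoid(y * p, y))
    var = float(np.trapezoid((y - mean) ** 2 * p, y))
    return mean, float(np.sqrt(max(var, 0.0)))


def _gaussian_result(
    mean: float, sd: float, obs: ObservationPDF, y_points: int, span: float = 6.0
) -> ConstraintResult:
    if sd <= 0:
        raise ValueError("degenerate posterior: zero spread everywhere")
    y = np.linspace(mean - span * sd, mean + span * sd, y_points)
    p = _stats.norm.pdf(y, mean, sd)
    p /= np.trapezoid(p, y)
    pm, ps = _moments(y, p)
    return ConstraintResult(y, p, pm, ps, obs, raw_integral=1.0)


def constrain(
    obs: ObservationPDF,
    relation: EmergentRelation,
    x_points: int = 2001,
    y_points: int = 2001,
    span_sd: float = 5.0,
) -> ConstraintResult:
    """P(y) = ∫ P(y|x) P(x) dx on a trapezoidal grid.

    The x-grid spans the observation mean ±``span_sd`` standard deviations;
    the y-grid covers every conditional mean ±6 conditional sd. If the raw
    posterior mass deviates from 1 by more than 1e-4 the grids are refined
    once (doubled) before erroring. A point-mass observation collapses to
    the conditional Gaussian at b'; a zero-width contour (collinear
    ensemble) collapses to the push-forward of the observation through the
    line.
    """
    if obs.is_point_mass:
        mu = float(relation.predict(obs.mean))
        s = float(relation.sigma_f(obs.mean)[0])
        return _gaussian_result(mu, s, obs, y_points)

    for attempt in range(2):
        nx = x_points * (2**attempt) + (x_points % 2 == 0)
        ny = y_points * (2**attempt)
        xg = np.linspace(obs.mean - span_sd * obs.sd, obs.mean + span_sd * obs.sd, nx)
        px = obs.pdf(xg)
        px = px / np.trapezoid(px, xg)
        f = relation.predict(xg)
        s = relation.sigma_f(xg)
        tiny = 1e-10 * max(1.0, float(np.max(np.abs(f))))
        if np.all(s <= tiny):
            # collinear ensemble: y = a + b x exactly, obs pushes forward
            return _gaussian_result(
                float(relation.predict(obs.mean)), abs(relation.slope) * obs.sd, obs, ny
            )
        if np.any(s <= 0.0):
            raise ValueError("sigma_f vanishes on part of the observation support")
        ylo = float(np.min(f - 6.0 * s))
        yhi = float(np.max(f + 6.0 * s))
        yg = np.linspace(ylo, yhi, ny)
        cond = _stats.norm.pdf(yg[:, None], f[None, :], s[None, :])
        dx = xg[1] - xg[0]
        w = np.full(nx, dx)
        w[0] = w[-1] = dx / 2.0  # trapezoid weights
        post = cond @ (px * w)
        raw = float(np.trapezoid(post, yg))
        if abs(raw - 1.0) <= 1e-4:
            post = post / raw
            pm, ps = _moments(yg, post)
            return ConstraintResult(yg, post, pm, ps, obs, raw_integral=raw)
    raise RuntimeError(
        f"posterior quadrature failed to normalize (integral {raw:.6f}) even "
        "after one grid refinement"
    )


@dataclass(frozen=True)
class GaussianPDF:
    """Gaussian summary (used for the unweighted multi-model-mean PDF)."""

    mean: float
    sd: float

    def pdf(self, y) -> np.ndarray:
        if self.sd == 0.0:
            raise ValueError("degenerate (zero-sd) Gaussian has no density")
        return _stats.norm.pdf(np.asarray(y, dtype=float), self.mean, self.sd)


def ensemble_gaussian_pdf(points: Sequence[EnsemblePoint]) -> GaussianPDF:
    """Gaussian PDF of the unweighted multi-model mean ΔGPP (sample sd)."""
    if len(points) < 2:
        raise ValueError("need at least 2 members for an ensemble spread")
    y = np.array([p.dgpp for p in points], dtype=float)
    return GaussianPDF(float(y.mean()), float(y.std(ddof=1)))


@dataclass(frozen=True)
class NppScaling:
    """GPP→NPP conversion inputs.

    ΔF_NPP = b · (Δ[CO2]/[CO2]_pi) · ΔF_GPP with b = 0.5 (10% relative sd);
    relative uncertainties of the GPP flux and of b combine in quadrature.
    """

    dgpp: float
    dgpp_sd: float
    delta_co2: float
    co2_pi: float = 284.0
    factor: float = 0.5
    factor_rel_sd: float = 0.10

    def __post_init__(self) -> None:
        if self.co2_pi <= 0 or self.delta_co2 < 0:
            raise ValueError("CO2 concentrations must be positive")

    def result(self) -> tuple[float, float]:
        k = self.delta_co2 / self.co2_pi
        value = self.factor * k * self.dgpp
        sd = abs(k) * math.hypot(
            self.factor * self.dgpp_sd, self.factor_rel_sd * self.factor * self.dgpp
        )
        return value, sd


def scale_gpp_to_npp(
    dgpp: float,
    dgpp_sd: float,
    delta_co2: float,
    co2_pi: float = 284.0,
    factor: float = 0.5,
    factor_rel_sd: float = 0.10,
) -> tuple[float, float]:
    """Convert a constrained ΔGPP (Pg C yr⁻¹) to an NPP enhancement ± sd."""
    return NppScaling(dgpp, dgpp_sd, delta_co2, co2_pi, factor, factor_rel_sd).result()
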