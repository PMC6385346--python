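# Methods

## The model and its assumptions

The package quantifies how strongly northern-high-latitude (NHL,
60°N–90°N) vegetation greens in response to its principal growth drivers,
and uses that observable to constrain the multi-model spread in projected
GPP enhancement at a doubling of pre-industrial CO₂ (284 ppm).

Two drivers matter in the NHL: the physiological effect of ambient CO₂ and
the radiative effect expressed as growing-season warmth, measured here as
growing degree days above 0 °C (GDD0). Over the historical period the two
are strongly collinear, so no attempt is made to separate their
contributions; instead both are standardized and reduced to their first
principal component ω, the one-dimensional projection of maximal variance.
Greening sensitivity is the OLS slope of annual-maximum leaf area index
(LAI_max) on ω. LAI_max, rather than a growing-season mean, is used because
it needs no start/end-of-season definition.

The emergent constraint assumes that across an ensemble the historical
greening sensitivity maps approximately linearly onto projected ΔGPP at
2×CO₂, and that the observed sensitivity is an unbiased draw from the same
relationship. Under those assumptions the constrained PDF is

    P(y) = ∫ P(y|x) P(x) dx,

with P(x) the Gaussian observation PDF N(b′, σ_b²) and P(y|x) Gaussian
around the best-fit line with scale σ_f(x), the bootstrap 68% contour. One
source framework prints the kernel of this integral as P{x|y}; this
implementation follows the conditional-on-x construction of the framework
it cites, which is the form the contour definition supports.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| latitude band | [60, 90], closed, by cell center | °N | NHL definition |
| covariance divisor | n (population), everywhere | — | internal consistency of Eq-style 1/n covariance; a `divisor="n-1"`/`sx_divisor` switch exists |
| LAI_max completeness | ≥ 6 non-missing months/year | — | annual max is robust to partial years; configurable |
| GDD0 completeness | all 12 months | — | a missing warm month silently biases the sum |
| calendar | gregorian (leap-aware); `noleap`, `360_day` supported | — | model vs. observational calendars change days-in-month |
| MK significance | two-sided p < 0.1 | — | greening/browning map criterion |
| bootstrap | m ≥ 100, stop when median slope and intercept both move < 1% (m_max 10⁴) | — | small-ensemble confidence contour |
| quadrature | 2001-point grids, x-span ±5 observation sd, y-span ±6 conditional sd | — | posterior mass error < 1e-4 before renormalization; auto-refines once |
| NPP scaling | b = 0.5 ± 10%, [CO₂]_pi = 284 ppm, Δ[CO₂] = 56.8 ppm | — | GPP:NPP conversion; Δ[CO₂] over the inversion-record period is a config input |
| drawdown window | ≥ 30 yr, 5-yr end means, 2-yr smoothing, gaps ≤ 2 months interpolated | — | change in summertime drawdown slope |

## Numerical choices

* **PC sign.** The sign of u₁ is arbitrary in the eigenproblem; it is fixed
  so the CO₂ loading is positive, making "sensitivity to ω" the response to
  increasing CO₂/warmth for observations and every member alike. ω is
  computed separately per dataset from that dataset's own drivers.
* **Degenerate PCA.** Exactly isotropic 2×2 covariance (λ₁ = λ₂, i.e.
  uncorrelated standardized drivers) has no defined leading axis and raises
  an error rather than returning an arbitrary direction.
* **Regression errors.** σ_b = s/(σ_x√N) with population σ_x; with the
  divisor-n convention this equals the textbook s/√Σ(x−x̄)². The empirical
  spread of fitted slopes matches σ_b (tested at N = 35).
* **Mann–Kendall.** Tie-corrected variance; exact null distribution of S
  (via the inversion-count generating function) for n < 10 without ties,
  continuity-corrected normal approximation otherwise. The statistic is
  invariant under strictly monotone transforms.
* **Bootstrap contour.** σ_f(x) is half the pointwise 16th–84th percentile
  spread of bootstrap-line predictions — the "68% contour" realized as a
  pointwise band, consistent with its use as the scale of P(y|x).
  Resamples with fewer than two distinct x are redrawn. The convergence
  criterion compares the median-slope/median-intercept line at m−1 and m.
* **Collinear ensembles** give a zero-width contour; the posterior then
  degenerates to the observation pushed through the line,
  N(f(b′), slope²σ_b²). A point-mass observation (σ_b = 0) collapses to
  the conditional N(f(b′), σ_f(b′)²). Contours below ~1e-10 relative are
  treated as collinear to absorb floating-point residue.
* **Drawdown derivative.** Forward first differences of monthly means
  (one-sided; the simplest estimator in ppm month⁻¹ — whether the original
  analysis centered it is unspecified). The final year of a window lacks
  its December difference and is dropped. The 2-year smoothing is the
  centered 2-point mean (year with its successor; edge years keep their
  single value). Adding any constant or pure linear trend changes every
  monthly difference by the same constant and cancels exactly in the
  change statistic — no detrending needed (tested to 1e-9).

## The synthetic generators: what they emulate and what they do not

The ensemble generator draws each member's latent sensitivity uniformly on
0.022–0.075 m² m⁻² per unit ω (uniform, not Gaussian, to mimic a
spread-out small ensemble), builds per-member CO₂/GDD0 driver series
(linear trends plus white noise, 1971–2005), computes ω through the real
PCA, and sets LAI_max = level + sensitivity·ω + noise. Projected ΔGPP lies
on a true emergent line with slope 90 Pg C yr⁻¹ per unit sensitivity and
intercept −0.65 (so the 0.045 observation maps to a constrained 3.4
Pg C yr⁻¹) plus residual sd 0.3, which reproduces the reported ensemble
correlation r ≈ 0.98 at n = 7. The observation record (1982–2016) carries
true sensitivity 0.045 with LAI noise 0.02 m², giving a fitted standard
error of ~0.002 — the "small observational error" regime in which the
constraint is sharp. Because the latents are uniform, the synthetic
ensemble mean (~3.7) is higher relative to the constrained value than in a
real skewed ensemble; the qualitative contrast — a posterior several times
narrower than the ensemble Gaussian — is preserved and is what the
end-to-end tests assert.

The station generator produces
ppm(t) = baseline + trend·t + A(t)·sin(2π(month−phase)/12) + ε with
A(t) = amplitude + deepening·t (defaults: 330 ppm, 1.7 ppm yr⁻¹, 8 ppm,
0.045 ppm yr⁻¹, noise 0.15 ppm — chosen so a 31-year record's
drawdown-change uncertainty is on the observed ±0.1–0.2 scale). Its
ground-truth drawdown change comes from exact first-differencing of the
noise-free closed form, independent of the estimator. For an integer phase
the unit-sinusoid maximal month-step drop is sin(π/6) = 1/2, so the truth
is ≈ −½·deepening·(n_years − 5).

Not emulated: ESM process structure (nitrogen limitation, dynamic
vegetation, phenology phase errors), autocorrelated or heteroscedastic
noise, satellite retrieval artifacts, data gaps with seasonal structure.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under the stated error model — i.i.d. Gaussian noise
around linear responses — not the realism of any particular geophysical
record.

## Problem sizes

Default study sizes are used throughout: 7-member ensembles with 35-year
records, 2001-point quadrature grids, bootstrap until the 1% median
criterion (typically m ≈ 100–150). Statistical guarantees are checked over
repeated generation: 500 replicates for bootstrap-band coverage, 200 for
end-to-end parameter recovery, 10⁶ draws for the Monte-Carlo cross-check
of the posterior quadrature.

## Known limitations

* The constraint inherits the usual emergent-constraint caveat: it is only
  as good as the assumed linear cross-ensemble relationship and the
  exchangeability of observations with members.
* σ_f(x) from a pointwise percentile band of n = 7 resamples undercovers
  slightly (empirically ~61% at the observation's x for a nominal 68%);
  the posterior interval is correspondingly a little sharp.
* Per-member sensitivity standard errors are displayed but not propagated
  into the ensemble fit (the unweighted fit matches the reference
  analysis); a weighted option exists.
* The NetCDF writer emits classic-format (NetCDF3) files via the scipy
  backend; HDF5-backed NetCDF4 inputs are not read.
* Regridding between resolutions is out of scope; fields are consumed on
  their native grid.
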