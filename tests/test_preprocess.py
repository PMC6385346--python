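"""Preprocessing: composite merging, annual reductions, GDD0 and the ω PCA."""
import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greenec import (
    AnnualSeries,
    annual_lai_max,
    area_weighted_nhl_mean,
    compute_gdd0,
    first_principal_component,
    merge_bimonthly_to_monthly,
    standardize,
)
from greenec.containers import MonthlyField

from conftest import make_series


def _field(values, lats, lons=None, years=None):
    values = np.asarray(values, dtype=float)
    lons = np.array([0.0]) if lons is None else np.asarray(lons, dtype=float)
    years = np.array([2000]) if years is None else years
    return MonthlyField(values, years, np.asarray(lats, dtype=float), lons)


class TestMergeBimonthly:
    def test_two_composites_average_one_passes_through(self):
        comps = [
            (dt.date(2000, 1, 5), np.array([[2.0]])),
            (dt.date(2000, 1, 20), np.array([[3.0]])),
            (dt.date(2000, 2, 10), np.array([[1.7]])),
        ]
        field = merge_bimonthly_to_monthly(comps, [65.0], [0.0])
        assert field.values[0, 0, 0, 0] == 2.5
        assert field.values[0, 1, 0, 0] == 1.7

    def test_empty_month_is_missing_not_zero(self):
        comps = [(dt.date(2000, 1, 5), np.array([[2.0]]))]
        field = merge_bimonthly_to_monthly(comps, [65.0], [0.0])
        assert np.isnan(field.values[0, 2, 0, 0])

    def test_three_composites_in_month_rejected(self):
        comps = [(dt.date(2000, 1, d), np.array([[1.0]])) for d in (2, 12, 25)]
        with pytest.raises(ValueError, match="composites"):
            merge_bimonthly_to_monthly(comps, [65.0], [0.0])


class TestAnnualLaiMax:
    def test_maximum_over_months(self):
        monthly = np.array([[0.1, 0.5, 1.9, 1.2, 0.9, 0.4, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1]])
        s = annual_lai_max([2000], monthly)
        assert s.values[0] == 1.9

    def test_constant_year(self):
        s = annual_lai_max([2000], np.full((1, 12), 1.0))
        assert s.values[0] == 1.0

    def test_single_month_passes_with_relaxed_policy(self):
        monthly = np.full((1, 12), np.nan)
        monthly[0, 6] = 0.7
        assert annual_lai_max([2000], monthly, min_months=1).values[0] == 0.7

    def test_sparse_year_flagged_missing_under_default_policy(self):
        monthly = np.full((1, 12), np.nan)
        monthly[0, :5] = 1.0  # 5 < 6 required months
        assert np.isnan(annual_lai_max([2000], monthly).values[0])


class TestAreaWeightedMean:
    def test_two_cell_hand_computed_mean(self):
        vals = np.full((1, 12, 2, 1), np.nan)
        vals[0, 0] = [[1.0], [3.0]]
        field = _field(vals, [60.0, 89.0])
        expected = (np.cos(np.deg2rad(60)) * 1 + np.cos(np.deg2rad(89)) * 3) / (
            np.cos(np.deg2rad(60)) + np.cos(np.deg2rad(89))
        )
        got = area_weighted_nhl_mean(field)[0, 0]
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(1.0675, abs=5e-4)

    def test_masked_cell_excluded(self):
        vals = np.full((1, 12, 2, 1), np.nan)
        vals[0, 0] = [[np.nan], [3.0]]
        field = _field(vals, [60.0, 89.0])
        assert area_weighted_nhl_mean(field)[0, 0] == pytest.approx(3.0)

    def test_all_masked_step_missing(self):
        field = _field(np.full((1, 12, 2, 1), np.nan), [60.0, 89.0])
        assert np.all(np.isnan(area_weighted_nhl_mean(field)))

    def test_empty_band_errors(self):
        field = _field(np.zeros((1, 12, 1, 1)), [40.0])
        with pytest.raises(ValueError, match="band"):
            area_weighted_nhl_mean(field)

    @given(value=st.floats(-10, 10), mask_seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_uniform_field_returns_its_value_for_any_mask(self, value, mask_seed):
        rng = np.random.default_rng(mask_seed)
        vals = np.full((1, 12, 4, 3), value)
        mask = rng.random((4, 3)) < 0.4
        if mask.all():
            mask[0, 0] = False
        vals[:, :, mask] = np.nan
        field = _field(vals, [60.0, 70.0, 80.0, 89.0], lons=[0.0, 120.0, 240.0])
        out = area_weighted_nhl_mean(field)
        assert np.allclose(out, value, atol=1e-12)


class TestGdd0:
    def test_all_subzero_gives_zero(self):
        s = compute_gdd0([2001], np.full((1, 12), -5.0))
        assert s.values[0] == 0.0

    def test_constant_ten_degrees_365_day_year(self):
        s = compute_gdd0([2001], np.full((1, 12), 10.0))
        assert s.values[0] == 3650.0

    def test_only_july_above_zero(self):
        t = np.full((1, 12), -2.0)
        t[0, 6] = 15.0
        assert compute_gdd0([2001], t).values[0] == 15.0 * 31

    def test_leap_year_feb_counts_29_days(self):
        t = np.zeros((1, 12))
        t[0, 1] = 1.0
        assert compute_gdd0([2000], t).values[0] == 29.0

    def test_missing_month_errors_without_policy(self):
        t = np.full((1, 12), 5.0)
        t[0, 3] = np.nan
        with pytest.raises(ValueError, match="12 monthly"):
            compute_gdd0([2001], t)
        assert compute_gdd0([2001], t, allow_missing=True).values[0] > 0

    @given(st.integers(0, 11), st.floats(0.1, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_every_monthly_temperature(self, month, bump):
        base = np.linspace(-10, 12, 12)[None, :]
        bumped = base.copy()
        bumped[0, month] += bump
        lo = compute_gdd0([2001], base).values[0]
        hi = compute_gdd0([2001], bumped).values[0]
        assert hi >= lo


class TestStandardize:
    def test_closed_form(self):
        s = standardize(make_series([1.0, 2.0, 3.0]))
        assert np.allclose(s.values, [-np.sqrt(1.5), 0.0, np.sqrt(1.5)])

    def test_idempotent(self):
        s = standardize(make_series([1.0, 4.0, 2.0, 5.0]))
        again = standardize(s)
        assert np.allclose(again.values, s.values)

    def test_constant_series_errors(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(make_series([2.0, 2.0, 2.0]))


def _eig2_oracle(c11, c12, c22):
    """Closed-form eigendecomposition of a symmetric 2x2 matrix."""
    tr, det = c11 + c22, c11 * c22 - c12**2
    disc = np.sqrt(max(tr**2 / 4 - det, 0.0))
    l1, l2 = tr / 2 + disc, tr / 2 - disc
    if c12 == 0:
        v = np.array([1.0, 0.0]) if c11 >= c22 else np.array([0.0, 1.0])
    else:
        v = np.array([l1 - c22, c12])
        v = v / np.linalg.norm(v)
    if v[0] < 0:
        v = -v
    return l1, l2, v


class TestDriverPCA:
    def test_identical_drivers(self):
        z = np.sin(np.arange(10)) + 0.1 * np.arange(10)
        p = first_principal_component(make_series(z, label="CO2"), make_series(z.copy(), label="GDD0"))
        assert np.allclose(p.eigenvectors[:, 0], [1 / np.sqrt(2)] * 2)
        assert p.eigenvalues[0] == pytest.approx(2.0)
        zs = standardize(make_series(z)).values
        assert np.allclose(p.omega.values, np.sqrt(2) * zs)

    def test_anticorrelated_drivers_sign_follows_co2(self):
        z = np.cos(np.arange(12)) + 0.2 * np.arange(12)
        p = first_principal_component(make_series(z, label="CO2"), make_series(-z, label="GDD0"))
        assert p.eigenvalues[0] == pytest.approx(2.0)
        zs = standardize(make_series(z)).values
        assert np.corrcoef(p.omega.values, zs)[0, 1] > 0.999

    def test_matches_closed_form_eigen_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(size=12).cumsum()
            b = 0.5 * a + rng.normal(size=12)
            sa, sb = make_series(a, label="CO2"), make_series(b, label="GDD0")
            p = first_principal_component(sa, sb)
            za = standardize(sa).values
            zb = standardize(sb).values
            c12 = float(za @ zb) / 12
            l1, l2, u1 = _eig2_oracle(1.0, c12, 1.0)
            assert p.eigenvalues[0] == pytest.approx(l1, abs=1e-9)
            assert p.eigenvalues[1] == pytest.approx(l2, abs=1e-9)
            omega_oracle = np.column_stack([za, zb]) @ u1
            assert np.allclose(p.omega.values, omega_oracle, atol=1e-9)

    def test_variance_of_omega_equals_lambda1_and_eigvals_sum_to_two(self, rng):
        a = rng.normal(size=15).cumsum()
        b = rng.normal(size=15).cumsum()
        p = first_principal_component(make_series(a), make_series(b))
        assert np.var(p.omega.values) == pytest.approx(p.eigenvalues[0], abs=1e-9)
        assert p.eigenvalues.sum() == pytest.approx(2.0, abs=1e-9)

    @given(
        scale1=st.floats(0.1, 50), off1=st.floats(-100, 100),
        scale2=st.floats(0.1, 50), off2=st.floats(-100, 100),
    )
    @settings(max_examples=25, deadline=None)
    def test_omega_invariant_under_affine_driver_rescaling(self, scale1, off1, scale2, off2):
        a = np.sin(np.arange(12)) + 0.3 * np.arange(12)
        b = np.cos(np.arange(12)) + 0.2 * np.arange(12)
        p0 = first_principal_component(make_series(a), make_series(b))
        p1 = first_principal_component(
            make_series(scale1 * a + off1), make_series(scale2 * b + off2)
        )
        assert np.allclose(p0.omega.values, p1.omega.values, atol=1e-8)

    def test_mismatched_years_error(self):
        a = make_series(np.arange(10.0) ** 1.5, start=1990)
        b = make_series(np.arange(10.0) ** 1.2, start=1991)
        with pytest.raises(ValueError, match="identical year"):
            first_principal_component(a, b)

    def test_degenerate_isotropy_errors(self, rng):
        # exactly uncorrelated standardized drivers -> isotropic covariance
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        with pytest.raises(ValueError, match="degenerate"):
            first_principal_component(make_series(a), make_series(b))
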