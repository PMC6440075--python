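"""Cross-basis and spline-basis construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tempmort.crossbasis import (
    CrossBasisSpec,
    NaturalSpline,
    bspline_basis,
    build_crossbasis,
    cumulative_contrast,
    exposure_basis,
    lag_basis,
    lag_contrast,
)


def cox_de_boor(x, i, k, knots):
    """Independent recursive B-spline evaluation (test oracle)."""
    if k == 0:
        # half-open intervals, closed at the final knot
        if knots[i] <= x < knots[i + 1]:
            return 1.0
        if x == knots[-1] and knots[i] < knots[i + 1] == knots[-1]:
            return 1.0
        return 0.0
    left = 0.0
    if knots[i + k] != knots[i]:
        left = (x - knots[i]) / (knots[i + k] - knots[i]) * cox_de_boor(x, i, k - 1, knots)
    right = 0.0
    if knots[i + k + 1] != knots[i + 1]:
        right = (
            (knots[i + k + 1] - x)
            / (knots[i + k + 1] - knots[i + 1])
            * cox_de_boor(x, i + 1, k - 1, knots)
        )
    return left + right


class TestBSplineBasis:
    def test_partition_of_unity_with_intercept(self):
        x = np.linspace(0.0, 1.0, 57)
        b = bspline_basis(x, 2, [], (0.0, 1.0), intercept=True)
        assert b.shape == (57, 3)
        np.testing.assert_allclose(b.sum(axis=1), 1.0, atol=1e-12)

    def test_left_boundary_endpoint(self):
        b = bspline_basis([0.0], 2, [0.4], (0.0, 1.0), intercept=True)
        np.testing.assert_allclose(b[0], [1.0, 0.0, 0.0, 0.0], atol=1e-14)

    @pytest.mark.parametrize("x", [0.1, 0.25, 0.5, 0.77, 0.99])
    def test_matches_cox_de_boor_recursion(self, x):
        knots = np.array([0.0, 0.0, 0.0, 0.5, 1.0, 1.0, 1.0])
        expected = [cox_de_boor(x, i, 2, knots) for i in range(4)]
        b = bspline_basis([x], 2, [0.5], (0.0, 1.0), intercept=True)
        np.testing.assert_allclose(b[0], expected, atol=1e-12)

    def test_no_intercept_drops_first_column(self):
        x = np.linspace(0, 1, 11)
        full = bspline_basis(x, 2, [0.3], (0.0, 1.0), intercept=True)
        reduced = bspline_basis(x, 2, [0.3], (0.0, 1.0), intercept=False)
        np.testing.assert_allclose(reduced, full[:, 1:])

    def test_knot_outside_boundary_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            bspline_basis([0.5], 2, [1.5], (0.0, 1.0), intercept=True)


class TestNaturalSpline:
    def test_regression_matches_independent_ns_implementation(self):
        # fitted values frozen from R splines::ns with the same df/knots
        x = np.linspace(0, 100, 41)
        y = np.sin(x / 15) + 0.01 * x
        basis = np.c_[np.ones(41), NaturalSpline.from_data(x, 6)(x)]
        beta, *_ = np.linalg.lstsq(basis, y, rcond=None)
        fitted = basis @ beta
        expected = [0.0003657973, 1.2419641867, 0.3108110626, -0.2009297837, 1.3919467918]
        np.testing.assert_allclose(fitted[[0, 10, 20, 30, 40]], expected, atol=1e-9)

    def test_full_rank_with_intercept(self):
        x = np.linspace(0, 10, 200)
        b = NaturalSpline.from_data(x, 8)(x)
        assert b.shape == (200, 8)
        assert np.linalg.matrix_rank(np.c_[np.ones(200), b]) == 9

    def test_linear_beyond_boundary(self):
        ns = NaturalSpline.from_data(np.linspace(0, 10, 50), 5)
        outside = ns(np.array([12.0, 14.0, 16.0]))
        first = outside[1] - outside[0]
        second = outside[2] - outside[1]
        np.testing.assert_allclose(first, second, atol=1e-9)


def _random_spec(rng):
    exp_knots = rng.integers(0, 3)
    lag_knots = rng.integers(0, 3)
    return CrossBasisSpec(
        exposure_fun=rng.choice(["linear", "quadratic-bspline"]),
        exposure_knots=tuple(np.sort(rng.uniform(2, 28, exp_knots))) if exp_knots else (),
        exposure_boundary=(0.0, 30.0),
        lag_fun=rng.choice(["constant", "quadratic-bspline"]),
        lag_knots=tuple(np.sort(rng.uniform(3, 27, lag_knots))) if lag_knots else (),
        lag_max=30,
        reference_temp=rng.uniform(10, 20),
    )


def _naive_crossbasis(x, spec):
    """Triple-loop oracle for the cross-basis entries."""
    a = exposure_basis(spec, x)
    c = lag_basis(spec)
    L = spec.lag_max
    out = np.full((len(x), a.shape[1] * c.shape[1]), np.nan)
    for t in range(L, len(x)):
        for j in range(a.shape[1]):
            for k in range(c.shape[1]):
                out[t, j * c.shape[1] + k] = sum(a[t - l, j] * c[l, k] for l in range(L + 1))
    return out


class TestCrossBasis:
    def test_linear_constant_is_centred_moving_sum(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 30, 150)
        spec = CrossBasisSpec(
            exposure_fun="linear", lag_fun="constant", lag_knots=(),
            exposure_boundary=(0.0, 30.0), reference_temp=12.0,
        )
        cb = build_crossbasis(x, spec)
        for t in (30, 77, 149):
            expected = sum(x[t - l] - 12.0 for l in range(31))
            assert abs(cb.values[t, 0] - expected) < 1e-10

    def test_all_reference_exposures_give_zero_matrix(self):
        spec = CrossBasisSpec(exposure_knots=(15.0,), exposure_boundary=(0, 30), reference_temp=12.0)
        cb = build_crossbasis(np.full(60, 12.0), spec)
        np.testing.assert_allclose(cb.values[cb.valid_from :], 0.0, atol=1e-12)

    def test_zero_lag_window_reduces_to_same_day_basis(self):
        spec = CrossBasisSpec(
            exposure_knots=(15.0,), exposure_boundary=(0, 30), lag_fun="constant",
            lag_knots=(), lag_max=0, reference_temp=12.0,
        )
        x = np.linspace(1, 29, 40)
        cb = build_crossbasis(x, spec)
        np.testing.assert_allclose(cb.values, exposure_basis(spec, x), atol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spec = _random_spec(rng)
        x = rng.uniform(0, 30, 70)
        cb = build_crossbasis(x, spec)
        naive = _naive_crossbasis(x, spec)
        np.testing.assert_allclose(cb.values[30:], naive[30:], atol=1e-10)

    def test_first_lag_rows_flagged_missing(self):
        spec = CrossBasisSpec(exposure_boundary=(0, 30))
        cb = build_crossbasis(np.linspace(1, 29, 50), spec)
        assert cb.valid_from == 30
        assert np.isnan(cb.values[:30]).all()
        assert np.isfinite(cb.values[30:]).all()

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            build_crossbasis(np.ones(20), CrossBasisSpec(exposure_boundary=(0, 2)))

    def test_model11_shape_has_12_columns(self):
        spec = CrossBasisSpec(
            exposure_knots=(13.5,), exposure_boundary=(0, 30), lag_knots=(15.0,)
        )
        assert spec.n_exposure_basis == 3
        assert spec.n_lag_basis == 4
        assert spec.n_columns == 12


class TestContrasts:
    def test_reference_gives_zero_weights(self):
        spec = CrossBasisSpec(exposure_knots=(15.0,), exposure_boundary=(0, 30), reference_temp=12.0)
        np.testing.assert_allclose(cumulative_contrast(spec, 12.0), 0.0, atol=1e-12)

    def test_linear_constant_weight_is_lag_window_length(self):
        spec = CrossBasisSpec(
            exposure_fun="linear", lag_fun="constant", lag_knots=(),
            exposure_boundary=(0, 30), reference_temp=12.0,
        )
        np.testing.assert_allclose(cumulative_contrast(spec, 13.0), [31.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_lag_slice_sums_to_cumulative(self, seed):
        rng = np.random.default_rng(seed)
        spec = _random_spec(rng)
        temp = rng.uniform(0, 30)
        w_cum = cumulative_contrast(spec, temp)
        w_lag = lag_contrast(spec, temp)
        np.testing.assert_allclose(w_lag.sum(axis=0), w_cum, atol=1e-10)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(temp=st.floats(0.0, 30.0), seed=st.integers(0, 10))
    def test_zero_coefficients_give_zero_log_rr(self, temp, seed):
        spec = _random_spec(np.random.default_rng(seed))
        w = cumulative_contrast(spec, temp)
        assert w @ np.zeros_like(w) == 0.0
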