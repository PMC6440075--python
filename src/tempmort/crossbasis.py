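"""Bi-dimensional cross-basis construction for distributed lag non-linear models.

A DLNM encodes a simultaneously non-linear and delayed effect of a daily
exposure (here temperature) on a count outcome through a *cross-basis*: the
tensor product of an exposure-response basis ``f(x)`` and a lag-response
basis ``w(l)``, summed over a lag window ``0..L``.  The resulting design
block enters an ordinary regression, and linear contrasts of its
coefficients yield the exposure-lag-response surface, lag-response slices
and the overall cumulative exposure-response curve.

The exposure basis is centred at a reference temperature so that the fitted
relative risk equals 1 there; the lag basis carries the intercept of the
tensor product (the standard identifiable parameterisation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "CrossBasisSpec",
    "CrossBasisMatrix",
    "bspline_basis",
    "NaturalSpline",
    "natural_spline_basis",
    "exposure_basis",
    "lag_basis",
    "build_crossbasis",
    "cumulative_contrast",
    "lag_contrast",
]

#: label of a linear exposure-response function
LINEAR = "linear"
#: label of a quadratic B-spline exposure- or lag-response function
QUAD_BSPLINE = "quadratic-bspline"
#: label of a constant (1 df) lag-response function
CONSTANT = "constant"

_BSPLINE_DEGREE = 2  # quadratic throughout


@dataclass(frozen=True)
class CrossBasisSpec:
    """Parameterisation of the two marginal bases of a cross-basis.

    Parameters
    ----------
    exposure_fun : {"linear", "quadratic-bspline"}
        Shape of the exposure-response function ``f(x)``.  The B-spline
        variant has no intercept (1 basis column per df beyond the dropped
        first function), giving ``2 + #knots`` columns.
    exposure_knots : interior knots (degC) of the exposure spline.
    exposure_boundary : (low, high) boundary knots in degC.
    lag_fun : {"constant", "quadratic-bspline"}
        Shape of the lag-response function ``w(l)``.  The B-spline variant
        keeps its intercept, giving ``3 + #knots`` columns; the constant
        variant is a single column of ones (1 df).
    lag_knots : interior knots (days) of the lag spline.
    lag_max : maximum lag L in days (window is 0..L).
    reference_temp : temperature (degC) at which log-RR is fixed to 0.
    """

    exposure_fun: str = QUAD_BSPLINE
    exposure_knots: tuple[float, ...] = ()
    exposure_boundary: tuple[float, float] = (0.0, 30.0)
    lag_fun: str = QUAD_BSPLINE
    lag_knots: tuple[float, ...] = (15.0,)
    lag_max: int = 30
    reference_temp: float = 15.0

    def __post_init__(self) -> None:
        if self.exposure_fun not in (LINEAR, QUAD_BSPLINE):
            raise ValueError(f"unknown exposure_fun {self.exposure_fun!r}")
        if self.lag_fun not in (CONSTANT, QUAD_BSPLINE):
            raise ValueError(f"unknown lag_fun {self.lag_fun!r}")
        if self.lag_max < 0:
            raise ValueError("lag_max must be >= 0")
        lo, hi = self.exposure_boundary
        if not lo < hi:
            raise ValueError("exposure boundary must satisfy low < high")
        for k in self.exposure_knots:
            if not lo < k < hi:
                raise ValueError(f"exposure knot {k} outside boundary ({lo}, {hi})")
        for k in self.lag_knots:
            if not 0 < k < self.lag_max:
                raise ValueError(f"lag knot {k} outside (0, {self.lag_max})")
        object.__setattr__(self, "exposure_knots", tuple(float(k) for k in self.exposure_knots))
        object.__setattr__(self, "lag_knots", tuple(float(k) for k in self.lag_knots))

    @property
    def n_exposure_basis(self) -> int:
        """Number of exposure basis columns v_x."""
        if self.exposure_fun == LINEAR:
            return 1
        return _BSPLINE_DEGREE + len(self.exposure_knots)

    @property
    def n_lag_basis(self) -> int:
        """Number of lag basis columns v_l."""
        if self.lag_fun == CONSTANT:
            return 1
        return _BSPLINE_DEGREE + 1 + len(self.lag_knots)

    @property
    def n_columns(self) -> int:
        """Cross-basis dimension v_x * v_l (the block's df)."""
        return self.n_exposure_basis * self.n_lag_basis

    def with_reference(self, reference_temp: float) -> "CrossBasisSpec":
        return replace(self, reference_temp=float(reference_temp))


@dataclass(frozen=True)
class CrossBasisMatrix:
    """Realised cross-basis design columns for one exposure series.

    Rows before ``valid_from`` (the first ``lag_max`` days) have incomplete
    lag histories and are NaN; the fitting layer drops them.
    """

    values: np.ndarray
    valid_from: int
    spec: CrossBasisSpec

    @property
    def column_names(self) -> list[str]:
        vl = self.spec.n_lag_basis
        return [f"cb_x{j}_l{k}" for j in range(self.spec.n_exposure_basis) for k in range(vl)]


def bspline_basis(
    x: Sequence[float] | np.ndarray,
    degree: int,
    interior_knots: Sequence[float],
    boundary: tuple[float, float],
    intercept: bool,
) -> np.ndarray:
    """Evaluate a B-spline basis at ``x`` (Cox-de Boor, via scipy).

    The knot vector repeats each boundary knot ``degree + 1`` times.  With
    ``intercept`` the full basis is returned and rows sum to 1 inside the
    boundary (partition of unity); without it the first basis function is
    dropped, the usual convention when an intercept is held elsewhere in
    the model.

    Values of ``x`` outside the boundary are clipped to it; the cross-basis
    layer guarantees exposures stay inside the boundary (the data range).
    """
    lo, hi = float(boundary[0]), float(boundary[1])
    if not lo < hi:
        raise ValueError("boundary must satisfy low < high")
    interior = np.sort(np.asarray(interior_knots, dtype=float))
    if interior.size and (interior[0] <= lo or interior[-1] >= hi):
        raise ValueError(f"interior knots {interior.tolist()} not strictly inside ({lo}, {hi})")
    x = np.clip(np.asarray(x, dtype=float), lo, hi)
    knots = np.concatenate([np.full(degree + 1, lo), interior, np.full(degree + 1, hi)])
    basis = BSpline.design_matrix(x, knots, degree).toarray()
    if not intercept:
        basis = basis[:, 1:]
    return basis


@dataclass(frozen=True)
class NaturalSpline:
    """Natural cubic regression spline basis with ``df`` columns (no constant).

    As in R's ``splines::ns``: a cubic B-spline basis is constrained to zero
    second derivative at the boundary knots (so the function is linear beyond
    them) and the first constrained column is dropped, leaving ``df`` columns
    to be used alongside a separate model intercept.  The object is purely a
    function of its knots, so the identical basis can be evaluated on new
    data (e.g. a validation period, where it extends linearly).
    """

    boundary: tuple[float, float]
    interior_knots: tuple[float, ...]

    @classmethod
    def from_data(
        cls,
        x: Sequence[float] | np.ndarray,
        df: int,
        boundary: tuple[float, float] | None = None,
    ) -> "NaturalSpline":
        """Place ``df - 1`` interior knots at equally spaced quantiles of x."""
        x = np.asarray(x, dtype=float)
        if df < 1:
            raise ValueError("df must be >= 1")
        if boundary is None:
            boundary = (float(x.min()), float(x.max()))
        probs = np.arange(1, df) / df
        interior = np.quantile(x[(x >= boundary[0]) & (x <= boundary[1])], probs)
        return cls(boundary=tuple(boundary), interior_knots=tuple(float(k) for k in interior))

    @property
    def df(self) -> int:
        return len(self.interior_knots) + 1

    def _constrained(self):
        lo, hi = self.boundary
        degree = 3
        knots = np.concatenate(
            [np.full(degree + 1, lo), np.asarray(self.interior_knots), np.full(degree + 1, hi)]
        )
        n_basis = len(self.interior_knots) + degree + 1
        const = np.empty((2, n_basis))
        for j in range(n_basis):
            c = np.zeros(n_basis)
            c[j] = 1.0
            d2 = BSpline(knots, c, degree).derivative(2)
            const[0, j] = d2(lo)
            const[1, j] = d2(hi)
        q, _ = np.linalg.qr(const.T, mode="complete")
        return knots, degree, q[:, 2:]  # null space of the constraints

    def __call__(self, x: Sequence[float] | np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.boundary
        knots, degree, null_basis = self._constrained()
        b = BSpline.design_matrix(np.clip(x, lo, hi), knots, degree).toarray() @ null_basis
        # explicit linear extension beyond the boundary knots
        eps = 1e-6 * (hi - lo)
        for bound, sign, mask in ((lo, 1.0, x < lo), (hi, -1.0, x > hi)):
            if mask.any():
                b0 = BSpline.design_matrix(np.array([bound]), knots, degree).toarray() @ null_basis
                b1 = (
                    BSpline.design_matrix(np.array([bound + sign * eps]), knots, degree).toarray()
                    @ null_basis
                )
                slope = sign * (b1 - b0) / eps
                b[mask] = b0 + (x[mask, None] - bound) * slope
        return b[:, 1:]  # drop one column; span + intercept = full constrained space


def natural_spline_basis(
    x: Sequence[float] | np.ndarray,
    df: int,
    boundary: tuple[float, float] | None = None,
) -> np.ndarray:
    """Convenience wrapper: evaluate :class:`NaturalSpline` fitted on ``x``."""
    return NaturalSpline.from_data(x, df, boundary)(x)


def exposure_basis(spec: CrossBasisSpec, x: Sequence[float] | np.ndarray) -> np.ndarray:
    """Exposure-response basis R(x), centred so every column is 0 at the reference."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if spec.exposure_fun == LINEAR:
        return (x - spec.reference_temp)[:, None]
    raw = bspline_basis(x, _BSPLINE_DEGREE, spec.exposure_knots, spec.exposure_boundary, intercept=False)
    ref = bspline_basis(
        np.array([spec.reference_temp]),
        _BSPLINE_DEGREE,
        spec.exposure_knots,
        spec.exposure_boundary,
        intercept=False,
    )
    return raw - ref


def lag_basis(spec: CrossBasisSpec, lags: np.ndarray | None = None) -> np.ndarray:
    """Lag-response basis C(l) evaluated at integer lags 0..L by default."""
    if lags is None:
        lags = np.arange(spec.lag_max + 1, dtype=float)
    lags = np.atleast_1d(np.asarray(lags, dtype=float))
    if spec.lag_fun == CONSTANT:
        return np.ones((lags.size, 1))
    if spec.lag_max == 0:
        # degenerate window: single lag, intercept only
        return np.ones((lags.size, 1))
    return bspline_basis(lags, _BSPLINE_DEGREE, spec.lag_knots, (0.0, float(spec.lag_max)), intercept=True)


def build_crossbasis(exposure: Sequence[float] | np.ndarray, spec: CrossBasisSpec) -> CrossBasisMatrix:
    """Build the cross-basis matrix for a daily exposure series.

    Entry ``(t, j*v_l + k)`` equals ``sum_{l=0..L} R_j(x_{t-l}) C_k(l)`` with
    R the centred exposure basis and C the lag basis at integer lags.  The
    first L rows are NaN (incomplete lag history).
    """
    x = np.asarray(exposure, dtype=float)
    L = spec.lag_max
    if x.size <= L:
        raise ValueError(f"exposure series length {x.size} must exceed lag_max {L}")
    a = exposure_basis(spec, x)  # n x v_x
    c = lag_basis(spec)  # (L+1) x v_l
    n, vx = a.shape
    vl = c.shape[1]
    out = np.zeros((n - L, vx, vl))
    for l in range(L + 1):
        # rows t = L..n-1 take exposure row t - l
        out += a[L - l : n - l, :, None] * c[l, None, :]
    values = np.full((n, vx * vl), np.nan)
    values[L:] = out.reshape(n - L, vx * vl)
    return CrossBasisMatrix(values=values, valid_from=L, spec=spec)


def cumulative_contrast(spec: CrossBasisSpec, temp: float) -> np.ndarray:
    """Weight vector w with w'beta = overall cumulative log-RR at ``temp``.

    The overall cumulative association sums the lag-specific contributions
    over the whole window, so the lag basis enters through its column sums.
    """
    a = exposure_basis(spec, [temp])[0]
    csum = lag_basis(spec).sum(axis=0)
    return np.outer(a, csum).ravel()


def lag_contrast(spec: CrossBasisSpec, temp: float, lags: np.ndarray | None = None) -> np.ndarray:
    """Weight matrix W (one row per lag) with (W beta)_l = log-RR at ``temp``, lag l."""
    a = exposure_basis(spec, [temp])[0]
    c = lag_basis(spec, lags)
    return (a[None, :, None] * c[:, None, :]).reshape(c.shape[0], -1)
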