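"""Quasi-Poisson time-series regression with a cross-basis temperature term.

The mortality model is

    log E(Y_t) = a + d1*DOW_t + d2*HOY_t + d3*POP_t + ns(date_t) + cb(x_t..x_{t-30})

fitted by iteratively reweighted least squares under a Poisson quasi-
likelihood, with the coefficient covariance scaled by the Pearson
dispersion.  Candidate parameterisations of the cross-basis (exposure and
lag spline shapes) and of the seasonal trend (7-9 df/year) form a grid of
48 models compared by QAIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr as scipy_qr
from scipy.special import gammaln

from .crossbasis import (
    CONSTANT,
    LINEAR,
    QUAD_BSPLINE,
    CrossBasisSpec,
    NaturalSpline,
    build_crossbasis,
)
from .synthetic import MAX_LAG, SUMMER_MONTHS, WINTER_MONTHS

logger = logging.getLogger(__name__)

__all__ = [
    "BasisStructure",
    "ModelSpec",
    "Design",
    "FittedDLNM",
    "FitError",
    "RankDeficiencyError",
    "ConvergenceError",
    "resolve_crossbasis",
    "build_design",
    "design_matrix_for",
    "fit_quasipoisson",
    "fit_model",
    "qaic",
    "enumerate_candidates",
    "select_best",
]


class FitError(RuntimeError):
    """Base class for model-fitting failures."""


class RankDeficiencyError(FitError):
    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"design matrix is rank deficient; collinear columns: {columns}")


class ConvergenceError(FitError):
    def __init__(self, trace: list[float]):
        self.trace = trace
        super().__init__(f"IRLS did not converge in {len(trace)} iterations; deviance trace {trace[-3:]}")


@dataclass(frozen=True)
class BasisStructure:
    """Shape of a cross-basis before knots are placed on actual data.

    Knot values depend on the observed temperature range, so a candidate
    model is first described structurally (function families and knot
    counts) and resolved into a concrete :class:`CrossBasisSpec` when the
    design is built.
    """

    exposure_fun: str = QUAD_BSPLINE
    n_exposure_knots: int = 1
    lag_fun: str = QUAD_BSPLINE
    n_lag_knots: int = 1

    @property
    def n_columns(self) -> int:
        vx = 1 if self.exposure_fun == LINEAR else 2 + self.n_exposure_knots
        vl = 1 if self.lag_fun == CONSTANT else 3 + self.n_lag_knots
        return vx * vl

    def label(self) -> str:
        ex = "lin" if self.exposure_fun == LINEAR else f"qbs{self.n_exposure_knots}"
        lg = "const" if self.lag_fun == CONSTANT else f"qbs{self.n_lag_knots}"
        return f"{ex}x{lg}"


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: cross-basis shape + trend df + covariates."""

    basis: BasisStructure = field(default_factory=BasisStructure)
    date_df_per_year: int = 8
    covariates: tuple[str, ...] = ("dow", "holiday", "pop")
    season: str | None = None
    temperature_variable: str = "tmean"
    lag_max: int = MAX_LAG

    def __post_init__(self) -> None:
        if self.date_df_per_year not in (7, 8, 9):
            raise ValueError("date_df_per_year must be in {7, 8, 9}")
        if self.season not in (None, "winter", "summer"):
            raise ValueError("season must be None, 'winter' or 'summer'")


def resolve_crossbasis(
    structure: BasisStructure,
    temps: np.ndarray,
    lag_max: int = MAX_LAG,
    reference_temp: float | None = None,
) -> CrossBasisSpec:
    """Place knots on the data and fix the reference temperature.

    Exposure knots sit at equal distances over the observed range (one knot
    at mid-range, two at the thirds); lag knots at equal distances over the
    raw 0..L scale (15 for one knot, {10, 20} for two).  The reference
    defaults to the median temperature so the relative-risk scale is
    anchored at typical conditions.
    """
    temps = np.asarray(temps, dtype=float)
    lo, hi = float(np.min(temps)), float(np.max(temps))
    if reference_temp is None:
        reference_temp = float(np.median(temps))
    k = structure.n_exposure_knots
    exposure_knots = tuple(lo + (hi - lo) * i / (k + 1) for i in range(1, k + 1))
    kl = structure.n_lag_knots
    lag_knots = tuple(lag_max * i / (kl + 1) for i in range(1, kl + 1))
    return CrossBasisSpec(
        exposure_fun=structure.exposure_fun,
        exposure_knots=exposure_knots if structure.exposure_fun != LINEAR else (),
        exposure_boundary=(lo, hi),
        lag_fun=structure.lag_fun,
        lag_knots=lag_knots if structure.lag_fun != CONSTANT else (),
        lag_max=lag_max,
        reference_temp=reference_temp,
    )


@dataclass
class Design:
    """Realised design matrix plus everything needed to rebuild it on new data."""

    X: np.ndarray
    y: np.ndarray
    column_names: list[str]
    blocks: dict  # block name -> list of column indices
    rows_used: np.ndarray  # positional indices into the source frame
    crossbasis: CrossBasisSpec
    trend: NaturalSpline
    origin_date: pd.Timestamp
    spec: ModelSpec
    pop_scale: tuple[float, float] | None  # (mean, sd) if pop column present
    temp_percentiles: dict | None = None  # {1: ..., 50: ..., 99: ...} over rows used

    @property
    def n_used(self) -> int:
        return len(self.y)


_SEASON_MONTHS = {"winter": WINTER_MONTHS, "summer": SUMMER_MONTHS}


def _assemble(
    data: pd.DataFrame,
    spec: ModelSpec,
    cbspec: CrossBasisSpec,
    trend: NaturalSpline,
    origin_date: pd.Timestamp,
    pop_scale: tuple[float, float] | None,
) -> Design:
    dates = pd.to_datetime(data["date"])
    day_index = (dates - origin_date).dt.days.to_numpy(dtype=float)
    temps = data[spec.temperature_variable].to_numpy(dtype=float)
    cb = build_crossbasis(temps, cbspec)

    n = len(data)
    keep = np.arange(n) >= cbspec.lag_max
    if spec.season is not None:
        keep &= dates.dt.month.isin(_SEASON_MONTHS[spec.season]).to_numpy()
    if "deaths" in data.columns:
        keep &= ~pd.isna(data["deaths"]).to_numpy()
    rows = np.flatnonzero(keep)

    cols: list[np.ndarray] = [np.ones(len(rows))]
    names = ["intercept"]
    blocks: dict[str, list[int]] = {"intercept": [0]}

    def add_block(name: str, mat: np.ndarray, colnames: list[str]) -> None:
        start = len(names)
        for j in range(mat.shape[1]):
            cols.append(mat[:, j])
        names.extend(colnames)
        blocks[name] = list(range(start, start + mat.shape[1]))

    dow = data["dow"].to_numpy()[rows]
    if "dow" in spec.covariates:
        levels = np.unique(data["dow"].to_numpy())
        contrasts = np.column_stack([(dow == lev).astype(float) for lev in levels[1:]])
        if contrasts.shape[1]:
            add_block("dow", contrasts, [f"dow_{int(lev)}" for lev in levels[1:]])
    if "holiday" in spec.covariates:
        hol = data["holiday"].to_numpy(dtype=float)[rows]
        if np.ptp(hol) > 0:
            add_block("holiday", hol[:, None], ["holiday"])
        else:
            logger.warning("holiday covariate is constant over the fitting rows; dropped")
    if "pop" in spec.covariates and "pop" in data.columns:
        pop = data["pop"].to_numpy(dtype=float)[rows]
        if pop_scale is not None or np.ptp(pop) > 0:
            if pop_scale is None:
                pop_scale = (float(pop.mean()), float(pop.std()))
            add_block("pop", ((pop - pop_scale[0]) / pop_scale[1])[:, None], ["pop"])
        else:
            pop_scale = None
            logger.warning("population covariate is constant; dropped")

    # Days beyond the trend's fitted range are folded back by whole years:
    # the spline's natural (linear) extension tracks the seasonal slope at
    # the boundary, which explodes when extrapolated months ahead, so
    # out-of-period prediction reuses the last observed seasonal cycle.
    idx = day_index[rows].copy()
    lo, hi = trend.boundary
    over = idx > hi
    if over.any():
        idx[over] -= 365.25 * np.ceil((idx[over] - hi) / 365.25)
    under = idx < lo
    if under.any():
        idx[under] += 365.25 * np.ceil((lo - idx[under]) / 365.25)
    trend_mat = trend(idx)
    add_block("trend", trend_mat, [f"trend_{j}" for j in range(trend_mat.shape[1])])
    add_block("crossbasis", cb.values[rows], cb.column_names)

    y = data["deaths"].to_numpy(dtype=float)[rows] if "deaths" in data.columns else np.full(len(rows), np.nan)
    return Design(
        X=np.column_stack(cols),
        y=y,
        column_names=names,
        blocks=blocks,
        rows_used=rows,
        crossbasis=cbspec,
        trend=trend,
        origin_date=origin_date,
        spec=spec,
        pop_scale=pop_scale,
        temp_percentiles={
            p: float(np.percentile(temps[rows], p)) for p in (1, 50, 99)
        },
    )


def build_design(
    data: pd.DataFrame,
    spec: ModelSpec,
    reference_temp: float | None = None,
    crossbasis: CrossBasisSpec | None = None,
    trend_boundary: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> Design:
    """Build the regression design for one candidate model.

    Lagged exposures are computed from the full continuous daily series
    before any seasonal restriction, so January outcome rows draw lags from
    December.  The first ``lag_max`` rows (incomplete lag history) are
    dropped.  ``crossbasis`` and ``trend_boundary`` let a caller pin the
    bases to those of a training fit.
    """
    if len(data) < 366:
        raise ValueError("at least one year of daily data is required")
    dates = pd.to_datetime(data["date"])
    origin = dates.iloc[0] if trend_boundary is None else trend_boundary[0]
    temps = data[spec.temperature_variable].to_numpy(dtype=float)
    if crossbasis is None:
        crossbasis = resolve_crossbasis(spec.basis, temps, spec.lag_max, reference_temp)
    day_index = (dates - origin).dt.days.to_numpy(dtype=float)
    if trend_boundary is None:
        span_days = day_index[-1] - day_index[0] + 1
        df = max(2, round(spec.date_df_per_year * span_days / 365.25))
        trend = NaturalSpline.from_data(day_index, int(df))
    else:
        last = (trend_boundary[1] - origin).days
        span_days = last + 1
        df = max(2, round(spec.date_df_per_year * span_days / 365.25))
        grid = np.arange(0.0, last + 1.0)
        trend = NaturalSpline.from_data(grid, int(df))
    return _assemble(data, spec, crossbasis, trend, origin, None)


def design_matrix_for(design: Design, data: pd.DataFrame) -> Design:
    """Evaluate a fitted design's bases on new data (e.g. a validation period)."""
    return _assemble(
        data, design.spec, design.crossbasis, design.trend, design.origin_date, design.pop_scale
    )


@dataclass
class FittedDLNM:
    """A fitted quasi-Poisson DLNM: coefficients, scaled covariance, QAIC inputs."""

    coefficients: np.ndarray
    covariance: np.ndarray
    dispersion: float
    loglik: float  # Poisson log-likelihood at the quasi-likelihood estimate
    n_used: int
    n_params: int
    converged: bool
    n_iter: int
    design: Design
    qaic: float | None = None

    @property
    def coef_series(self) -> pd.Series:
        return pd.Series(self.coefficients, index=self.design.column_names)

    def block_coefficients(self, name: str) -> np.ndarray:
        return self.coefficients[self.design.blocks[name]]

    def block_covariance(self, name: str) -> np.ndarray:
        idx = np.asarray(self.design.blocks[name])
        return self.covariance[np.ix_(idx, idx)]


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    r = scipy_qr(X, mode="r", pivoting=True)
    diag = np.abs(np.diag(r[0]))
    piv = r[1]
    tol = diag[0] * max(X.shape) * np.finfo(float).eps
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad or X.shape[1] > len(diag):
        bad = bad or [names[i] for i in piv[len(diag) :]]
        raise RankDeficiencyError(bad)


def fit_quasipoisson(
    design: Design, tol: float = 1e-8, max_iter: int = 100
) -> FittedDLNM:
    """Fit by IRLS; covariance = dispersion * (X'WX)^-1.

    Convergence is declared on a relative deviance change below ``tol``
    (at most ``max_iter`` iterations); the Pearson dispersion is the
    chi-square statistic over the residual degrees of freedom.
    """
    X, y = design.X, design.y
    n, p = X.shape
    if n <= p:
        raise FitError(f"{n} rows for {p} parameters; model not estimable")
    _check_rank(X, design.column_names)
    mu = y + 0.5
    eta = np.log(mu)
    dev = np.inf
    trace: list[float] = []
    converged = False
    for it in range(1, max_iter + 1):
        w = mu
        z = eta + (y - mu) / mu
        xtw = X.T * w
        beta = np.linalg.solve(xtw @ X, xtw @ z)
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
        new_dev = 2.0 * dev_terms.sum()
        trace.append(new_dev)
        if np.isfinite(dev) and abs(new_dev - dev) < tol * (abs(new_dev) + 0.1):
            converged = True
            dev = new_dev
            break
        dev = new_dev
    if not converged:
        raise ConvergenceError(trace)
    pearson = ((y - mu) ** 2 / mu).sum()
    dispersion = pearson / (n - p)
    info = (X.T * mu) @ X
    cov = dispersion * np.linalg.inv(info)
    loglik = float((y * eta - mu - gammaln(y + 1)).sum())
    return FittedDLNM(
        coefficients=beta,
        covariance=cov,
        dispersion=float(dispersion),
        loglik=loglik,
        n_used=n,
        n_params=p,
        converged=True,
        n_iter=it,
        design=design,
    )


def fit_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    reference_temp: float | None = None,
    crossbasis: CrossBasisSpec | None = None,
    trend_boundary=None,
) -> FittedDLNM:
    """Convenience: build the design and fit in one step."""
    design = build_design(data, spec, reference_temp, crossbasis, trend_boundary)
    return fit_quasipoisson(design)


def qaic(fit: FittedDLNM, dispersion_ref: float) -> float:
    """Quasi-AIC: -2 * logLik / phi_ref + 2 * #parameters (lower is better)."""
    if dispersion_ref <= 0:
        raise ValueError("dispersion_ref must be positive")
    return -2.0 * fit.loglik / dispersion_ref + 2.0 * fit.n_params


_EXPOSURE_GRID = (
    (LINEAR, 0),
    (QUAD_BSPLINE, 0),
    (QUAD_BSPLINE, 1),
    (QUAD_BSPLINE, 2),
)
_LAG_GRID = (
    (CONSTANT, 0),
    (QUAD_BSPLINE, 0),
    (QUAD_BSPLINE, 1),
    (QUAD_BSPLINE, 2),
)


def enumerate_candidates(
    season: str | None = None, temperature_variable: str = "tmean"
) -> list[ModelSpec]:
    """The 48-model grid: 4 exposure shapes x 4 lag shapes x 3 trend dfs.

    Cross-basis df spans 1 (linear x constant) to 20 (2-knot quadratic
    B-splines in both dimensions, 4 x 5).
    """
    out = []
    for (lag_fun, nlk), (exp_fun, nek), df in product(_LAG_GRID, _EXPOSURE_GRID, (7, 8, 9)):
        out.append(
            ModelSpec(
                basis=BasisStructure(
                    exposure_fun=exp_fun,
                    n_exposure_knots=nek,
                    lag_fun=lag_fun,
                    n_lag_knots=nlk,
                ),
                date_df_per_year=df,
                season=season,
                temperature_variable=temperature_variable,
            )
        )
    return out


def select_best(
    data: pd.DataFrame,
    candidates: Sequence[ModelSpec],
    reference_temp: float | None = None,
) -> tuple[ModelSpec, FittedDLNM, pd.DataFrame]:
    """Fit every candidate and rank by QAIC.

    All candidates share a common dispersion reference, taken from the most
    complex candidate (largest cross-basis, then largest trend df), so the
    penalised quasi-likelihoods are on one scale.  Failed fits are recorded
    in the table and excluded from the ranking.
    """
    if not candidates:
        raise ValueError("no candidates supplied")
    most_complex = max(candidates, key=lambda s: (s.basis.n_columns, s.date_df_per_year))
    fits: dict[int, FittedDLNM] = {}
    errors: dict[int, str] = {}
    for i, spec in enumerate(candidates):
        try:
            fits[i] = fit_model(data, spec, reference_temp)
        except FitError as exc:  # logged, excluded from ranking
            errors[i] = str(exc)
            logger.warning("candidate %d (%s) failed: %s", i + 1, spec.basis.label(), exc)
    if not fits:
        raise FitError("all candidate fits failed")
    ref_idx = candidates.index(most_complex)
    phi_ref = fits[ref_idx].dispersion if ref_idx in fits else max(f.dispersion for f in fits.values())
    rows = []
    for i, spec in enumerate(candidates):
        row = {
            "model_id": i + 1,
            "exposure_fun": spec.basis.exposure_fun,
            "exposure_knots": spec.basis.n_exposure_knots if spec.basis.exposure_fun != LINEAR else 0,
            "lag_fun": spec.basis.lag_fun,
            "lag_knots": spec.basis.n_lag_knots if spec.basis.lag_fun != CONSTANT else 0,
            "date_df": spec.date_df_per_year,
            "cb_df": spec.basis.n_columns,
        }
        if i in fits:
            f = fits[i]
            f.qaic = qaic(f, phi_ref)
            row.update(qaic=f.qaic, dispersion=f.dispersion, converged=True)
        else:
            row.update(qaic=np.nan, dispersion=np.nan, converged=False)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("qaic", na_position="last").reset_index(drop=True)
    best_id = int(table.iloc[0]["model_id"]) - 1
    return candidates[best_id], fits[best_id], table
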