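"""Predicted relative-risk summaries from a fitted DLNM.

Three views of the fitted exposure-lag-response association:

* the overall cumulative exposure-response curve (log-RR of a sustained
  exposure, summing lag contributions over the whole 0-30 window);
* the lag-response curve at a fixed exposure intensity;
* the full exposure x lag RR surface.

All are linear contrasts w'beta of the cross-basis coefficient block, with
delta-method (Wald) 95% intervals exp(w'beta +/- 1.96 sqrt(w'Vw)) on the
log scale.  RR = 1 exactly at the reference temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossbasis import CrossBasisSpec, cumulative_contrast, lag_contrast
from .fit import Design, FittedDLNM, design_matrix_for

__all__ = [
    "CumulativeCurve",
    "LagCurve",
    "RRSurface",
    "predict_cumulative",
    "predict_lag",
    "predict_surface",
    "expected_deaths",
]

_Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class CumulativeCurve:
    """Overall cumulative exposure-response association over a temperature grid."""

    temps: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    @property
    def rr_low(self) -> np.ndarray:
        return np.exp(self.log_rr - _Z95 * self.se)

    @property
    def rr_high(self) -> np.ndarray:
        return np.exp(self.log_rr + _Z95 * self.se)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temp": self.temps,
                "log_rr": self.log_rr,
                "se": self.se,
                "rr": self.rr,
                "rr_low": self.rr_low,
                "rr_high": self.rr_high,
            }
        )

    def at(self, temp: float) -> pd.Series:
        """Row of the curve nearest to ``temp``."""
        i = int(np.argmin(np.abs(self.temps - temp)))
        return self.to_frame().iloc[i]


@dataclass
class LagCurve:
    """Lag-response association at one fixed exposure intensity."""

    lags: np.ndarray
    temp: float
    log_rr: np.ndarray
    se: np.ndarray

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    @property
    def rr_low(self) -> np.ndarray:
        return np.exp(self.log_rr - _Z95 * self.se)

    @property
    def rr_high(self) -> np.ndarray:
        return np.exp(self.log_rr + _Z95 * self.se)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lags,
                "temp": self.temp,
                "log_rr": self.log_rr,
                "se": self.se,
                "rr": self.rr,
                "rr_low": self.rr_low,
                "rr_high": self.rr_high,
            }
        )


@dataclass
class RRSurface:
    """RR over a temperature x lag grid (rows = temperatures)."""

    temps: np.ndarray
    lags: np.ndarray
    rr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        t, l = np.meshgrid(self.temps, self.lags, indexing="ij")
        return pd.DataFrame({"temp": t.ravel(), "lag": l.ravel(), "rr": self.rr.ravel()})


def _cb_block(fit: FittedDLNM, spec: CrossBasisSpec):
    beta = fit.block_coefficients("crossbasis")
    if beta.size != spec.n_columns:
        raise ValueError(
            f"cross-basis block has {beta.size} coefficients but spec implies {spec.n_columns}"
        )
    return beta, fit.block_covariance("crossbasis")


def predict_cumulative(
    fit: FittedDLNM,
    spec: CrossBasisSpec | None = None,
    temp_grid: np.ndarray | None = None,
) -> CumulativeCurve:
    """Overall cumulative log-RR with Wald intervals over a temperature grid.

    The default grid runs in 1 degC steps over the exposure boundary (the
    observed range of the training data).
    """
    spec = spec or fit.design.crossbasis
    if temp_grid is None:
        lo, hi = spec.exposure_boundary
        temp_grid = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    temp_grid = np.atleast_1d(np.asarray(temp_grid, dtype=float))
    beta, cov = _cb_block(fit, spec)
    w = np.stack([cumulative_contrast(spec, t) for t in temp_grid])
    log_rr = w @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", w, cov, w), 0.0))
    return CumulativeCurve(temps=temp_grid, log_rr=log_rr, se=se)


def predict_lag(
    fit: FittedDLNM,
    temp: float,
    spec: CrossBasisSpec | None = None,
    lags: np.ndarray | None = None,
) -> LagCurve:
    """Lag-response log-RR at a fixed exposure, with Wald intervals."""
    spec = spec or fit.design.crossbasis
    if lags is None:
        lags = np.arange(spec.lag_max + 1)
    beta, cov = _cb_block(fit, spec)
    w = lag_contrast(spec, temp, np.asarray(lags, dtype=float))
    log_rr = w @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", w, cov, w), 0.0))
    return LagCurve(lags=np.asarray(lags), temp=float(temp), log_rr=log_rr, se=se)


def predict_surface(
    fit: FittedDLNM,
    spec: CrossBasisSpec | None = None,
    temp_grid: np.ndarray | None = None,
    lag_grid: np.ndarray | None = None,
) -> RRSurface:
    """Exposure-lag-response RR surface; its row at the reference is all ones."""
    spec = spec or fit.design.crossbasis
    if temp_grid is None:
        lo, hi = spec.exposure_boundary
        temp_grid = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    if lag_grid is None:
        lag_grid = np.arange(spec.lag_max + 1)
    temp_grid = np.atleast_1d(np.asarray(temp_grid, dtype=float))
    rr = np.empty((temp_grid.size, np.atleast_1d(lag_grid).size))
    for i, t in enumerate(temp_grid):
        rr[i] = predict_lag(fit, t, spec, lag_grid).rr
    return RRSurface(temps=temp_grid, lags=np.atleast_1d(np.asarray(lag_grid)), rr=rr)


def expected_deaths(fit: FittedDLNM, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, Design]:
    """Predicted daily death counts for new data under a fitted model.

    Returns (observed, predicted, design) over the rows of ``data`` with a
    complete lag history, evaluating the training fit's bases (cross-basis,
    trend spline continued in calendar time).
    """
    design = design_matrix_for(fit.design, data)
    mu = np.exp(np.clip(design.X @ fit.coefficients, -30, 30))
    return design.y, mu, design
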