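"""Synthetic daily temperature-mortality series with a known truth.

Real mortality series of this kind (daily circulatory-disease deaths for a
metropolitan area, paired with station temperature) are rarely deposited, so
this module generates series with the statistical structure the analysis
assumes:

* daily mean temperature = annual sinusoid + stationary AR(1) noise, with
  min/max derived through a diurnal half-range;
* a "climate-model" twin of the temperature series with systematic location,
  scale and upper-tail bias (the input the quantile-mapping correction
  expects);
* overdispersed daily death counts whose log-mean combines a baseline rate,
  weekday and holiday offsets, a smooth seasonal trend and a *known*
  non-linear delayed temperature effect over lags 0-30.

The true exposure-lag-response surface is separable: an exposure-response
function (quadratic rise towards cold below the reference temperature,
optional rise towards heat above it) times an exponentially decaying lag
weight normalised to sum to one over the lag window.  Because the weights
sum to one, the overall cumulative log-RR curve equals the exposure function
itself, which makes recovery tests exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurfaceParams",
    "TruthScenario",
    "generate_temperature",
    "distort_temperature",
    "generate_mortality",
    "true_exposure_response",
    "true_lag_weights",
    "true_surface",
    "true_cumulative_curve",
    "generate_region",
    "add_calendar_columns",
    "season_of_month",
    "WINTER_MONTHS",
    "SUMMER_MONTHS",
]

WINTER_MONTHS = frozenset({12, 1, 2, 3})
SUMMER_MONTHS = frozenset({6, 7, 8, 9})

# fixed-date public holidays (month, day); deterministic across years
_HOLIDAYS = ((1, 1), (4, 25), (5, 1), (6, 10), (8, 15), (10, 5), (11, 1), (12, 1), (12, 8), (12, 25))

MAX_LAG = 30


@dataclass(frozen=True)
class SurfaceParams:
    """Parameters of the true exposure-lag-response log-RR surface.

    ``cold_log_rr`` is the overall cumulative log-RR reached at the cold
    anchor temperature (roughly the 1st percentile of generated tmean) and
    ``heat_log_rr`` the analogue at the hot anchor (99th percentile);
    ``lag_decay`` is the e-folding time (days) of the lag weights.
    """

    cold_log_rr: float = 0.5
    heat_log_rr: float = 0.0
    lag_decay: float = 4.0

    def __post_init__(self) -> None:
        if self.lag_decay <= 0:
            raise ValueError("lag_decay must be positive")


@dataclass(frozen=True)
class TruthScenario:
    """Complete description of a synthetic region's data-generating process.

    Defaults emulate a southern-European metropolitan area: mean deaths
    around 20/day with mild overdispersion, annual temperature cycle of
    amplitude 6 degC around 16 degC, and day-to-day AR(1) weather noise.
    """

    n_days: int = 5478  # 15 years
    temp_mean_annual: float = 16.0
    temp_amplitude: float = 6.0
    ar_coefficient: float = 0.7
    noise_sd: float = 3.0  # marginal (stationary) SD of the AR(1) component
    diurnal_half_range: float = 4.0
    surface_params: SurfaceParams = field(default_factory=SurfaceParams)
    baseline_log_rate: float = float(np.log(20.0))
    dow_effects: tuple[float, ...] = (0.0, -0.01, -0.02, -0.01, 0.0, 0.02, 0.03)
    holiday_effect: float = 0.05
    seasonal_log_amplitude: float = 0.08  # smooth winter-peaking trend term
    overdispersion: float = 1.3
    pop: float = 2_000_000.0
    start_date: str = "1986-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days <= MAX_LAG + 1:
            raise ValueError(f"n_days must exceed {MAX_LAG + 1} (the lag window)")
        if self.overdispersion < 1:
            raise ValueError("overdispersion must be >= 1")
        if abs(self.ar_coefficient) >= 1:
            raise ValueError(
                f"ar_coefficient {self.ar_coefficient} is non-stationary; require |rho| < 1"
            )
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Mon..Sun)")

    # ---- anchors of the true surface, derived analytically from the
    # temperature model so the truth never depends on a realised sample ----
    @property
    def reference_temp(self) -> float:
        """Temperature at which the true log-RR is zero (the annual mean)."""
        return self.temp_mean_annual

    @property
    def cold_anchor(self) -> float:
        """Approximate 1st percentile of tmean under the sinusoid+AR model."""
        return self.temp_mean_annual - self.temp_amplitude - 2.0 * self.noise_sd

    @property
    def heat_anchor(self) -> float:
        """Approximate 99th percentile of tmean."""
        return self.temp_mean_annual + self.temp_amplitude + 2.0 * self.noise_sd


def season_of_month(month: int | np.ndarray) -> np.ndarray:
    """Map month number(s) to season labels winter/summer/other."""
    month = np.atleast_1d(np.asarray(month))
    out = np.where(
        np.isin(month, list(WINTER_MONTHS)),
        "winter",
        np.where(np.isin(month, list(SUMMER_MONTHS)), "summer", "other"),
    )
    return out


def add_calendar_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Fill dow, holiday, and season columns from the date column."""
    frame = frame.copy()
    dates = pd.to_datetime(frame["date"])
    frame["dow"] = dates.dt.dayofweek.to_numpy()
    md = list(zip(dates.dt.month, dates.dt.day))
    frame["holiday"] = np.array([1 if t in _HOLIDAYS else 0 for t in md], dtype=int)
    frame["season"] = season_of_month(dates.dt.month.to_numpy())
    return frame


def generate_temperature(scenario: TruthScenario) -> pd.DataFrame:
    """Generate a daily temperature series (tmean/tmin/tmax) with calendar columns.

    tmean follows an annual cosine peaking in mid-July plus a stationary
    AR(1) process whose *marginal* standard deviation is ``noise_sd``;
    tmin/tmax are tmean -/+ the diurnal half-range.  Deterministic under a
    fixed scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_days
    dates = pd.date_range(scenario.start_date, periods=n, freq="D")
    doy = dates.dayofyear.to_numpy()
    seasonal = scenario.temp_mean_annual + scenario.temp_amplitude * np.cos(
        2 * np.pi * (doy - 196) / 365.25
    )
    rho = scenario.ar_coefficient
    innov_sd = scenario.noise_sd * np.sqrt(1 - rho**2)
    eps = rng.normal(0.0, 1.0, n)
    noise = np.empty(n)
    noise[0] = eps[0] * scenario.noise_sd
    for t in range(1, n):
        noise[t] = rho * noise[t - 1] + innov_sd * eps[t]
    tmean = seasonal + noise
    frame = pd.DataFrame(
        {
            "date": dates,
            "deaths": np.nan,
            "tmean": tmean,
            "tmin": tmean - scenario.diurnal_half_range,
            "tmax": tmean + scenario.diurnal_half_range,
            "pop": scenario.pop,
        }
    )
    return add_calendar_columns(frame)


def distort_temperature(
    series: pd.DataFrame,
    shift: float = 1.0,
    scale: float = 1.1,
    tail_skew: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Create a systematically biased "climate model" twin of a series.

    Each temperature column becomes ``scale * x + shift`` plus a shared
    daily adjustment: an upper-tail distortion
    ``tail_skew * max(0, tmean - q90)**2 / (q99 - q90)`` (warm extremes
    drift further than the bulk, a common climate-model artefact) plus
    optional noise.  The adjustment is computed from ``tmean`` and applied
    identically to ``tmin``/``tmax`` so the within-day ordering
    ``tmin <= tmean <= tmax`` is always preserved; with zero noise the
    day-to-day rank order is preserved too.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    out = series.copy()
    tmean = out["tmean"].to_numpy(dtype=float)
    adjust = np.zeros(len(out))
    if tail_skew != 0.0:
        q90, q99 = np.quantile(tmean, [0.90, 0.99])
        width = max(q99 - q90, 1e-9)
        adjust = adjust + tail_skew * np.maximum(0.0, tmean - q90) ** 2 / width
    if noise_sd > 0.0:
        adjust = adjust + rng.normal(0.0, noise_sd, len(out))
    for col in ("tmean", "tmin", "tmax"):
        if col in out.columns:
            out[col] = scale * out[col].to_numpy(dtype=float) + shift + adjust
    return out


# ---------------------------------------------------------------------------
# the known truth surface
# ---------------------------------------------------------------------------


def true_exposure_response(scenario: TruthScenario, temp: np.ndarray | float) -> np.ndarray:
    """Overall cumulative log-RR at ``temp`` relative to the reference.

    Quadratic rise towards cold below the reference (reaching
    ``cold_log_rr`` at the cold anchor) and towards heat above it; zero and
    flat at the reference, so the curve is C1-smooth.
    """
    t = np.atleast_1d(np.asarray(temp, dtype=float))
    ref = scenario.reference_temp
    p = scenario.surface_params
    cold_span = max(ref - scenario.cold_anchor, 1e-9)
    heat_span = max(scenario.heat_anchor - ref, 1e-9)
    out = np.where(
        t < ref,
        p.cold_log_rr * ((ref - t) / cold_span) ** 2,
        p.heat_log_rr * ((t - ref) / heat_span) ** 2,
    )
    return out


def true_lag_weights(scenario: TruthScenario) -> np.ndarray:
    """Exponentially decaying lag weights over lags 0..30, summing to 1."""
    lags = np.arange(MAX_LAG + 1, dtype=float)
    w = np.exp(-lags / scenario.surface_params.lag_decay)
    return w / w.sum()


def true_surface(scenario: TruthScenario, temp: np.ndarray | float, lag: int | np.ndarray) -> np.ndarray:
    """True lag-specific log-RR contribution surface(temp, lag)."""
    w = true_lag_weights(scenario)
    lag = np.atleast_1d(np.asarray(lag, dtype=int))
    return np.squeeze(np.outer(true_exposure_response(scenario, temp), w[lag]))


def true_cumulative_curve(scenario: TruthScenario, temp_grid: np.ndarray) -> pd.DataFrame:
    """Analytic overall cumulative log-RR over a temperature grid.

    Because the lag weights sum to one, the cumulative curve equals the
    exposure-response function pointwise.
    """
    grid = np.atleast_1d(np.asarray(temp_grid, dtype=float))
    log_rr = true_exposure_response(scenario, grid)
    return pd.DataFrame({"temp": grid, "log_rr": log_rr, "rr": np.exp(log_rr)})


def _negative_binomial(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Poisson-gamma mixture with mean mu and variance phi * mu (NB1)."""
    if phi == 1.0:
        return rng.poisson(mu)
    shape = mu / (phi - 1.0)
    lam = rng.gamma(shape, phi - 1.0)
    return rng.poisson(lam)


def generate_mortality(temps: pd.DataFrame, scenario: TruthScenario) -> pd.DataFrame:
    """Draw daily death counts for a temperature series under the scenario truth.

    log E(Y_t) = baseline + dow + holiday + seasonal trend
                 + sum_l surface(x_{t-l}, l), lags 0..30.

    Counts are Poisson-gamma (negative binomial) with variance/mean ratio
    equal to ``scenario.overdispersion``.  The first 30 rows keep NaN deaths:
    their lagged exposures are unavailable, so they serve only as history.
    """
    if len(temps) <= MAX_LAG + 1:
        raise ValueError(f"temperature series must exceed {MAX_LAG + 1} days")
    rng = np.random.default_rng(scenario.seed + 1_000_003)
    out = temps.copy()
    x = out["tmean"].to_numpy(dtype=float)
    n = len(x)
    w = true_lag_weights(scenario)
    f = true_exposure_response(scenario, x)
    # cumulative lagged contribution sum_l f(x_{t-l}) w_l for t >= 30
    contrib = np.zeros(n - MAX_LAG)
    for l in range(MAX_LAG + 1):
        contrib += w[l] * f[MAX_LAG - l : n - l]
    dates = pd.to_datetime(out["date"])
    doy = dates.dt.dayofyear.to_numpy()
    seasonal = scenario.seasonal_log_amplitude * np.cos(2 * np.pi * (doy - 15) / 365.25)
    log_mu = (
        scenario.baseline_log_rate
        + np.asarray(scenario.dow_effects)[out["dow"].to_numpy()]
        + scenario.holiday_effect * out["holiday"].to_numpy()
        + seasonal
    )
    log_mu = log_mu.astype(float)
    log_mu[MAX_LAG:] += contrib
    mu = np.exp(log_mu)
    deaths = np.full(n, np.nan)
    deaths[MAX_LAG:] = _negative_binomial(rng, mu[MAX_LAG:], scenario.overdispersion)
    out["deaths"] = deaths
    return out


def generate_region(scenario: TruthScenario) -> pd.DataFrame:
    """Convenience: temperature + mortality in one call."""
    return generate_mortality(generate_temperature(scenario), scenario)
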