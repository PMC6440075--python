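"""Empirical quantile-quantile bias correction of modelled temperature.

Climate-model temperature series carry systematic distributional errors
relative to station observations.  Quantile mapping corrects the *whole*
distribution, tails included: the empirical quantiles of the simulated
series are matched to those of the observed series, and corrected values
are obtained by monotone interpolation between the matched quantiles.
Beyond the outermost fitted quantiles the correction is, by default, the
constant offset at the nearest fitted quantile (avoiding wild linear
extrapolation of extremes); linear extrapolation of the end slopes is
available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import season_of_month

__all__ = ["QuantileMap", "fit_quantile_map", "apply_quantile_map", "SeasonalQuantileMap"]

CONSTANT_OFFSET = "constant-offset"
LINEAR_EXTRAPOLATION = "linear-extrapolation"


@dataclass(frozen=True)
class QuantileMap:
    """Matched empirical quantiles of an observed and a simulated series."""

    probs: np.ndarray
    obs_quantiles: np.ndarray
    sim_quantiles: np.ndarray
    tail_rule: str = CONSTANT_OFFSET

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        obs = np.asarray(self.obs_quantiles, dtype=float)
        sim = np.asarray(self.sim_quantiles, dtype=float)
        if not (len(probs) == len(obs) == len(sim)):
            raise ValueError("probs, obs_quantiles and sim_quantiles must have equal length")
        if np.any(np.diff(probs) <= 0):
            raise ValueError("probs must be strictly increasing")
        if np.any(np.diff(obs) < 0) or np.any(np.diff(sim) < 0):
            raise ValueError("quantile arrays must be non-decreasing")
        if self.tail_rule not in (CONSTANT_OFFSET, LINEAR_EXTRAPOLATION):
            raise ValueError(f"unknown tail_rule {self.tail_rule!r}")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "obs_quantiles", obs)
        object.__setattr__(self, "sim_quantiles", sim)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"prob": self.probs, "obs_q": self.obs_quantiles, "sim_q": self.sim_quantiles}
        )


def fit_quantile_map(
    observed: np.ndarray,
    simulated: np.ndarray,
    n_quantiles: int = 99,
    tail_rule: str = CONSTANT_OFFSET,
) -> QuantileMap:
    """Fit the transfer function projecting the observed distribution onto the simulated one.

    Quantiles are matched at probabilities ``(1..n)/(n+1)`` (percentiles for
    the default ``n_quantiles = 99``); the resulting map is monotone by
    construction.
    """
    observed = np.asarray(observed, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if observed.size == 0 or simulated.size == 0:
        raise ValueError("observed and simulated series must be non-empty")
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    if np.ptp(simulated) == 0:
        raise ValueError("simulated series is constant; quantile map is not invertible")
    probs = np.arange(1, n_quantiles + 1) / (n_quantiles + 1)
    return QuantileMap(
        probs=probs,
        obs_quantiles=np.quantile(observed, probs),
        sim_quantiles=np.quantile(simulated, probs),
        tail_rule=tail_rule,
    )


def apply_quantile_map(qmap: QuantileMap, values: np.ndarray) -> np.ndarray:
    """Correct simulated values through the fitted quantile map.

    Inside the fitted range the correction interpolates linearly between
    matched quantiles; outside it follows the map's tail rule.  Output order
    matches input order.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    sim, obs = qmap.sim_quantiles, qmap.obs_quantiles
    # collapse ties in the simulated quantiles (flat spells) to their mean target
    uniq, inverse = np.unique(sim, return_inverse=True)
    if uniq.size < sim.size:
        obs_u = np.array([obs[inverse == i].mean() for i in range(uniq.size)])
        sim, obs = uniq, obs_u
    out = np.interp(values, sim, obs)
    below = values < sim[0]
    above = values > sim[-1]
    if qmap.tail_rule == CONSTANT_OFFSET:
        out[below] = values[below] + (obs[0] - sim[0])
        out[above] = values[above] + (obs[-1] - sim[-1])
    else:  # linear-extrapolation of the end slopes
        lo_slope = (obs[1] - obs[0]) / (sim[1] - sim[0])
        hi_slope = (obs[-1] - obs[-2]) / (sim[-1] - sim[-2])
        out[below] = obs[0] + lo_slope * (values[below] - sim[0])
        out[above] = obs[-1] + hi_slope * (values[above] - sim[-1])
    return out


@dataclass(frozen=True)
class SeasonalQuantileMap:
    """Per-season quantile maps (winter / summer / other month groups).

    The mortality analysis is run by season, so the calibration is fitted
    seasonally by default; an all-year map is a single-entry special case.
    """

    maps: dict

    @classmethod
    def fit(
        cls,
        observed: pd.DataFrame,
        simulated: pd.DataFrame,
        column: str = "tmean",
        n_quantiles: int = 99,
        tail_rule: str = CONSTANT_OFFSET,
        seasonal: bool = True,
    ) -> "SeasonalQuantileMap":
        obs_season = season_of_month(pd.to_datetime(observed["date"]).dt.month.to_numpy())
        sim_season = season_of_month(pd.to_datetime(simulated["date"]).dt.month.to_numpy())
        if not seasonal:
            qm = fit_quantile_map(
                observed[column].to_numpy(), simulated[column].to_numpy(), n_quantiles, tail_rule
            )
            return cls(maps={"all": qm})
        maps = {}
        for season in ("winter", "summer", "other"):
            o = observed[column].to_numpy()[obs_season == season]
            s = simulated[column].to_numpy()[sim_season == season]
            if o.size and s.size:
                maps[season] = fit_quantile_map(o, s, n_quantiles, tail_rule)
        return cls(maps=maps)

    def apply(self, simulated: pd.DataFrame, column: str = "tmean") -> pd.DataFrame:
        """Correct ``column``; companion temperature columns receive the same
        per-day delta so the ``tmin <= tmean <= tmax`` ordering survives."""
        out = simulated.copy()
        values = out[column].to_numpy(dtype=float)
        if "all" in self.maps:
            corrected = apply_quantile_map(self.maps["all"], values)
        else:
            season = season_of_month(pd.to_datetime(out["date"]).dt.month.to_numpy())
            corrected = values.copy()
            for name, qmap in self.maps.items():
                mask = season == name
                corrected[mask] = apply_quantile_map(qmap, values[mask])
        delta = corrected - values
        out[column] = corrected
        for other in ("tmean", "tmin", "tmax"):
            if other != column and other in out.columns:
                out[other] = out[other].to_numpy(dtype=float) + delta
        return out
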