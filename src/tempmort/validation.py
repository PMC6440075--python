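"""Out-of-sample validation of effect estimates and death predictions.

Two complementary checks of a trained model against an independent test
period:

* *effect validation*: compare the exposure-lag-response log-RR vectors
  estimated on the training and test periods over a fixed grid, through a
  relative RMSE and a relative mean absolute deviation (both scaled by the
  mean test-period effect);
* *bootstrap prediction validation*: resample test-period days with
  replacement, predict expected deaths from the training fit, and summarise
  the prediction RMSE and the relative bias of the mean predicted count
  across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit import FittedDLNM
from .predict import expected_deaths, predict_lag

__all__ = [
    "EffectValidation",
    "BootstrapValidation",
    "effect_validation",
    "bootstrap_validation",
    "bias_histogram",
    "prediction_rmse",
]


@dataclass
class EffectValidation:
    """Relative RMSE / MAD between training and test effect vectors."""

    rmse_rel: float
    mad_rel: float
    defined: bool  # False when the mean test effect is ~0 (metrics undefined)
    grid: pd.DataFrame


def _effect_metrics(beta_hat: np.ndarray, beta: np.ndarray) -> tuple[float, float, bool]:
    denom = beta.mean()
    if abs(denom) < 1e-12:
        return np.nan, np.nan, False
    diff = beta_hat - beta
    rmse = np.sqrt(np.mean(diff**2)) / denom
    mad = abs(diff.mean()) / denom
    return float(rmse), float(mad), True


def effect_validation(
    fit_train: FittedDLNM,
    fit_test: FittedDLNM,
    temps: np.ndarray | None = None,
) -> EffectValidation:
    """Compare lag-specific effects of two fits sharing one cross-basis spec.

    The effect vector stacks the lag-response log-RR at lags 0..L for each
    evaluation temperature (default: the 1st, 50th and 99th percentiles of
    the training-period exposure).  The metrics are flagged undefined
    rather than infinite when the mean test-period effect is zero.
    """
    spec = fit_train.design.crossbasis
    if spec != fit_test.design.crossbasis:
        raise ValueError("training and test fits must share the same cross-basis spec")
    if temps is None:
        pct = fit_train.design.temp_percentiles or {}
        temps = np.array([pct.get(1), pct.get(50), pct.get(99)], dtype=float)
    rows = []
    bh, b = [], []
    for t in np.atleast_1d(temps):
        c_train = predict_lag(fit_train, float(t))
        c_test = predict_lag(fit_test, float(t))
        bh.append(c_train.log_rr)
        b.append(c_test.log_rr)
        rows.append(
            pd.DataFrame(
                {
                    "temp": float(t),
                    "lag": c_train.lags,
                    "log_rr_train": c_train.log_rr,
                    "log_rr_test": c_test.log_rr,
                }
            )
        )
    rmse, mad, defined = _effect_metrics(np.concatenate(bh), np.concatenate(b))
    return EffectValidation(rmse_rel=rmse, mad_rel=mad, defined=defined, grid=pd.concat(rows, ignore_index=True))


def prediction_rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean squared error between observed and predicted daily deaths."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


@dataclass
class BootstrapValidation:
    """Prediction-error summaries from day-resampling of the validation period."""

    n_boot: int
    rmse_per_replicate: np.ndarray
    rmse_original: float
    biases: np.ndarray  # mean predicted - mean observed, deaths/day, per replicate
    relative_biases: np.ndarray  # biases / mean observed per replicate
    seed: int

    @property
    def average_error(self) -> float:
        """Mean replicate RMSE minus the RMSE on the unresampled data."""
        return float(self.rmse_per_replicate.mean() - self.rmse_original)

    def to_dict(self) -> dict:
        return {
            "n_boot": self.n_boot,
            "seed": self.seed,
            "rmse_original": self.rmse_original,
            "rmse_per_replicate": self.rmse_per_replicate.tolist(),
            "average_error": self.average_error,
            "biases": self.biases.tolist(),
            "relative_biases": self.relative_biases.tolist(),
        }


def bootstrap_validation(
    fit_train: FittedDLNM,
    validation_data: pd.DataFrame,
    n_boot: int = 50,
    seed: int = 0,
) -> BootstrapValidation:
    """Day-level bootstrap of the validation period's prediction error.

    The training coefficients are reused on every resample (no refitting):
    the resample changes which observed days the fixed predictions are
    scored against.  Days are drawn i.i.d. with replacement, same size as
    the validation sample.
    """
    y, mu, _ = expected_deaths(fit_train, validation_data)
    n = len(y)
    rng = np.random.default_rng(seed)
    rmse = np.empty(n_boot)
    bias = np.empty(n_boot)
    rel_bias = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        rmse[b] = prediction_rmse(y[idx], mu[idx])
        bias[b] = mu[idx].mean() - y[idx].mean()
        rel_bias[b] = bias[b] / y[idx].mean()
    return BootstrapValidation(
        n_boot=n_boot,
        rmse_per_replicate=rmse,
        rmse_original=prediction_rmse(y, mu),
        biases=bias,
        relative_biases=rel_bias,
        seed=seed,
    )


def bias_histogram(boot: BootstrapValidation, bins: int = 10) -> dict:
    """Binned summary of the per-replicate relative biases, with mean and sd."""
    counts, edges = np.histogram(boot.relative_biases, bins=bins)
    return {
        "bin_edges": edges,
        "counts": counts,
        "mean": float(boot.relative_biases.mean()),
        "sd": float(boot.relative_biases.std(ddof=1)) if boot.n_boot > 1 else 0.0,
    }
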