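"""Inverse prediction of MLSS from channel intensities, and error metrics.

Calibration lines are fitted with intensity as the response, so predicting
biomass from a new intensity is inverse regression:

    linear:       MLSS = (V - intercept) / M
    exponential:  MLSS = ln(V0 / V) / kappa

Predictions falling below zero or outside the calibrated MLSS span are
flagged, never silently clipped — an operator should see when the camera is
reporting something the calibration cannot support.  Model selection across
channels uses the standard deviation statistics (RMSE, MAE, MAPE, R^2) of
in-sample inverse predictions; MAPE skips actual-zero points (division by
zero) and reports how many were skipped so the rule is visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import (
    CalibrationModel,
    CalibrationSample,
    Channel,
    ChannelFit,
    ExponentialFit,
    channel_value,
)
from .exceptions import DegenerateDataError, InputDataError

__all__ = [
    "Prediction",
    "MetricsReport",
    "predict_linear",
    "predict_exponential",
    "metrics",
    "select_best_channel",
    "CHANNEL_PRIORITY",
]

#: Fixed tie-break order for channel selection (best-documented channel first).
CHANNEL_PRIORITY: tuple[Channel, ...] = ("B", "GRAY", "G", "R")

FLAG_BELOW_ZERO = "below-zero"
FLAG_ABOVE_RANGE = "above-calibration-range"


@dataclass(frozen=True)
class Prediction:
    """One MLSS estimate (g/L) with provenance and QC flags."""

    mlss_hat: float
    channel: Channel
    model_kind: str  # "linear" | "exponential"
    flags: tuple[str, ...] = ()

    def clipped(self) -> float:
        """Operational convenience: max(0, mlss_hat)."""
        return max(0.0, self.mlss_hat)


@dataclass(frozen=True)
class MetricsReport:
    """Standard deviation statistics of predicted vs actual MLSS."""

    rmse: float  # g/L
    mae: float  # g/L
    mape: float  # percent, over actual > 0 points only
    r_squared: float
    n_used: int
    n_excluded_mape: int = 0

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mae": self.mae,
            "mape": self.mape,
            "r_squared": self.r_squared,
            "n_used": self.n_used,
            "n_excluded_mape": self.n_excluded_mape,
        }


def predict_linear(value: float, fit: ChannelFit) -> Prediction:
    """Invert the calibration line: MLSS = (value - intercept) / slope."""
    if fit.slope == 0:
        raise DegenerateDataError(
            f"channel {fit.channel}: zero slope, calibration line cannot be inverted"
        )
    mlss_hat = (value - fit.intercept) / fit.slope
    flags = []
    if mlss_hat < 0:
        flags.append(FLAG_BELOW_ZERO)
    if fit.mlss_range is not None and mlss_hat > fit.mlss_range[1]:
        flags.append(FLAG_ABOVE_RANGE)
    return Prediction(float(mlss_hat), fit.channel, "linear", tuple(flags))


def predict_exponential(value: float, fit: ExponentialFit) -> Prediction:
    """Invert the Beer-Lambert model: MLSS = ln(v0 / value) / kappa."""
    if value <= 0:
        raise InputDataError(
            f"intensity must be > 0 for exponential inversion, got {value}"
        )
    if fit.kappa == 0:
        raise DegenerateDataError("zero attenuation coefficient: cannot invert")
    mlss_hat = float(np.log(fit.v0 / value) / fit.kappa)
    flags = []
    if mlss_hat < 0:
        flags.append(FLAG_BELOW_ZERO)
    if mlss_hat > fit.mlss_max:
        flags.append(FLAG_ABOVE_RANGE)
    return Prediction(mlss_hat, fit.channel, "exponential", tuple(flags))


def metrics(actual: Sequence[float], predicted: Sequence[float]) -> MetricsReport:
    """RMSE, MAE, MAPE (%) and R^2 of predictions against known MLSS.

    MAPE averages |error|/actual over strictly positive actuals only; points
    at actual zero are counted in ``n_excluded_mape``.  R^2 is
    1 - SS_res/SS_tot about the mean of the actuals and is undefined (error)
    when all actuals coincide.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise InputDataError(
            f"actual and predicted must be equal-length 1-D, got {a.shape} vs {p.shape}"
        )
    if a.size == 0:
        raise InputDataError("empty input to metrics")
    err = a - p
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    pos = a > 0
    n_excl = int((~pos).sum())
    mape = float(100.0 * np.mean(np.abs(err[pos] / a[pos]))) if pos.any() else 0.0
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateDataError("all actual values identical: R^2 undefined")
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return MetricsReport(
        rmse=rmse, mae=mae, mape=mape, r_squared=r2, n_used=int(a.size),
        n_excluded_mape=n_excl,
    )


def channel_metrics(
    model: CalibrationModel, samples: Sequence[CalibrationSample]
) -> dict[Channel, MetricsReport]:
    """In-sample inverse-prediction metrics for every fitted channel."""
    if not samples:
        raise InputDataError("no samples to evaluate")
    actual = [s.mlss for s in samples]
    out: dict[Channel, MetricsReport] = {}
    for chan, fit in model.fits.items():
        values = [channel_value(s.rgb, chan, model.gray) for s in samples]
        preds = [predict_linear(v, fit).mlss_hat for v in values]
        out[chan] = metrics(actual, preds)
    return out


def select_best_channel(
    model: CalibrationModel,
    samples: Sequence[CalibrationSample],
    channels: Sequence[Channel] | None = None,
) -> tuple[Channel, dict[Channel, MetricsReport]]:
    """Pick the channel whose inverse predictions track MLSS best.

    Highest R^2 wins; ties fall back to lowest RMSE, then to the fixed order
    B, GRAY, G, R.  ``channels`` restricts the comparison set (e.g. to the
    color channels only); by default every fitted channel competes.
    """
    reports = channel_metrics(model, samples)
    if channels is not None:
        unknown = [c for c in channels if c not in reports]
        if unknown:
            raise InputDataError(f"channels {unknown} not fitted in this model")
        reports = {c: reports[c] for c in channels}
    ordered = [c for c in CHANNEL_PRIORITY if c in reports]
    ordered += [c for c in reports if c not in CHANNEL_PRIORITY]
    best = min(
        ordered,
        key=lambda c: (-reports[c].r_squared, reports[c].rmse, ordered.index(c)),
    )
    return best, reports
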