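"""Channel-vs-MLSS calibration: linear fits, gray coefficients, Beer-Lambert.

The method calibrates each color channel's mean intensity V against biomass
concentration (MLSS, g/L) by ordinary least squares,

    V_c = intercept_c + M_c * MLSS,       c in {R, G, B},

with intensity as the response, so the slopes M_c carry units of intensity
per g/L.  A single composite "gray" index is then defined by normalizing the
slopes,

    K_c = M_c / (M_R + M_G + M_B),    Gray = K_R*R + K_G*G + K_B*B,

which weights each channel by its sensitivity to MLSS; the weights sum to 1,
so a spectrally flat pixel keeps its value.  In the low-turbidity regime
transmitted light decays exponentially with absorber concentration
(Beer-Lambert), motivating the alternative model

    V = V0 * exp(-kappa * MLSS),   MLSS <= mlss_max (default 8 g/L),

fitted as a straight line on log-intensity (deterministic, no starting
values).  Because the literature does not fix on which scale exponential fit
quality is quoted, both the log-scale R^2 and the R^2 of back-transformed
predictions on the intensity scale are reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, InputDataError
from .imaging import EXTRACTION_COLUMNS, RGBMean

__all__ = [
    "Channel",
    "COLOR_CHANNELS",
    "CalibrationSample",
    "ChannelFit",
    "GrayCoefficients",
    "ExponentialFit",
    "CalibrationModel",
    "channel_value",
    "fit_channel",
    "gray_coefficients",
    "to_grayscale",
    "fit_exponential",
    "build_model",
    "read_calibration_csv",
    "DEFAULT_MLSS_MAX",
]

Channel = str  # one of "R", "G", "B", "GRAY"
COLOR_CHANNELS: tuple[Channel, ...] = ("R", "G", "B")
ALL_CHANNELS: tuple[Channel, ...] = ("R", "G", "B", "GRAY")

#: Upper MLSS bound (g/L) of the low-turbidity exponential regime.
DEFAULT_MLSS_MAX = 8.0


@dataclass(frozen=True)
class CalibrationSample:
    """One calibration point: known MLSS plus the measured channel means."""

    sample_id: str
    mlss: float
    rgb: RGBMean
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.mlss < 0:
            raise InputDataError(f"MLSS must be >= 0, got {self.mlss}")
        if self.n_replicates < 1:
            raise InputDataError("n_replicates must be >= 1")


@dataclass(frozen=True)
class GrayCoefficients:
    """Slope-normalized channel weights; always sum to 1."""

    k_r: float
    k_g: float
    k_b: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.k_r, self.k_g, self.k_b)


@dataclass(frozen=True)
class ChannelFit:
    """OLS line of one channel (or the gray composite) against MLSS."""

    channel: Channel
    slope: float  # intensity units per g/L (M_R / M_G / M_B for colors)
    intercept: float  # intensity at MLSS 0
    r_squared: float
    n: int
    mlss_range: tuple[float, float] | None = None  # fitted MLSS span, g/L

    def predict_value(self, mlss: float) -> float:
        """Forward model: expected intensity at a given MLSS."""
        return self.intercept + self.slope * mlss


@dataclass(frozen=True)
class ExponentialFit:
    """Beer-Lambert parameters V = v0 * exp(-kappa * MLSS) for one channel.

    ``kappa`` (per g/L) is positive for cultures that darken with biomass.
    ``r_squared_log`` scores the straight-line fit on log-intensity;
    ``r_squared_linear`` scores back-transformed predictions on the
    intensity scale.
    """

    channel: Channel
    v0: float
    kappa: float
    r_squared_log: float
    r_squared_linear: float
    mlss_max: float
    n: int

    def predict_value(self, mlss: float) -> float:
        return self.v0 * np.exp(-self.kappa * mlss)


def channel_value(rgb: RGBMean, channel: Channel, k: GrayCoefficients | None = None) -> float:
    """Scalar intensity of one channel, computing the gray composite on demand."""
    if channel == "R":
        return rgb.r
    if channel == "G":
        return rgb.g
    if channel == "B":
        return rgb.b
    if channel == "GRAY":
        if k is None:
            raise InputDataError("gray coefficients required for channel GRAY")
        return to_grayscale(rgb, k)
    raise InputDataError(f"unknown channel {channel!r}")


def _check_design(mlss: np.ndarray, n_min: int = 3) -> None:
    if len(mlss) < n_min:
        raise InputDataError(
            f"insufficient samples: need >= {n_min}, got {len(mlss)}"
        )
    if np.unique(mlss).size < 2:
        raise DegenerateDataError("all MLSS values identical: slope is undefined")


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R^2 = 1 - SS_res/SS_tot of y on x."""
    res = stats.linregress(x, y)
    pred = res.intercept + res.slope * x
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(res.slope), float(res.intercept), r2


def fit_channel(
    samples: Sequence[CalibrationSample],
    channel: Channel,
    k: GrayCoefficients | None = None,
) -> ChannelFit:
    """OLS of channel intensity (response) on MLSS (predictor).

    Intensity is deliberately the response — the calibration slopes are
    sensitivities in intensity units per g/L; MLSS prediction is done later
    by inverting the fitted line, never by re-regressing MLSS on intensity.
    """
    mlss = np.array([s.mlss for s in samples], dtype=float)
    _check_design(mlss)
    y = np.array([channel_value(s.rgb, channel, k) for s in samples], dtype=float)
    slope, intercept, r2 = _ols(mlss, y)
    return ChannelFit(
        channel=channel,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n=len(samples),
        mlss_range=(float(mlss.min()), float(mlss.max())),
    )


def gray_coefficients(m_r: float, m_g: float, m_b: float) -> GrayCoefficients:
    """Normalize the three calibration slopes into gray weights.

    K_c = M_c / (M_R + M_G + M_B).  Requires all slopes nonzero and of the
    same sign (co-directional fading); mixed signs would put weights outside
    (0, 1) and make the composite meaningless, so that fails loudly.
    """
    slopes = (m_r, m_g, m_b)
    if any(m == 0 for m in slopes):
        raise DegenerateDataError("zero channel slope: gray weights undefined")
    signs = {np.sign(m) for m in slopes}
    if len(signs) > 1:
        raise DegenerateDataError(
            f"channel slopes {slopes} have mixed signs; gray weights require "
            "all channels to fade in the same direction"
        )
    total = m_r + m_g + m_b
    return GrayCoefficients(m_r / total, m_g / total, m_b / total)


def to_grayscale(rgb: RGBMean, k: GrayCoefficients) -> float:
    """Weighted composite K_R*R + K_G*G + K_B*B on the 0-255 scale."""
    return k.k_r * rgb.r + k.k_g * rgb.g + k.k_b * rgb.b


def fit_exponential(
    samples: Sequence[CalibrationSample],
    channel: Channel,
    mlss_max: float = DEFAULT_MLSS_MAX,
    k: GrayCoefficients | None = None,
) -> ExponentialFit:
    """Beer-Lambert fit on the MLSS <= mlss_max subset via log-linear OLS.

    v0 = exp(intercept), kappa = -slope of ln(V) on MLSS.  Any non-positive
    intensity in the subset is a domain error, not a point to drop.
    """
    subset = [s for s in samples if s.mlss <= mlss_max]
    mlss = np.array([s.mlss for s in subset], dtype=float)
    _check_design(mlss)
    v = np.array([channel_value(s.rgb, channel, k) for s in subset], dtype=float)
    if np.any(v <= 0):
        raise InputDataError(
            f"channel {channel}: non-positive intensity in the exponential "
            "subset; log transform undefined"
        )
    slope, intercept, r2_log = _ols(mlss, np.log(v))
    pred = np.exp(intercept + slope * mlss)
    ss_res = float(np.sum((v - pred) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2_lin = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ExponentialFit(
        channel=channel,
        v0=float(np.exp(intercept)),
        kappa=float(-slope),
        r_squared_log=r2_log,
        r_squared_linear=r2_lin,
        mlss_max=float(mlss_max),
        n=len(subset),
    )


@dataclass
class CalibrationModel:
    """Complete calibration: per-channel lines, gray weights, exponentials.

    The GRAY fit is always computed from gray values produced by the stored
    coefficients, never fitted independently of them.
    """

    fits: dict[Channel, ChannelFit]
    gray: GrayCoefficients
    exponential: dict[Channel, ExponentialFit] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "channels": {
                c: {
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "r_squared": f.r_squared,
                    "n": f.n,
                    "mlss_range": list(f.mlss_range) if f.mlss_range else None,
                }
                for c, f in self.fits.items()
            },
            "gray": {"k_r": self.gray.k_r, "k_g": self.gray.k_g, "k_b": self.gray.k_b},
            "exponential": {
                c: {
                    "v0": e.v0,
                    "kappa": e.kappa,
                    "r_squared_log": e.r_squared_log,
                    "r_squared_linear": e.r_squared_linear,
                    "mlss_max": e.mlss_max,
                    "n": e.n,
                }
                for c, e in self.exponential.items()
            },
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        fits = {
            c: ChannelFit(
                channel=c,
                slope=v["slope"],
                intercept=v["intercept"],
                r_squared=v["r_squared"],
                n=v["n"],
                mlss_range=tuple(v["mlss_range"]) if v.get("mlss_range") else None,
            )
            for c, v in d["channels"].items()
        }
        gray = GrayCoefficients(**d["gray"])
        expo = {
            c: ExponentialFit(channel=c, **v) for c, v in d.get("exponential", {}).items()
        }
        return cls(fits=fits, gray=gray, exponential=expo, metadata=d.get("metadata", {}))

    def to_json(self, path: str | Path) -> None:
        # json round-trips doubles bit-stably (repr-based float encoding)
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        try:
            return cls.from_dict(json.loads(Path(path).read_text()))
        except (OSError, json.JSONDecodeError, KeyError, TypeError) as exc:
            raise InputDataError(f"cannot read model {path}: {exc}") from exc


def build_model(
    samples: Sequence[CalibrationSample],
    mlss_max: float = DEFAULT_MLSS_MAX,
    fit_exponentials: bool = True,
    metadata: dict | None = None,
) -> CalibrationModel:
    """Fit R, G, B lines, derive gray weights, fit GRAY, then exponentials.

    Exponential fits are per color channel plus GRAY and are skipped (not
    failed) for a channel whose low-MLSS subset is unusable, since the linear
    calibration remains valid regardless.
    """
    fits = {c: fit_channel(samples, c) for c in COLOR_CHANNELS}
    k = gray_coefficients(fits["R"].slope, fits["G"].slope, fits["B"].slope)
    fits["GRAY"] = fit_channel(samples, "GRAY", k=k)
    expo: dict[Channel, ExponentialFit] = {}
    if fit_exponentials:
        for c in ALL_CHANNELS:
            try:
                expo[c] = fit_exponential(samples, c, mlss_max=mlss_max, k=k)
            except (InputDataError, DegenerateDataError):
                continue
    return CalibrationModel(fits=fits, gray=k, exponential=expo, metadata=metadata or {})


def read_calibration_csv(path: str | Path) -> list[CalibrationSample]:
    """Read a calibration table in the extraction-CSV schema.

    Requires the ``mlss_g_per_L`` column to be filled; rows without a known
    MLSS cannot calibrate anything.
    """
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputDataError(f"cannot read calibration table {path}: {exc}") from exc
    missing = [c for c in EXTRACTION_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise InputDataError(
            f"calibration table {path} lacks required columns {missing}"
        )
    samples = []
    for _, row in df.iterrows():
        if pd.isna(row["mlss_g_per_L"]):
            raise InputDataError(
                f"row {row['sample_id']!r} in {path} has no MLSS value"
            )
        samples.append(
            CalibrationSample(
                sample_id=str(row["sample_id"]),
                mlss=float(row["mlss_g_per_L"]),
                rgb=RGBMean(
                    float(row["r_mean"]),
                    float(row["g_mean"]),
                    float(row["b_mean"]),
                    n_pixels=int(row["n_pixels"]) if "n_pixels" in df.columns and not pd.isna(row.get("n_pixels")) else 1,
                ),
                n_replicates=int(row["n_replicates"]) if "n_replicates" in df.columns and not pd.isna(row.get("n_replicates")) else 1,
            )
        )
    return samples
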