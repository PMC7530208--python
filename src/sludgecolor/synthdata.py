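"""Synthetic dish images with Beer-Lambert optics, plus the reference table.

The generator produces petri-dish photographs with exactly the optical
structure the calibration method assumes: the dish interior at biomass
concentration ``m`` has per-channel intensity

    V_c(m) = base_c * exp(-kappa_c * m),

with the blue attenuation coefficient largest by default — blue sits
nearest the UV end of the spectrum, so a turbid bacterial culture absorbs
it most strongly and it darkens fastest.  Additive Gaussian sensor noise is
applied before 8-bit quantization, and clipping at 0/255 models sensor
saturation.  Because ground-truth MLSS and attenuation are known, the full
pipeline (render -> extract -> calibrate -> predict) can be validated
end-to-end without any laboratory data.

The module also ships the bundled reference calibration table: 23 printed
(MLSS, R, G, B) rows spanning 0-14.901 g/L from an activated-sludge imaging
study, each row the average of three replicate photographs.  The published
calibration coefficients derive from a 21-row subset of that table — the
rows at MLSS 12.98 and 13.52 g/L are not part of the published fit (the
study reports 21 samples while its table prints 23 rows; excluding exactly
those two rows reproduces every published slope to five significant
figures).  ``reference_dataset`` returns all 23 rows;
``reference_calibration_subset`` returns the 21-row calibration series.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .calibration import CalibrationSample
from .exceptions import InputDataError
from .imaging import DEFAULT_SHRINK, CircularROI, RGBMean, average_replicates, mean_rgb

__all__ = [
    "SceneConfig",
    "SyntheticSeries",
    "attenuate",
    "render_dish_image",
    "generate_series",
    "reference_dataset",
    "reference_calibration_subset",
    "REFERENCE_EXCLUDED_MLSS",
]


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, optics, and noise of the synthetic dish scene.

    Defaults emulate the reference system: base_color is the per-channel
    fitted intensity at MLSS 0 and attenuation the per-channel Beer-Lambert
    coefficient (per g/L) fitted on its low-MLSS subset, so synthetic series
    reproduce the reference optics ordering kappa_B > kappa_G > kappa_R.
    noise_sd is the per-channel Gaussian sd in intensity units (DN).
    """

    image_size: tuple[int, int] = (400, 400)  # (width, height) px
    dish_center: tuple[float, float] = (200.0, 200.0)  # (cx, cy) px
    dish_radius: float = 150.0
    rim_width: float = 8.0
    rim_color: tuple[float, float, float] = (255.0, 255.0, 255.0)
    background_color: tuple[float, float, float] = (40.0, 40.0, 40.0)
    base_color: tuple[float, float, float] = (230.0, 232.0, 241.0)
    attenuation: tuple[float, float, float] = (0.017, 0.037, 0.090)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.image_size
        cx, cy = self.dish_center
        r = self.dish_radius
        if not (cx - r >= 0 and cy - r >= 0 and cx + r <= w - 1 and cy + r <= h - 1):
            raise InputDataError(
                f"dish (center {self.dish_center}, radius {r}) does not fit "
                f"inside a {w}x{h} image"
            )
        if any(not 0 < c <= 255 for c in self.base_color):
            raise InputDataError(f"base_color {self.base_color} outside (0, 255]")
        if any(k < 0 for k in self.attenuation):
            raise InputDataError("attenuation coefficients must be >= 0")
        if self.noise_sd < 0:
            raise InputDataError("noise_sd must be >= 0")
        if not 0 < self.rim_width < self.dish_radius:
            raise InputDataError("rim_width must lie in (0, dish_radius)")

    @property
    def roi(self) -> CircularROI:
        return CircularROI(self.dish_center[0], self.dish_center[1], self.dish_radius)

    def interior_color(self, mlss: float) -> tuple[float, float, float]:
        """Noise-free interior intensity at the given MLSS (un-quantized)."""
        return tuple(
            attenuate(b, k, mlss) for b, k in zip(self.base_color, self.attenuation)
        )


@dataclass
class SyntheticSeries:
    """Generated calibration samples together with the ground truth used."""

    samples: list[CalibrationSample]
    truth: SceneConfig


def attenuate(base: float, kappa: float, mlss: float) -> float:
    """Beer-Lambert transmitted intensity: base * exp(-kappa * mlss)."""
    if base < 0 or kappa < 0 or mlss < 0:
        raise InputDataError("attenuate requires non-negative arguments")
    return float(base * np.exp(-kappa * mlss))


def _image_rng(config: SceneConfig, sample_index: int, replicate_index: int) -> np.random.Generator:
    # one root seed; per-image streams keyed by (sample, replicate) so any
    # single image can be regenerated in isolation
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=config.seed, spawn_key=(sample_index, replicate_index)
        )
    )


def render_dish_image(
    config: SceneConfig,
    mlss: float,
    sample_index: int = 0,
    replicate_index: int = 0,
) -> np.ndarray:
    """Rasterize one dish photograph at the given MLSS.

    Background fill, bright rim annulus, interior at the attenuated color,
    plus Gaussian noise from the stream keyed by (seed, sample, replicate);
    the float image is then rounded and clamped to [0, 255] uint8.  The same
    (config, mlss, indices) always yields a byte-identical image.
    """
    w, h = config.image_size
    cx, cy = config.dish_center
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    outer = d2 < config.dish_radius**2
    interior = d2 < (config.dish_radius - config.rim_width) ** 2

    img = np.empty((h, w, 3), dtype=float)
    img[:] = config.background_color
    img[outer] = config.rim_color
    img[interior] = config.interior_color(mlss)

    if config.noise_sd > 0:
        rng = _image_rng(config, sample_index, replicate_index)
        img += rng.normal(0.0, config.noise_sd, size=img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_series(
    config: SceneConfig,
    mlss_values: Sequence[float],
    replicates: int = 3,
    outdir: str | Path | None = None,
    rasterize: bool = False,
    shrink: float = DEFAULT_SHRINK,
) -> SyntheticSeries:
    """Produce calibration samples for each MLSS, averaged over replicates.

    By default an analytic shortcut emits replicate channel means directly —
    the attenuated interior color plus a Gaussian perturbation of sd
    noise_sd/sqrt(n_interior_pixels), the sampling error of a mean over the
    interior — without rasterizing.  With ``rasterize=True`` (implied by
    ``outdir``) full images are rendered, optionally written as PNGs named
    ``sample{ID}_rep{K}.png``, and reduced through the real extraction path
    (``mean_rgb`` on the known dish ROI).
    """
    if replicates < 1:
        raise InputDataError("replicates must be >= 1")
    rasterize = rasterize or outdir is not None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

    # analytic n_pixels: centers strictly inside the shrunken interior circle
    inner_r = (config.dish_radius - config.rim_width) * shrink
    n_interior = _count_interior_pixels(config, inner_r)
    if n_interior < 1:
        raise InputDataError("shrunken interior contains no pixels")

    samples: list[CalibrationSample] = []
    for i, mlss in enumerate(mlss_values):
        reps: list[RGBMean] = []
        for j in range(replicates):
            if rasterize:
                img = render_dish_image(config, mlss, sample_index=i, replicate_index=j)
                if outdir is not None:
                    import imageio.v3 as iio

                    iio.imwrite(outdir / f"sample{i}_rep{j}.png", img)
                # shrink applied to the interior edge, not the rim circle,
                # so rim pixels can never leak into the mean
                roi = CircularROI(*config.dish_center, config.dish_radius - config.rim_width)
                reps.append(mean_rgb(img, roi, shrink=shrink))
            else:
                rng = _image_rng(config, i, j)
                true = np.array(config.interior_color(mlss))
                noisy = true + rng.normal(0.0, config.noise_sd / np.sqrt(n_interior), size=3)
                noisy = np.clip(noisy, 0.0, 255.0)
                reps.append(RGBMean(*map(float, noisy), n_pixels=n_interior))
        samples.append(
            CalibrationSample(
                sample_id=f"sample{i}",
                mlss=float(mlss),
                rgb=average_replicates(reps),
                n_replicates=replicates,
            )
        )
    series = SyntheticSeries(samples=samples, truth=config)
    if outdir is not None:
        _write_manifest(series, outdir / "manifest.csv")
    return series


def _count_interior_pixels(config: SceneConfig, radius: float) -> int:
    w, h = config.image_size
    cx, cy = config.dish_center
    yy, xx = np.mgrid[0:h, 0:w]
    return int(((xx - cx) ** 2 + (yy - cy) ** 2 < radius**2).sum())


def _write_manifest(series: SyntheticSeries, path: Path) -> None:
    """Extraction-CSV schema plus a true_mlss column."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sample_id", "mlss_g_per_L", "r_mean", "g_mean", "b_mean",
             "n_pixels", "n_replicates", "true_mlss"]
        )
        for s in series.samples:
            writer.writerow(
                [s.sample_id, repr(s.mlss), repr(s.rgb.r), repr(s.rgb.g),
                 repr(s.rgb.b), s.rgb.n_pixels, s.n_replicates, repr(s.mlss)]
            )


# --- bundled reference calibration table ---------------------------------

# 23 printed rows: MLSS (g/L), mean R, G, B over three replicate photographs.
_REFERENCE_ROWS: tuple[tuple[float, float, float, float], ...] = (
    (0.0, 232.08, 232.09, 233.6),
    (0.263, 229.51, 229.35, 229.71),
    (0.34, 225.81, 225.51, 225.66),
    (0.527, 225.85, 224.62, 223.85),
    (0.644, 225.58, 224.5, 223.7),
    (0.772, 225.4, 224.41, 223.49),
    (0.966, 225.03, 224.11, 223.001),
    (1.053, 224.97, 223.36, 221.49),
    (1.931, 224.46, 222.18, 216.78),
    (2.318, 224.26, 220.21, 210.13),
    (2.897, 221.07, 212.37, 193.21),
    (5.795, 212.44, 190.33, 138.33),
    (6.623, 211.21, 188.84, 138.42),
    (6.439, 207.118, 184.67, 136.23),
    (6.954, 200.72, 176.9, 122.58),
    (7.243, 200.35, 174.85, 123.05),
    (7.726, 197.4, 170.91, 118.35),
    (8.585, 190.2, 157.97, 102.74),
    (11.59, 174.36, 130.76, 66.12),
    (12.33, 174.56, 131.07, 67.7),
    (12.98, 165.33, 121.65, 53.14),
    (13.52, 142.19, 101.2, 34.193),
    (14.901, 128.15, 81.26, 26.2),
)

#: MLSS values of the two printed rows outside the published 21-sample fit.
REFERENCE_EXCLUDED_MLSS: tuple[float, float] = (12.98, 13.52)


def reference_dataset() -> list[CalibrationSample]:
    """All 23 printed rows of the bundled reference table."""
    return [
        CalibrationSample(
            sample_id=f"ref{i:02d}",
            mlss=m,
            rgb=RGBMean(r, g, b, n_pixels=1),
            n_replicates=3,
        )
        for i, (m, r, g, b) in enumerate(_REFERENCE_ROWS)
    ]


def reference_calibration_subset() -> list[CalibrationSample]:
    """The 21-row series the published calibration coefficients derive from.

    Excludes the printed rows at MLSS 12.98 and 13.52 g/L; fitting this
    subset reproduces the published channel slopes, gray coefficients and
    R^2 values at their printed precision.
    """
    return [s for s in reference_dataset() if s.mlss not in REFERENCE_EXCLUDED_MLSS]
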