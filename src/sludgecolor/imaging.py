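"""Image loading, dish localization, and reduction to mean RGB intensities.

A sample photograph of a circular culture dish is reduced to a single
(R, G, B) triple: the arithmetic mean of each 8-bit channel over the pixels
inside a (shrunken) circular region of interest.  Replicate photographs of
the same sample are averaged per channel.  All downstream calibration and
prediction operates on these means.

Images are handled as ``numpy`` arrays of shape (height, width, 3) with
dtype ``uint8`` — the "image grid" throughout this package.  Means are
computed on the stored sRGB-encoded values directly, without gamma
linearization, because the calibration is defined on stored 8-bit values.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InputDataError

__all__ = [
    "CircularROI",
    "RGBMean",
    "load_image",
    "detect_dish_roi",
    "mean_rgb",
    "average_replicates",
    "saturation_fraction",
    "write_extraction_csv",
    "DEFAULT_SHRINK",
    "DEFAULT_SATURATION_THRESHOLD",
]

#: Default ROI radius shrink factor: excludes the dish rim and meniscus
#: highlights while retaining most of the interior area.
DEFAULT_SHRINK = 0.8

#: Fraction of saturated in-ROI pixels above which callers should warn that
#: the exposure is too bright for reliable channel means.
DEFAULT_SATURATION_THRESHOLD = 0.01


@dataclass(frozen=True)
class CircularROI:
    """Circular region of interest in pixel coordinates.

    The origin is the top-left pixel center; ``cx`` grows rightward (columns)
    and ``cy`` downward (rows).  A pixel belongs to the ROI iff its center
    satisfies (x-cx)^2 + (y-cy)^2 < radius^2 (strict — no partial weighting).
    """

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise InputDataError(f"ROI radius must be > 0, got {self.radius}")

    def shrunk(self, shrink: float) -> "CircularROI":
        if not 0 < shrink <= 1:
            raise InputDataError(f"shrink must lie in (0, 1], got {shrink}")
        return CircularROI(self.cx, self.cy, self.radius * shrink)

    def inside(self, height: int, width: int) -> bool:
        """True when the circle lies fully inside the image bounds."""
        return (
            self.cx - self.radius >= -0.5
            and self.cy - self.radius >= -0.5
            and self.cx + self.radius <= width - 0.5
            and self.cy + self.radius <= height - 0.5
        )


@dataclass(frozen=True)
class RGBMean:
    """Mean channel intensities of one image region, on the 0-255 scale."""

    r: float
    g: float
    b: float
    n_pixels: int = 1

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise InputDataError(f"channel {name}={v} outside [0, 255]")
        if self.n_pixels < 1:
            raise InputDataError(f"n_pixels must be >= 1, got {self.n_pixels}")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b], dtype=float)


def load_image(path: str | Path) -> np.ndarray:
    """Decode an 8-bit PNG/TIFF/JPEG into an (H, W, 3) uint8 array.

    Grayscale images are promoted to three equal channels; alpha channels are
    dropped.  Bit depths other than 8 per channel raise instead of silently
    rescaling, because the calibration is defined on the 0-255 scale.
    """
    import imageio.v3 as iio

    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise InputDataError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise InputDataError(
            f"unsupported bit depth in {path}: dtype {arr.dtype}, expected 8-bit"
        )
    if arr.ndim == 2:  # grayscale -> replicate
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 2:  # gray + alpha
        arr = np.stack([arr[:, :, 0]] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:  # RGBA -> drop alpha
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] == 3:
        arr = arr.copy()
    else:
        raise InputDataError(f"unsupported image shape {arr.shape} in {path}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise InputDataError(f"empty image {path}")
    return arr


def _roi_mask(shape: tuple[int, ...], roi: CircularROI) -> np.ndarray:
    h, w = shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - roi.cx) ** 2 + (yy - roi.cy) ** 2 < roi.radius**2


def detect_dish_roi(image: np.ndarray) -> CircularROI:
    """Locate the circular dish via a Hough transform on edge pixels.

    Expects a single bright-rimmed dish on a darker or uniform background.
    Deterministic for a fixed image.  Among circles whose (normalized) Hough
    accumulator exceeds 0.4, the largest radius wins, ties broken by
    accumulator strength.  An explicit ROI always takes precedence in the
    CLI; this is a convenience for unattended batch extraction.
    """
    from skimage.feature import canny
    from skimage.transform import hough_circle, hough_circle_peaks

    h, w = image.shape[:2]
    gray = image.astype(float).mean(axis=2) / 255.0
    edges = canny(gray, sigma=2.0)
    if not edges.any():
        raise InputDataError(
            "no circle found (no edges); supply an explicit ROI (--roi cx,cy,r)"
        )
    r_min = max(5, min(h, w) // 8)
    r_max = min(h, w) // 2 + 1
    radii = np.arange(r_min, r_max, 1)
    accum = hough_circle(edges, radii)
    accums, cxs, cys, rads = hough_circle_peaks(
        accum, radii, total_num_peaks=10, normalize=True
    )
    good = accums >= 0.4
    if not good.any():
        raise InputDataError(
            "no circle found; supply an explicit ROI (--roi cx,cy,r)"
        )
    order = np.lexsort((accums[good], rads[good]))[-1]
    roi = CircularROI(
        float(cxs[good][order]), float(cys[good][order]), float(rads[good][order])
    )
    if not roi.inside(h, w):
        raise InputDataError(
            f"detected dish (cx={roi.cx}, cy={roi.cy}, r={roi.radius}) is clipped "
            "by the image border; supply an explicit ROI (--roi cx,cy,r)"
        )
    return roi


def mean_rgb(
    image: np.ndarray, roi: CircularROI, shrink: float = DEFAULT_SHRINK
) -> RGBMean:
    """Mean per-channel intensity over pixels strictly inside the shrunken ROI.

    The radius is multiplied by ``shrink`` (default 0.8) before masking, to
    exclude the dish rim and edge highlights.  A pixel counts iff its center
    lies strictly inside the shrunken circle.
    """
    inner = roi.shrunk(shrink)
    h, w = image.shape[:2]
    if not inner.inside(h, w):
        raise InputDataError(
            f"shrunken ROI (cx={inner.cx}, cy={inner.cy}, r={inner.radius}) "
            f"extends beyond the {w}x{h} image"
        )
    mask = _roi_mask(image.shape, inner)
    n = int(mask.sum())
    if n == 0:
        raise InputDataError("empty ROI: no pixel centers inside the shrunken circle")
    sel = image[mask].astype(float)
    means = sel.mean(axis=0)
    return RGBMean(float(means[0]), float(means[1]), float(means[2]), n_pixels=n)


def average_replicates(means: Sequence[RGBMean]) -> RGBMean:
    """Unweighted per-channel average of replicate measurements.

    Replicates are averaged plainly regardless of each image's pixel count;
    the returned ``n_pixels`` is the sum over inputs.
    """
    if len(means) == 0:
        raise InputDataError("cannot average an empty list of replicates")
    stack = np.array([m.as_array() for m in means])
    avg = stack.mean(axis=0)
    return RGBMean(
        float(avg[0]),
        float(avg[1]),
        float(avg[2]),
        n_pixels=int(sum(m.n_pixels for m in means)),
    )


def saturation_fraction(image: np.ndarray, roi: CircularROI) -> float:
    """Fraction of in-ROI pixels with any channel clipped at 255.

    Exposure QC: saturated pixels bias channel means downward-blind, so
    callers should warn above ``DEFAULT_SATURATION_THRESHOLD``.
    """
    h, w = image.shape[:2]
    if not roi.inside(h, w):
        raise InputDataError("ROI extends beyond the image")
    mask = _roi_mask(image.shape, roi)
    n = int(mask.sum())
    if n == 0:
        raise InputDataError("empty ROI")
    saturated = (image[mask] == 255).any(axis=1)
    return float(saturated.sum()) / n


# --- extraction CSV -------------------------------------------------------

EXTRACTION_COLUMNS = [
    "sample_id",
    "mlss_g_per_L",
    "r_mean",
    "g_mean",
    "b_mean",
    "n_pixels",
    "n_replicates",
]


def write_extraction_csv(
    rows: Iterable[tuple[str, float | None, RGBMean, int]], path: str | Path
) -> None:
    """Write (sample_id, mlss-or-None, mean, n_replicates) rows to CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EXTRACTION_COLUMNS)
        for sample_id, mlss, mean, n_rep in rows:
            writer.writerow(
                [
                    sample_id,
                    "" if mlss is None else repr(float(mlss)),
                    repr(mean.r),
                    repr(mean.g),
                    repr(mean.b),
                    mean.n_pixels,
                    n_rep,
                ]
            )


def group_by_pattern(paths: Sequence[str | Path], pattern: str) -> dict[str, list[Path]]:
    """Group image paths into replicate sets by a regex with one capture group.

    The group captured from each file's basename is the sample id; files whose
    basename does not match raise an input error (silent drops would corrupt
    replicate averaging).
    """
    rx = re.compile(pattern)
    groups: dict[str, list[Path]] = {}
    for p in paths:
        p = Path(p)
        m = rx.search(p.name)
        if not m or not m.groups():
            raise InputDataError(
                f"filename {p.name!r} does not match group pattern {pattern!r}"
            )
        groups.setdefault(m.group(1), []).append(p)
    return groups
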