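"""Membrane image I/O, Gaussian pre-blur and prominence-based maxima finding.

The localization chain mirrors the classic semi-automatic dot-blot workflow:
blur the scan to suppress speckle, list local intensity maxima above a
noise-tolerance (prominence) threshold, and hand those to grid inference.
Densitometry itself always runs on the *original* unblurred raster.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy import ndimage
from skimage.morphology import reconstruction

__all__ = [
    "MembraneImage",
    "MaximaSet",
    "read_image",
    "write_image",
    "gaussian_blur",
    "find_local_maxima",
    "write_maxima_csv",
    "read_maxima_csv",
]


@dataclass
class MembraneImage:
    """A 2-D non-negative intensity raster in signal-high polarity.

    ``signal_high`` means spots are brighter than background (the internal
    convention; dark-spot scans are inverted on read).
    """

    pixels: np.ndarray
    polarity: str = "signal_high"
    constant_warning: bool = False

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("MembraneImage requires a 2-D array")
        h, w = self.pixels.shape
        if h < 16 or w < 16:
            raise ValueError(f"image too small ({h}x{w}); need >= 16 px per side")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ValueError("image contains negative intensities")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class MaximaSet:
    """Detected local maxima: ``points`` is an (n, 3) array of (x, y, intensity)."""

    points: np.ndarray
    prominence_threshold: float
    min_separation: float

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> np.ndarray:
        return self.points[:, :2]

    def check_bounds(self, shape: tuple[int, int]) -> None:
        """Validate all points lie inside an image of the given (h, w) shape."""
        h, w = shape
        x, y = self.points[:, 0], self.points[:, 1]
        bad = (x < 0) | (x > w - 1) | (y < 0) | (y > h - 1)
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"maximum {i} at ({x[i]:g}, {y[i]:g}) outside {w}x{h} image bounds"
            )


def read_image(path: str | Path, polarity: str = "signal_high") -> MembraneImage:
    """Read an 8/16-bit grayscale TIFF or PNG as a :class:`MembraneImage`.

    RGB inputs are collapsed to luminance by channel averaging.  Images whose
    spots are darker than background (``polarity="signal_low"``) are inverted
    as ``max - pixel`` so that downstream code can assume bright spots.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise IOError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    if polarity == "signal_low":
        arr = arr.max() - arr
    elif polarity != "signal_high":
        raise ValueError(f"unknown polarity {polarity!r}")
    constant = bool(arr.max() == arr.min())
    return MembraneImage(arr, polarity="signal_high", constant_warning=constant)


def write_image(image: MembraneImage, path: str | Path) -> None:
    """Write as 16-bit TIFF (``.tif``) or PNG; intensities clipped to uint16."""
    path = Path(path)
    arr = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def gaussian_blur(image: MembraneImage, sigma: float = 4.0) -> MembraneImage:
    """Gaussian convolution with standard deviation ``sigma`` (pixels).

    Boundary handling is reflective, so total intensity is conserved for
    interior content.  The default sigma of 4 px matches the pre-processing
    blur conventionally applied before spot localization on these arrays.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    # truncate=6 keeps the kernel tail below 1e-8 so repeated blurs compose
    blurred = ndimage.gaussian_filter(image.pixels, sigma=sigma, mode="reflect",
                                      truncate=6.0)
    return MembraneImage(blurred, polarity=image.polarity)


def find_local_maxima(
    image: MembraneImage,
    prominence: float | None = None,
    min_separation: float = 5.0,
) -> MaximaSet:
    """List strict local maxima with topographic prominence >= ``prominence``.

    Prominence follows the noise-tolerance definition: a peak's height above
    the highest saddle connecting it to higher terrain (the global maximum
    has full prominence).  It is computed via grayscale reconstruction of
    ``image - prominence`` under ``image``: a peak survives iff its h-dome
    reaches the requested height.  Candidates are strict 8-neighbourhood
    maxima; peaks closer than ``min_separation`` to a stronger accepted peak
    are suppressed (greedy, by descending intensity).  The result is sorted
    by descending intensity, ties broken by (y, x).

    ``prominence`` defaults to 10% of the image dynamic range.
    """
    pix = image.pixels
    rng = float(pix.max() - pix.min())
    if prominence is None:
        prominence = 0.1 * rng
    if prominence < 0:
        raise ValueError("prominence must be >= 0")
    if rng == 0:
        return MaximaSet(np.empty((0, 3)), prominence, min_separation)

    # strict local maxima over the 8-neighbourhood
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neighborhood_max = ndimage.maximum_filter(
        pix, footprint=footprint, mode="constant", cval=-np.inf
    )
    candidates = pix > neighborhood_max

    if prominence > 0:
        # h-dome: dome height == prominence exactly where dynamic >= prominence
        seed = pix - prominence
        dome = pix - reconstruction(seed, pix, method="dilation")
        tol = 1e-9 * max(1.0, rng)
        candidates &= dome >= prominence - tol
        # the global maximum's prominence is its height above the image floor
        candidates &= pix >= pix.min() + prominence - tol

    ys, xs = np.nonzero(candidates)
    vals = pix[ys, xs]
    order = np.lexsort((xs, ys, -vals))
    xs, ys, vals = xs[order], ys[order], vals[order]

    # greedy minimum-separation suppression, strongest peaks first
    keep_x, keep_y, keep_v = [], [], []
    min_sep2 = min_separation * min_separation
    for x, y, v in zip(xs, ys, vals):
        ok = True
        for kx, ky in zip(keep_x, keep_y):
            if (x - kx) ** 2 + (y - ky) ** 2 < min_sep2:
                ok = False
                break
        if ok:
            keep_x.append(x)
            keep_y.append(y)
            keep_v.append(v)
    pts = np.column_stack([keep_x, keep_y, keep_v]).astype(np.float64) \
        if keep_x else np.empty((0, 3))
    return MaximaSet(pts, float(prominence), float(min_separation))


_MAXIMA_COLUMNS = ["x", "y", "intensity"]


def write_maxima_csv(maxima: MaximaSet, path: str | Path) -> None:
    df = pd.DataFrame(maxima.points, columns=_MAXIMA_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9g")


def read_maxima_csv(path: str | Path) -> MaximaSet:
    """Read a maxima CSV (columns x, y, intensity) written by this package."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"cannot parse maxima CSV {path}: {exc}") from exc
    missing = [c for c in _MAXIMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[_MAXIMA_COLUMNS].isna()
    if bad.any().any():
        line = int(bad.any(axis=1).idxmax()) + 2  # 1-based + header row
        raise ValueError(f"{path}: malformed value at line {line}")
    return MaximaSet(df[_MAXIMA_COLUMNS].to_numpy(float), np.nan, np.nan)
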