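"""Silhouette extraction and per-row width profiling.

The measurement chain is: clear the (bright) background, keep the largest
4-connected dark component, fill interior holes, then read the per-row
extent of the filled mask.  A Canny edge map is exposed as an inspectable
intermediate stage, but widths are always taken from the filled mask so
the contract stays deterministic and hole-robust.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import feature, filters, measure as skmeasure

from bodymetry.errors import EmptySilhouetteError, ValidationError

__all__ = [
    "WidthProfile",
    "BackgroundAssumptionWarning",
    "load_image",
    "to_grayscale",
    "segment_foreground",
    "detect_edges",
    "width_profile",
    "silhouette_height_px",
    "read_mask",
    "write_mask",
]


class BackgroundAssumptionWarning(UserWarning):
    """More than 60% of pixels classified foreground: bright-background
    assumption is probably violated."""


@dataclass
class WidthProfile:
    """Per-row foreground widths of one view.

    ``row_widths_px[r]`` is the full span (rightmost - leftmost + 1) of
    foreground pixels in image row ``r`` (row 0 = top of image), zero
    where the row is empty.  ``chv_px`` is the silhouette pixel height
    ``bottom_row - top_row + 1`` used as the scale anchor.
    """

    view_angle_deg: float
    row_widths_px: np.ndarray
    top_row: int
    bottom_row: int

    @property
    def chv_px(self) -> int:
        return self.bottom_row - self.top_row + 1

    def height_fraction(self, row: int) -> float:
        """Normalized height-from-ground of ``row`` in [0, 1]."""
        if self.chv_px == 1:
            return 0.0
        return (self.bottom_row - row) / (self.chv_px - 1)

    def to_csv(self, path) -> None:
        """Write widths as CSV (row, width_px) plus a JSON sidecar."""
        path = Path(path)
        lines = ["row,width_px"]
        lines += [f"{r},{int(w)}" for r, w in enumerate(self.row_widths_px)]
        path.write_text("\n".join(lines) + "\n")
        sidecar = {
            "view_angle_deg": self.view_angle_deg,
            "chv_px": self.chv_px,
            "top_row": int(self.top_row),
            "bottom_row": int(self.bottom_row),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path) -> "WidthProfile":
        path = Path(path)
        rows = [
            line.split(",") for line in path.read_text().strip().splitlines()[1:]
        ]
        widths = np.array([int(w) for _, w in rows], dtype=int)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            view_angle_deg=float(meta["view_angle_deg"]),
            row_widths_px=widths,
            top_row=int(meta["top_row"]),
            bottom_row=int(meta["bottom_row"]),
        )


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF image as a numpy array."""
    return np.asarray(iio.imread(Path(path)))


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse a color image to single-channel float luminance in [0, 1]."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        if img.shape[2] == 4:  # drop alpha
            img = img[..., :3]
        img = img @ np.array([0.2125, 0.7154, 0.0721])
    if img.max() > 1.0:
        img = img / 255.0
    return img


def segment_foreground(
    image: np.ndarray,
    threshold: float | None = None,
) -> np.ndarray:
    """Segment a dark subject on a bright background into a clean mask.

    Pixels below the luminance threshold (Otsu when ``threshold`` is None)
    are foreground; the largest 4-connected component is kept and interior
    holes are filled.  Deterministic for fixed inputs.

    Raises
    ------
    EmptySilhouetteError
        If no foreground pixel survives.

    Warns
    -----
    BackgroundAssumptionWarning
        If more than 60% of the image is classified foreground.
    """
    gray = to_grayscale(image)
    if gray.size == 0:
        raise ValidationError("image is empty")
    if threshold is None:
        if np.ptp(gray) == 0:
            raise EmptySilhouetteError("empty silhouette: image is uniform")
        threshold = filters.threshold_otsu(gray)
    fg = gray < threshold
    if not fg.any():
        raise EmptySilhouetteError("empty silhouette: no pixel below threshold")
    if fg.mean() > 0.60:
        warnings.warn(
            "background assumption violated: >60% of pixels are foreground",
            BackgroundAssumptionWarning,
            stacklevel=2,
        )
    labels = skmeasure.label(fg, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()
    return ndimage.binary_fill_holes(mask)


def detect_edges(
    gray: np.ndarray,
    sigma: float = 2.0,
    low: float = 0.1,
    high: float = 0.3,
) -> np.ndarray:
    """Canny edge map of a single-channel image.

    ``low``/``high`` are hysteresis thresholds expressed as fractions of
    the intensity range.  This stage is for inspection and parity with the
    classic chain; measurements are taken from the filled mask instead.
    """
    gray = np.asarray(gray)
    if gray.ndim != 1 and gray.ndim != 2:
        raise ValidationError("grayscale required: input must be single-channel")
    if gray.ndim == 1:
        gray = gray[None, :]
    if not 0 <= low < high:
        raise ValidationError(f"need 0 <= low < high, got low={low} high={high}")
    img = gray.astype(float)
    rng = np.ptp(img)
    if rng == 0:
        return np.zeros_like(img, dtype=bool)
    img = (img - img.min()) / rng
    return feature.canny(img, sigma=sigma, low_threshold=low, high_threshold=high)


def _require_nonempty(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValidationError("mask must be 2-D")
    if not mask.any():
        raise EmptySilhouetteError("empty silhouette mask")
    return mask


def width_profile(mask: np.ndarray, view_angle_deg: float = 0.0) -> WidthProfile:
    """Per-row widths (rightmost - leftmost + 1) of a silhouette mask."""
    mask = _require_nonempty(mask)
    any_row = mask.any(axis=1)
    widths = np.zeros(mask.shape[0], dtype=int)
    cols = np.arange(mask.shape[1])
    for r in np.flatnonzero(any_row):
        c = cols[mask[r]]
        widths[r] = c[-1] - c[0] + 1
    rows = np.flatnonzero(any_row)
    return WidthProfile(
        view_angle_deg=float(view_angle_deg),
        row_widths_px=widths,
        top_row=int(rows[0]),
        bottom_row=int(rows[-1]),
    )


def silhouette_height_px(mask: np.ndarray) -> int:
    """Pixel height of the silhouette: bottom_row - top_row + 1."""
    mask = _require_nonempty(mask)
    rows = np.flatnonzero(mask.any(axis=1))
    return int(rows[-1] - rows[0] + 1)


def read_mask(path) -> np.ndarray:
    """Read an 8-bit PNG mask (0 = background, nonzero = foreground)."""
    return np.asarray(iio.imread(Path(path))) > 0


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG (0/255)."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))
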