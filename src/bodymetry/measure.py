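"""Multi-view measurement: pixel-to-cm scaling, view alignment, girth
profiles and waist/hip landmark location.

Each view contributes a per-row width profile in pixels.  The subject's
true stature (cm) and the silhouette pixel height anchor the scale:
``value_cm = stature_cm * value_px / height_px``.  Views are resampled
onto a common grid of normalized height fractions (0 = ground, 1 = crown)
so that each row yields a fan of half-widths across the view angles, from
which both circumference estimators are evaluated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from bodymetry import geometry, silhouette
from bodymetry.errors import StageError, ValidationError
from bodymetry.geometry import RadialFan
from bodymetry.silhouette import WidthProfile

__all__ = [
    "MeasureConfig",
    "ViewSet",
    "RadialMatrix",
    "GirthProfiles",
    "BodyMeasurements",
    "px_to_cm",
    "align_views",
    "girth_profile",
    "find_landmarks",
    "measure_subject",
    "load_view_directory",
]

_ANGLE_TOL = 1e-6


@dataclass(frozen=True)
class MeasureConfig:
    """Pipeline configuration.

    Landmark bands are normalized height intervals (fraction of stature
    from the ground): the waist is the minimum-girth row within
    ``waist_band`` and the hip the maximum-girth row within ``hip_band``.
    Defaults follow common anthropometric practice.
    """

    n_rows: int = 500
    waist_band: tuple[float, float] = (0.55, 0.70)
    hip_band: tuple[float, float] = (0.42, 0.55)
    threshold: float | None = None  # None = Otsu
    canny_sigma: float = 2.0
    report_decimals: int = 2

    def __post_init__(self):
        if self.n_rows < 2:
            raise ValidationError("n_rows must be >= 2")
        for name, band in (("waist_band", self.waist_band), ("hip_band", self.hip_band)):
            lo, hi = band
            if not (0.0 <= lo < hi <= 1.0):
                raise ValidationError(f"{name} must satisfy 0 <= lo < hi <= 1, got {band}")
        if self.waist_band == self.hip_band:
            raise ValidationError("waist_band and hip_band must differ")
        if self.waist_band[0] < self.hip_band[1]:
            raise ValidationError(
                "waist_band must lie above hip_band "
                f"(got waist {self.waist_band}, hip {self.hip_band})"
            )


@dataclass
class ViewSet:
    """Width profiles for one subject, one per view angle, plus stature."""

    views: list[tuple[float, WidthProfile]]
    stature_cm: float

    def __post_init__(self):
        if self.stature_cm <= 0:
            raise ValidationError(f"stature_cm must be positive, got {self.stature_cm}")
        if len(self.views) < 3:
            raise ValidationError("need at least 3 views spanning [0, 180]")
        self.views = sorted(self.views, key=lambda av: av[0])
        angles = np.array([a for a, _ in self.views], dtype=float)
        if abs(angles[0]) > _ANGLE_TOL or abs(angles[-1] - 180.0) > _ANGLE_TOL:
            raise ValidationError("view angles must span exactly [0, 180] degrees")
        steps = np.diff(angles)
        if np.ptp(steps) > _ANGLE_TOL:
            raise ValidationError("view angles must be uniformly spaced")
        step = float(steps[0])
        if abs(180.0 / step - round(180.0 / step)) > 1e-9:
            raise ValidationError(f"angular step {step} does not divide 180")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([a for a, _ in self.views], dtype=float)


@dataclass
class RadialMatrix:
    """Half-widths in cm on a [row x angle] grid of normalized heights.

    Rows run ground (fraction 0) to crown (fraction 1).
    """

    half_widths_cm: np.ndarray
    angles_deg: np.ndarray
    stature_cm: float
    height_frac: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.half_widths_cm.shape[0]


@dataclass
class GirthProfiles:
    """Per-row circumference estimates by both methods."""

    height_frac: np.ndarray
    cosine_cm: np.ndarray
    ellipse_cm: np.ndarray

    def to_csv(self, path) -> None:
        lines = ["height_frac,girth_cosine_cm,girth_ellipse_cm"]
        for h, c, e in zip(self.height_frac, self.cosine_cm, self.ellipse_cm):
            lines.append(f"{h:.6f},{c:.6f},{e:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class BodyMeasurements:
    """Final measurement record for one subject."""

    stature_cm: float
    height_frac: np.ndarray
    girth_cosine_cm: np.ndarray
    girth_ellipse_cm: np.ndarray
    waist_cm: dict[str, float]
    hip_cm: dict[str, float]
    waist_row_frac: float
    hip_row_frac: float
    config: MeasureConfig = field(default_factory=MeasureConfig)

    @property
    def profiles(self) -> GirthProfiles:
        return GirthProfiles(self.height_frac, self.girth_cosine_cm, self.girth_ellipse_cm)

    def to_json(self, path=None) -> str:
        nd = self.config.report_decimals
        payload = {
            "stature_cm": self.stature_cm,
            "waist_cm": {k: round(v, nd) for k, v in self.waist_cm.items()},
            "hip_cm": {k: round(v, nd) for k, v in self.hip_cm.items()},
            "waist_row_frac": round(self.waist_row_frac, 4),
            "hip_row_frac": round(self.hip_row_frac, 4),
            "config": {
                "n_rows": self.config.n_rows,
                "waist_band": list(self.config.waist_band),
                "hip_band": list(self.config.hip_band),
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def px_to_cm(ahv_cm: float, value_px: float, chv_px: int) -> float:
    """Scale a pixel measurement to cm via the known stature.

    ``result = ahv_cm * value_px / chv_px`` where ``ahv_cm`` is the
    subject's true height and ``chv_px`` the silhouette pixel height.
    """
    if ahv_cm <= 0:
        raise ValidationError(f"ahv_cm must be positive, got {ahv_cm}")
    if chv_px < 1:
        raise ValidationError(f"chv_px must be >= 1, got {chv_px}")
    if value_px < 0:
        raise ValidationError(f"value_px must be non-negative, got {value_px}")
    return ahv_cm * value_px / chv_px


def align_views(vs: ViewSet, n_rows: int = 500) -> RadialMatrix:
    """Resample every view onto a common grid of height fractions.

    Each view is normalized by its own silhouette bounding box (pixel
    heights may differ slightly between views), converted to cm via the
    stature anchor, halved into radii, and linearly interpolated onto
    ``n_rows`` fractions from ground to crown.
    """
    if n_rows < 2:
        raise ValidationError("n_rows must be >= 2")
    target = np.linspace(0.0, 1.0, n_rows)
    columns = []
    for angle, prof in vs.views:
        widths = np.asarray(prof.row_widths_px, dtype=float)
        rows = np.arange(prof.top_row, prof.bottom_row + 1)
        span = widths[prof.top_row : prof.bottom_row + 1]
        if span.size == 0 or not np.any(span > 0):
            raise StageError("align", f"view at {angle} deg has an empty profile")
        chv = prof.chv_px
        half_cm = np.array(
            [px_to_cm(vs.stature_cm, w, chv) / 2.0 for w in span]
        )
        if chv == 1:
            columns.append(np.full(n_rows, half_cm[0]))
            continue
        frac = (prof.bottom_row - rows) / (chv - 1)  # descending with row
        columns.append(np.interp(target, frac[::-1], half_cm[::-1]))
    return RadialMatrix(
        half_widths_cm=np.column_stack(columns),
        angles_deg=vs.angles_deg,
        stature_cm=vs.stature_cm,
        height_frac=target,
    )


def girth_profile(m: RadialMatrix) -> GirthProfiles:
    """Both circumference estimates for every row of a radial matrix.

    The cosine estimate uses the full fan of the row; the ellipse estimate
    uses only the 0 and 90 degree half-widths.
    """
    angles = m.angles_deg
    try:
        i0 = int(np.flatnonzero(np.abs(angles - 0.0) < _ANGLE_TOL)[0])
        i90 = int(np.flatnonzero(np.abs(angles - 90.0) < _ANGLE_TOL)[0])
    except IndexError:
        raise ValidationError(
            "ellipse method requires views at 0 and 90 degrees; "
            f"got angles {angles.tolist()}"
        ) from None
    cosine = np.empty(m.n_rows)
    ellipse = np.empty(m.n_rows)
    for r in range(m.n_rows):
        radii = m.half_widths_cm[r]
        if np.all(radii == 0):
            cosine[r] = 0.0
            ellipse[r] = 0.0
            continue
        cosine[r] = geometry.cosine_perimeter(RadialFan(angles, radii)).value
        ellipse[r] = geometry.ellipse_perimeter(radii[i0], radii[i90]).value
    return GirthProfiles(m.height_frac.copy(), cosine, ellipse)


def _band_extremum(
    frac: np.ndarray, values: np.ndarray, band: tuple[float, float], mode: str
) -> float:
    lo, hi = band
    idx = np.flatnonzero((frac >= lo) & (frac <= hi))
    if idx.size == 0:
        raise ValidationError(f"band {band} contains no profile rows")
    vals = values[idx]
    target = vals.min() if mode == "min" else vals.max()
    ties = idx[vals == target]
    center = (lo + hi) / 2.0
    best = ties[np.argmin(np.abs(frac[ties] - center))]
    return float(frac[best])


def find_landmarks(
    profiles: GirthProfiles, cfg: MeasureConfig
) -> tuple[float, float]:
    """Locate the waist (band minimum) and hip (band maximum) rows.

    Extrema are taken on the cosine profile; exact ties resolve to the row
    nearest the band center.  Returns ``(waist_row_frac, hip_row_frac)``.
    """
    waist = _band_extremum(profiles.height_frac, profiles.cosine_cm, cfg.waist_band, "min")
    hip = _band_extremum(profiles.height_frac, profiles.cosine_cm, cfg.hip_band, "max")
    return waist, hip


def _as_view_list(views) -> list[tuple[float, np.ndarray]]:
    if isinstance(views, Mapping):
        return [(float(a), v) for a, v in views.items()]
    return [(float(a), v) for a, v in views]


def measure_subject(
    views: Mapping[float, np.ndarray] | Sequence[tuple[float, np.ndarray]],
    stature_cm: float,
    cfg: MeasureConfig | None = None,
) -> BodyMeasurements:
    """Full pipeline from per-view rasters to waist/hip circumferences.

    ``views`` maps view angle (deg) to either a boolean silhouette mask or
    a grayscale/color image (segmented automatically).  Deterministic for
    fixed inputs and configuration.
    """
    cfg = cfg or MeasureConfig()
    profiles = []
    for angle, raster in _as_view_list(views):
        arr = np.asarray(raster)
        try:
            if arr.dtype == bool:
                mask = arr
            else:
                mask = silhouette.segment_foreground(arr, threshold=cfg.threshold)
            profiles.append((angle, silhouette.width_profile(mask, angle)))
        except Exception as exc:  # surface the failing stage and angle
            raise StageError("segment", f"view at {angle} deg: {exc}") from exc
    vs = ViewSet(views=profiles, stature_cm=stature_cm)
    matrix = align_views(vs, cfg.n_rows)
    girths = girth_profile(matrix)
    waist_frac, hip_frac = find_landmarks(girths, cfg)
    iw = int(np.argmin(np.abs(girths.height_frac - waist_frac)))
    ih = int(np.argmin(np.abs(girths.height_frac - hip_frac)))
    return BodyMeasurements(
        stature_cm=float(stature_cm),
        height_frac=girths.height_frac,
        girth_cosine_cm=girths.cosine_cm,
        girth_ellipse_cm=girths.ellipse_cm,
        waist_cm={"cosine": float(girths.cosine_cm[iw]), "ellipse": float(girths.ellipse_cm[iw])},
        hip_cm={"cosine": float(girths.cosine_cm[ih]), "ellipse": float(girths.ellipse_cm[ih])},
        waist_row_frac=waist_frac,
        hip_row_frac=hip_frac,
        config=cfg,
    )


def load_view_directory(path) -> tuple[dict[float, np.ndarray], float | None]:
    """Load masks from a fixture directory.

    Reads ``manifest.json`` when present (mapping angle to file plus
    ``stature_cm``); otherwise collects files named ``view_<angle>.png``.
    Returns ``(views, stature_cm_or_None)``.
    """
    path = Path(path)
    manifest = path / "manifest.json"
    views: dict[float, np.ndarray] = {}
    stature = None
    if manifest.exists():
        meta = json.loads(manifest.read_text())
        stature = meta.get("stature_cm")
        reader = (
            silhouette.load_image if meta.get("kind") == "image" else silhouette.read_mask
        )
        for angle, fname in meta["views"].items():
            views[float(angle)] = reader(path / fname)
    else:
        for f in sorted(path.glob("view_*.png")):
            angle = float(f.stem.split("_", 1)[1])
            views[angle] = silhouette.read_mask(f)
    if not views:
        raise ValidationError(f"no view masks found in {path}")
    return views, stature
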