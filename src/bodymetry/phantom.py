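"""Parametric body phantoms with analytic cross-sections.

A phantom is a vertical stack of superellipse cross-sections
``|x/a|^p + |y/b|^p = 1`` whose parameters are interpolated linearly
between declared levels.  The family is convex for ``p >= 1``, has a
closed-form support width for ``p = 2`` and cheap quadrature otherwise,
and spans circle-to-square torso shapes, which is what makes it a useful
stand-in for physical reference models: every level's true circumference
and projected half-width are known exactly, so rendered silhouettes come
with an oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import integrate

from bodymetry import silhouette
from bodymetry.errors import InsufficientResolutionError, ValidationError

__all__ = [
    "Level",
    "PhantomSpec",
    "TruthTable",
    "preset",
    "PRESET_NAMES",
    "true_girth",
    "support_half_width",
    "render_view",
    "render_photo",
    "make_fixture_set",
]


@dataclass(frozen=True)
class Level:
    """One cross-section: height fraction plus superellipse parameters."""

    h: float
    a: float
    b: float
    p: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.h <= 1.0:
            raise ValidationError(f"height fraction must be in [0, 1], got {self.h}")
        if self.a <= 0 or self.b <= 0:
            raise ValidationError("semi-axes must be positive")
        if self.p < 1:
            raise ValidationError(f"exponent must be >= 1 (convex), got {self.p}")


@dataclass(frozen=True)
class PhantomSpec:
    """A body phantom: stature plus a stack of cross-section levels."""

    stature_cm: float
    levels: tuple[Level, ...]
    name: str = "custom"

    def __post_init__(self):
        if self.stature_cm <= 0:
            raise ValidationError("stature_cm must be positive")
        levels = tuple(
            lv if isinstance(lv, Level) else Level(*lv) for lv in self.levels
        )
        object.__setattr__(self, "levels", levels)
        hs = [lv.h for lv in levels]
        if len(hs) < 2 or hs[0] != 0.0 or hs[-1] != 1.0:
            raise ValidationError("levels must run from h=0 to h=1")
        if any(h2 <= h1 for h1, h2 in zip(hs, hs[1:])):
            raise ValidationError("level heights must be strictly increasing")

    def section(self, h: float) -> tuple[float, float, float]:
        """Interpolated ``(a, b, p)`` at height fraction ``h``."""
        if not 0.0 <= h <= 1.0:
            raise ValidationError(f"height fraction must be in [0, 1], got {h}")
        hs = np.array([lv.h for lv in self.levels])
        a = float(np.interp(h, hs, [lv.a for lv in self.levels]))
        b = float(np.interp(h, hs, [lv.b for lv in self.levels]))
        p = float(np.interp(h, hs, [lv.p for lv in self.levels]))
        return a, b, p

    def max_half_width(self) -> float:
        """Upper bound on any projected half-width, for canvas sizing."""
        return max(math.hypot(lv.a, lv.b) for lv in self.levels)

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "stature_cm": self.stature_cm,
            "levels": [[lv.h, lv.a, lv.b, lv.p] for lv in self.levels],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(
            stature_cm=float(d["stature_cm"]),
            levels=tuple(Level(*map(float, row)) for row in d["levels"]),
            name=str(d.get("name", "custom")),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path) -> "PhantomSpec":
        """Load a spec from YAML or JSON."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# presets

_HOURGLASS_LEVELS = (
    # (h, a, b); torso aspect fixed at b = 0.75 a so girth extrema sit
    # exactly at the designed fractions (hip bulge 0.50, waist pinch 0.60)
    (0.00, 0.50, 0.40),
    (0.42, 0.90, 0.675),
    (0.50, 1.35, 1.0125),
    (0.60, 0.95, 0.7125),
    (0.70, 1.10, 0.825),
    (0.82, 1.15, 0.8625),
    (0.88, 0.45, 0.40),
    (1.00, 0.55, 0.50),
)
_TORSO_RANGE = (0.42, 0.75)  # levels scaled by the thin/overweight factor


def _hourglass(name: str, torso_scale: float = 1.0) -> PhantomSpec:
    levels = []
    for h, a, b in _HOURGLASS_LEVELS:
        s = torso_scale if _TORSO_RANGE[0] <= h <= _TORSO_RANGE[1] else 1.0
        levels.append(Level(h, a * s, b * s))
    return PhantomSpec(stature_cm=15.0, levels=tuple(levels), name=name)


def elliptic_cylinder(
    a: float, b: float, stature_cm: float = 15.0, p: float = 2.0, name: str = "elliptic"
) -> PhantomSpec:
    """Constant elliptical (or superelliptical) cross-section phantom."""
    return PhantomSpec(
        stature_cm=stature_cm,
        levels=(Level(0.0, a, b, p), Level(1.0, a, b, p)),
        name=name,
    )


PRESET_NAMES = ("cylinder", "elliptic", "hourglass", "thin", "overweight")


def preset(name: str) -> PhantomSpec:
    """Named phantom presets used throughout the tests and CLI."""
    if name == "cylinder":
        return elliptic_cylinder(1.0, 1.0, name="cylinder")
    if name == "elliptic":
        return elliptic_cylinder(1.2, 0.8, name="elliptic")
    if name == "hourglass":
        return _hourglass("hourglass")
    if name == "thin":
        return _hourglass("thin", torso_scale=0.80)
    if name == "overweight":
        return _hourglass("overweight", torso_scale=1.05)
    raise ValidationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


# ---------------------------------------------------------------------------
# analytic oracles


def _superellipse_arclength(a: float, b: float, p: float) -> float:
    """Perimeter of |x/a|^p + |y/b|^p = 1 by adaptive quadrature.

    Uses the polar parametrization r(phi) = u^(-1/p) with
    u = (cos(phi)/a)^p + (sin(phi)/b)^p, whose arc-length integrand
    sqrt(r^2 + r'^2) is smooth on the first quadrant for all p >= 1.
    """

    def ds(phi):
        c, s = math.cos(phi), math.sin(phi)
        u = (c / a) ** p + (s / b) ** p
        r = u ** (-1.0 / p)
        du = p * (-((c / a) ** (p - 1.0)) * s / a + ((s / b) ** (p - 1.0)) * c / b)
        dr = -(1.0 / p) * u ** (-1.0 / p - 1.0) * du
        return math.hypot(r, dr)

    length, _ = integrate.quad(ds, 0.0, math.pi / 2.0, epsabs=0.0, epsrel=1e-10, limit=500)
    return 4.0 * length


def true_girth(spec: PhantomSpec, h: float) -> float:
    """Exact circumference of the cross-section at height fraction ``h``."""
    a, b, p = spec.section(h)
    return _superellipse_arclength(a, b, p)


def support_half_width(spec: PhantomSpec, h: float, angle_deg: float) -> float:
    """Half-width of the level-``h`` section projected at ``angle_deg``.

    This is the support function of the superellipse in the image-plane
    direction: for ``p = 2`` it reduces to ``sqrt(a^2 cos^2 + b^2 sin^2)``.
    """
    a, b, p = spec.section(h)
    th = math.radians(angle_deg)
    ac, bs = a * abs(math.cos(th)), b * abs(math.sin(th))
    if p == 1.0:
        return max(ac, bs)
    if p > 1e6:  # rectangle limit
        return ac + bs
    q = p / (p - 1.0)  # dual exponent
    return (ac**q + bs**q) ** (1.0 / q)


# ---------------------------------------------------------------------------
# rendering


def _row_half_widths_cm(
    spec: PhantomSpec, angle_deg: float, chv_px: int, dist_cm: float | None
) -> np.ndarray:
    fracs = np.arange(chv_px)[::-1] / (chv_px - 1)  # row 0 = crown
    out = np.empty(chv_px)
    for i, h in enumerate(fracs):
        w = support_half_width(spec, h, angle_deg)
        if dist_cm is not None:
            if dist_cm <= w:
                raise ValidationError(
                    f"pinhole distance {dist_cm} cm must exceed half-width {w:.2f} cm"
                )
            w = dist_cm * w / math.sqrt(dist_cm**2 - w**2)
        out[i] = w
    return out


def render_view(
    spec: PhantomSpec,
    angle_deg: float,
    px_per_cm: float = 20.0,
    projection: str = "orthographic",
    dist_cm: float | None = None,
    margin_px: int = 4,
) -> np.ndarray:
    """Rasterize the silhouette seen from ``angle_deg`` as a boolean mask.

    Each body row gets a centered run of ``round(2 * half_width * px_per_cm)``
    foreground pixels.  ``projection='pinhole'`` magnifies widths by the
    tangent-line geometry of a camera at ``dist_cm`` (widths only; the
    camera is assumed level with each row).  Deterministic.
    """
    if px_per_cm <= 0:
        raise ValidationError("px_per_cm must be positive")
    if projection not in ("orthographic", "pinhole"):
        raise ValidationError(f"unknown projection {projection!r}")
    if projection == "pinhole":
        if dist_cm is None or dist_cm <= 0:
            raise ValidationError("pinhole projection requires dist_cm > 0")
    else:
        dist_cm = None
    chv = int(round(spec.stature_cm * px_per_cm))
    if chv < 20:
        raise InsufficientResolutionError(
            f"stature renders to {chv} px; need at least 20 (raise px_per_cm)"
        )
    half_cm = _row_half_widths_cm(spec, angle_deg, chv, dist_cm)
    widths = np.round(2.0 * half_cm * px_per_cm).astype(int)
    canvas_w = int(widths.max()) + 2 * margin_px + 2
    cx = canvas_w // 2
    mask = np.zeros((chv + 2 * margin_px, canvas_w), dtype=bool)
    for i, w in enumerate(widths):
        if w <= 0:
            continue
        left = cx - w // 2
        mask[margin_px + i, left : left + w] = True
    return mask


def render_photo(
    spec: PhantomSpec,
    angle_deg: float,
    px_per_cm: float = 20.0,
    fg: float = 0.08,
    bg: float = 0.95,
    noise_gaussian: float = 0.0,
    noise_salt_pepper: float = 0.0,
    rng: np.random.Generator | int | None = None,
    **render_kwargs,
) -> np.ndarray:
    """Photograph-like grayscale render: dark body on a light background.

    Optional seeded Gaussian intensity noise (std as a fraction of range)
    and salt-and-pepper corruption exercise the segmentation stage.
    """
    mask = render_view(spec, angle_deg, px_per_cm, **render_kwargs)
    img = np.where(mask, fg, bg).astype(float)
    rng = np.random.default_rng(rng)
    if noise_gaussian > 0:
        img = img + rng.normal(0.0, noise_gaussian, img.shape)
    if noise_salt_pepper > 0:
        flip = rng.random(img.shape) < noise_salt_pepper
        img[flip] = rng.integers(0, 2, flip.sum()).astype(float)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# fixtures


@dataclass
class TruthTable:
    """Oracle girths and per-angle support half-widths on a height grid."""

    frame: pd.DataFrame  # height_frac, girth_cm, halfwidth_<angle>...

    @classmethod
    def build(
        cls, spec: PhantomSpec, angles_deg, n_levels: int = 101
    ) -> "TruthTable":
        hs = np.linspace(0.0, 1.0, n_levels)
        data = {"height_frac": hs}
        data["girth_cm"] = [true_girth(spec, h) for h in hs]
        for ang in angles_deg:
            data[f"halfwidth_{ang:g}"] = [
                support_half_width(spec, h, ang) for h in hs
            ]
        return cls(pd.DataFrame(data))

    def girth_at(self, h: float) -> float:
        f = self.frame
        return float(np.interp(h, f["height_frac"], f["girth_cm"]))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.8f")

    @classmethod
    def from_csv(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path))


def make_fixture_set(
    spec: PhantomSpec,
    angles_deg,
    px_per_cm: float,
    out_dir,
    seed: int = 0,
    noise_gaussian: float = 0.0,
    noise_salt_pepper: float = 0.0,
) -> tuple[dict, TruthTable]:
    """Write rendered views, a manifest and the oracle truth CSV.

    Noise-free runs write binary masks; noisy runs write grayscale photos
    (the manifest records which).  Byte-identical for identical seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    noisy = noise_gaussian > 0 or noise_salt_pepper > 0
    rng = np.random.default_rng(seed)
    views = {}
    for ang in angles_deg:
        fname = f"view_{ang:g}.png"
        if noisy:
            img = render_photo(
                spec,
                ang,
                px_per_cm,
                noise_gaussian=noise_gaussian,
                noise_salt_pepper=noise_salt_pepper,
                rng=rng,
            )
            import imageio.v3 as iio

            iio.imwrite(out / fname, np.round(img * 255).astype(np.uint8))
        else:
            silhouette.write_mask(out / fname, render_view(spec, ang, px_per_cm))
        views[f"{ang:g}"] = fname
    manifest = {
        "phantom": spec.name,
        "stature_cm": spec.stature_cm,
        "px_per_cm": px_per_cm,
        "kind": "image" if noisy else "mask",
        "seed": seed,
        "views": views,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    truth = TruthTable.build(spec, [float(a) for a in angles_deg])
    truth.to_csv(out / "truth.csv")
    spec.to_yaml(out / "phantom.yaml")
    return manifest, truth
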