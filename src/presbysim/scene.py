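"""Synthetic multi-distance visual scene, or calibration of user images.

The psychophysics protocol shows a composite scene: a landscape poster and
high-contrast letters at far (4 m), text on a laptop at intermediate (66 cm)
and text on a phone at near (33 cm).  Far and intermediate occupy the upper
60% of the field, near the lower 40%.  This module builds a seedable,
copyright-free surrogate: procedurally drawn optotype-like glyphs and a
1/f-spectrum texture standing in for the landscape, with indoor-background
(~30 cd/m^2) and display (~52 cd/m^2) luminances.

Each viewing distance contributes one plane of a :class:`SceneStack`; a plane
is nonzero only inside its region mask, so the composite layout is the sum of
the three planes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .optics import OpticalConfig

__all__ = ["SceneStack", "generate_scene", "load_scene", "TARGET_NAMES"]

TARGET_NAMES = ("far", "intermediate", "near")

BACKGROUND_LUMINANCE = 30.0  # cd/m^2, indoor ambient
DISPLAY_LUMINANCE = 52.0  # cd/m^2, high-definition displays
GLYPH_LUMINANCE = 1.0  # cd/m^2, dark print on a bright display

UPPER_FIELD_FRACTION = 0.6  # far + intermediate share of the field
MARGIN_FRACTION = 0.04  # uniform-background band framing the displays

# Default glyph heights in arcmin (about 0.4 logMAR-equivalent strokes for
# the reading text; larger optotypes on the far chart).
DEFAULT_GLYPH_ARCMIN = {"far": 30.0, "intermediate": 16.0, "near": 12.0}


class SceneError(ValueError):
    """Raised for invalid scene parameters or unusable input images."""


# 5x7 bitmaps of Sloan-like letters used for optotypes and text surrogates.
_FONT = {
    "E": ("11111", "10000", "10000", "11110", "10000", "10000", "11111"),
    "F": ("11111", "10000", "10000", "11110", "10000", "10000", "10000"),
    "P": ("11110", "10001", "10001", "11110", "10000", "10000", "10000"),
    "T": ("11111", "00100", "00100", "00100", "00100", "00100", "00100"),
    "O": ("01110", "10001", "10001", "10001", "10001", "10001", "01110"),
    "Z": ("11111", "00001", "00010", "00100", "01000", "10000", "11111"),
    "L": ("10000", "10000", "10000", "10000", "10000", "10000", "11111"),
    "D": ("11110", "10001", "10001", "10001", "10001", "10001", "11110"),
    "H": ("10001", "10001", "10001", "11111", "10001", "10001", "10001"),
    "N": ("10001", "11001", "10101", "10011", "10001", "10001", "10001"),
}
_LETTERS = tuple(_FONT)


@dataclass
class SceneStack:
    """Calibrated luminance planes (cd/m^2) and region masks per distance."""

    planes: dict[str, np.ndarray]
    region_masks: dict[str, np.ndarray]
    pixel_pitch: float  # arcmin per pixel

    def __post_init__(self) -> None:
        shapes = {p.shape for p in self.planes.values()}
        shapes |= {m.shape for m in self.region_masks.values()}
        if len(shapes) != 1:
            raise SceneError(f"planes and masks disagree on frame shape: {shapes}")
        for name, plane in self.planes.items():
            if not np.all(np.isfinite(plane)) or (plane < 0).any():
                raise SceneError(f"plane '{name}' has non-finite or negative luminance")
        overlap = sum(m.astype(int) for m in self.region_masks.values())
        if (overlap > 1).any():
            raise SceneError("region masks overlap")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.planes.values())).shape

    def composite(self) -> np.ndarray:
        """The full scene as seen when every plane is in its region."""
        return sum(self.planes.values())


def _glyph(letter: str, stroke_px: int) -> np.ndarray:
    bitmap = np.array([[c == "1" for c in row] for row in _FONT[letter]], dtype=float)
    return np.kron(bitmap, np.ones((stroke_px, stroke_px)))


def _draw_text_rows(
    canvas: np.ndarray,
    rng: np.random.Generator,
    top: int,
    left: int,
    height: int,
    width: int,
    glyph_px: int,
    ink: float,
) -> None:
    """Fill a rectangle with rows of random letters (text surrogate)."""
    stroke = max(1, glyph_px // 7)
    gh, gw = 7 * stroke, 5 * stroke
    gap, line_gap = max(1, stroke), max(2, 2 * stroke)
    row = top
    while row + gh <= top + height:
        col = left
        while col + gw <= left + width:
            g = _glyph(_LETTERS[rng.integers(len(_LETTERS))], stroke)
            patch = canvas[row : row + gh, col : col + gw]
            patch[g > 0.5] = ink
            col += gw + gap
        row += gh + line_gap


def _pink_texture(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-spectrum texture in [0, 1] — a natural-image (landscape) surrogate."""
    h, w = shape
    noise = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    spec = np.fft.fft2(noise) / f
    spec[0, 0] = 0.0
    tex = np.real(np.fft.ifft2(spec))
    tex -= tex.min()
    peak = tex.max()
    return tex / peak if peak > 0 else tex


def generate_scene(
    config: OpticalConfig,
    seed: int = 0,
    *,
    background: float = BACKGROUND_LUMINANCE,
    display: float = DISPLAY_LUMINANCE,
    glyph_luminance: float = GLYPH_LUMINANCE,
    upper_fraction: float = UPPER_FIELD_FRACTION,
    margin_fraction: float = MARGIN_FRACTION,
    glyph_arcmin: dict[str, float] | None = None,
) -> SceneStack:
    """Generate the composite three-distance scene, deterministically per seed.

    The frame covers ``config.field_of_view`` at the PSF pixel pitch.  The
    upper ``upper_fraction`` of the field is split left/right into the far
    and intermediate regions, the remainder is the near region.
    """
    if config.field_of_view < 4.0:
        raise SceneError(
            f"field_of_view {config.field_of_view} deg too small to host the "
            "three viewing regions (need >= 4 deg)"
        )
    sizes = dict(DEFAULT_GLYPH_ARCMIN)
    if glyph_arcmin:
        sizes.update(glyph_arcmin)
    pitch = config.image_sampling
    n = int(round(config.field_of_view * 60.0 / pitch))
    n += n % 2
    rng = np.random.default_rng(seed)

    split = int(round(upper_fraction * n))
    masks = {
        "far": np.zeros((n, n), dtype=bool),
        "intermediate": np.zeros((n, n), dtype=bool),
        "near": np.zeros((n, n), dtype=bool),
    }
    masks["far"][:split, : n // 2] = True
    masks["intermediate"][:split, n // 2 :] = True
    masks["near"][split:, :] = True

    margin = int(round(margin_fraction * n))
    planes = {}
    for name in TARGET_NAMES:
        plane = np.zeros((n, n))
        plane[masks[name]] = background
        rows, cols = np.nonzero(masks[name])
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        # content rectangle, inset by the uniform-background margin
        ir0, ir1 = max(r0, margin), min(r1, n - margin)
        ic0, ic1 = max(c0, margin), min(c1, n - margin)
        inner_h, inner_w = ir1 - ir0, ic1 - ic0
        if inner_h < 16 or inner_w < 16:
            raise SceneError("field too small for the region margins")
        glyph_px = max(7, int(round(sizes[name] / pitch)))
        if name == "far":
            # left: 1/f landscape surrogate; right: bright chart with optotypes
            tex_w = inner_w // 2
            tex = _pink_texture(rng, (inner_h, tex_w))
            plane[ir0:ir1, ic0 : ic0 + tex_w] = 12.0 + 36.0 * tex
            chart = (ic0 + tex_w + max(1, inner_w // 20), ic1)
            plane[ir0:ir1, chart[0] : chart[1]] = display
            _draw_text_rows(
                plane, rng, ir0 + glyph_px // 2, chart[0] + glyph_px // 4,
                inner_h - glyph_px, chart[1] - chart[0] - glyph_px // 2,
                glyph_px, glyph_luminance,
            )
        else:
            plane[ir0:ir1, ic0:ic1] = display
            pad = max(2, glyph_px // 4)
            _draw_text_rows(
                plane, rng, ir0 + pad, ic0 + pad,
                inner_h - 2 * pad, inner_w - 2 * pad,
                glyph_px, glyph_luminance,
            )
        planes[name] = plane
    return SceneStack(planes=planes, region_masks=masks, pixel_pitch=pitch)


def _to_luminance(img: np.ndarray) -> np.ndarray:
    """Grayscale conversion (Rec.601 weights) and normalization to [0, 1]."""
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    if np.issubdtype(np.asarray(img).dtype, np.integer):
        arr = arr / float(np.iinfo(np.asarray(img).dtype).max)
    elif arr.max() > 1.0:
        arr = arr / arr.max()
    return np.clip(arr, 0.0, 1.0)


def load_scene(
    paths: dict[str, str],
    pixel_pitch: float,
    luminance_range: tuple[float, float] = (0.0, DISPLAY_LUMINANCE),
    upper_fraction: float = UPPER_FIELD_FRACTION,
) -> SceneStack:
    """Load user-supplied plane images (PNG/TIFF, 8/16-bit gray or RGB).

    Pixel values are mapped linearly from the full dtype range onto
    ``luminance_range`` (cd/m^2).  All planes must share dimensions; region
    masks default to the standard 60/40 field partition.
    """
    import imageio.v3 as iio

    missing = [t for t in TARGET_NAMES if t not in paths]
    if missing:
        raise SceneError(f"missing target plane(s): {', '.join(missing)}")
    if not (math.isfinite(pixel_pitch) and pixel_pitch > 0):
        raise SceneError(f"pixel_pitch must be positive, got {pixel_pitch}")
    lo, hi = luminance_range
    planes = {}
    shape = None
    for name in TARGET_NAMES:
        try:
            raw = iio.imread(paths[name])
        except (OSError, ValueError) as exc:
            raise SceneError(f"cannot read image for '{name}': {exc}") from exc
        lum = lo + (hi - lo) * _to_luminance(raw)
        if shape is None:
            shape = lum.shape
        elif lum.shape != shape:
            raise SceneError(
                f"plane '{name}' has shape {lum.shape}, expected {shape}"
            )
        planes[name] = lum
    h, w = shape
    split = int(round(upper_fraction * h))
    masks = {
        "far": np.zeros((h, w), dtype=bool),
        "intermediate": np.zeros((h, w), dtype=bool),
        "near": np.zeros((h, w), dtype=bool),
    }
    masks["far"][:split, : w // 2] = True
    masks["intermediate"][:split, w // 2 :] = True
    masks["near"][split:, :] = True
    return SceneStack(planes=planes, region_masks=masks, pixel_pitch=pixel_pitch)
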