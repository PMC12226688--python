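"""Colors, surface patterns, fractal images, and texture compositing.

Colors are designed in CIE LCh (lightness, chroma, hue angle): all default
stimulus colors share L* = 60 and c* = 40 and differ only in hue, in 30-degree
steps, so that color pairs used in a pattern differ in hue but not in
luminance or saturation.  The neutral default is the achromatic point
(L* = 60, c* = 0).  Patterns are hard-edged 1200 x 1200 rasters with 150-pixel
bands; fractal surface images are stacks of filled polygons that are exactly
invariant under 180-degree rotation about the image center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw
from skimage import color as _skcolor

from .features import _rng_for

PATTERN_KINDS = ("solid", "horizontal", "diagonal", "vertical", "grid")

#: shared lightness/chroma of the default hue wheel
DEFAULT_L = 60.0
DEFAULT_C = 40.0
HUE_STEP = 30.0


@dataclass(frozen=True)
class ColorLCh:
    """A CIE LCh color; hue wraps modulo 360, chroma is non-negative."""

    L: float
    c: float
    h: float = 0.0

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("chroma must be non-negative")
        object.__setattr__(self, "h", self.h % 360.0)


NEUTRAL_GRAY = ColorLCh(DEFAULT_L, 0.0, 0.0)


def color_from_name(name: str) -> ColorLCh:
    """Map a catalogue color identifier ('gray', 'hue030', ...) to LCh."""
    if name == "gray":
        return NEUTRAL_GRAY
    if name.startswith("hue"):
        return ColorLCh(DEFAULT_L, DEFAULT_C, float(int(name[3:])))
    raise ValueError(f"unknown color name {name!r}")


def lch_to_srgb(c: ColorLCh) -> tuple[int, int, int]:
    """Convert LCh -> Lab -> XYZ (D65) -> gamma-encoded sRGB, clipped 8-bit."""
    hr = math.radians(c.h)
    lab = np.array([[[c.L, c.c * math.cos(hr), c.c * math.sin(hr)]]])
    rgb = _skcolor.lab2rgb(lab)[0, 0]  # clips out-of-gamut channels
    return tuple(int(v) for v in np.round(np.clip(rgb, 0, 1) * 255))


def hue_pair(base: ColorLCh) -> tuple[ColorLCh, ColorLCh]:
    """The base color and its partner 30 degrees further around the hue circle."""
    return base, ColorLCh(base.L, base.c, (base.h + HUE_STEP) % 360.0)


@dataclass
class TextureImage:
    """An 8-bit RGBA raster."""

    pixels: np.ndarray  # (H, W, 4) uint8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 4 or px.dtype != np.uint8:
            raise ValueError("pixels must be (H, W, 4) uint8")
        self.pixels = px

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    def to_pil(self) -> Image.Image:
        return Image.fromarray(self.pixels, "RGBA")

    @staticmethod
    def from_pil(img: Image.Image) -> "TextureImage":
        return TextureImage(np.asarray(img.convert("RGBA"), dtype=np.uint8))

    def save(self, path) -> None:
        self.to_pil().save(path, format="PNG")

    @staticmethod
    def solid(rgb: tuple[int, int, int], size: int = 1200) -> "TextureImage":
        px = np.empty((size, size, 4), dtype=np.uint8)
        px[..., :3] = rgb
        px[..., 3] = 255
        return TextureImage(px)


def _as_rgb(color) -> tuple[int, int, int]:
    if isinstance(color, ColorLCh):
        return lch_to_srgb(color)
    if isinstance(color, str):
        return lch_to_srgb(color_from_name(color))
    return tuple(int(v) for v in color)


def make_pattern(kind: str, color_secondary, size: int = 1200,
                 stripe_width: int = 150, color_primary=NEUTRAL_GRAY) -> TextureImage:
    """One of the five preconfigured surface patterns.

    Bands alternate between the neutral primary color and ``color_secondary``
    with hard edges, ``stripe_width`` pixels wide; the diagonal pattern runs at
    45 degrees and the grid is the union of the horizontal and vertical
    secondary bands.  ``size`` must be a multiple of ``stripe_width``.
    """
    if kind not in PATTERN_KINDS:
        raise ValueError(f"unknown pattern kind {kind!r}")
    if size % stripe_width != 0:
        raise ValueError("size must be a multiple of stripe_width")
    gray = np.array(_as_rgb(color_primary), dtype=np.uint8)
    sec = np.array(_as_rgb(color_secondary), dtype=np.uint8)
    yy, xx = np.mgrid[0:size, 0:size]
    if kind == "solid":
        mask = np.ones((size, size), dtype=bool)
    elif kind == "horizontal":
        mask = (yy // stripe_width) % 2 == 1
    elif kind == "vertical":
        mask = (xx // stripe_width) % 2 == 1
    elif kind == "diagonal":
        mask = ((xx + yy) // stripe_width) % 2 == 1
    else:  # grid
        mask = (((yy // stripe_width) % 2 == 1) | ((xx // stripe_width) % 2 == 1))
    px = np.empty((size, size, 4), dtype=np.uint8)
    px[..., :3] = np.where(mask[..., None], sec, gray)
    px[..., 3] = 255
    return TextureImage(px)


def make_fractal(seed: int, n_layers: int = 6, size: int = 1200,
                 min_vertices: int = 6, max_vertices: int = 24,
                 min_radius: float = 0.10, max_radius: float = 0.45) -> TextureImage:
    """A point-symmetric polygon "fractal" surface image.

    ``n_layers`` filled polygons are drawn back to front (larger first); each
    polygon is point-symmetric about the canvas center (every vertex has its
    180-degree twin) with vertex count, radii, and RGBA color drawn from the
    seeded stream.  Exact 180-degree rotational invariance is enforced by
    rendering the top half-plane and rotating it onto the bottom half.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    rng = _rng_for(seed)
    cx = cy = size / 2.0
    layers = []
    for _ in range(n_layers):
        m = int(rng.integers(min_vertices, max_vertices + 1)) // 2
        m = max(m, 3)
        angles = np.sort(rng.uniform(0.0, math.pi, m))
        radii = rng.uniform(min_radius * size, max_radius * size, m)
        rgb = rng.integers(0, 256, 3)
        half = [(cx + r * math.cos(a), cy + r * math.sin(a))
                for a, r in zip(angles, radii)]
        pts = half + [(2 * cx - x, 2 * cy - y) for x, y in half]
        layers.append((float(radii.max()), pts, tuple(int(v) for v in rgb) + (255,)))
    layers.sort(key=lambda t: -t[0])  # larger polygons behind
    img = Image.new("RGBA", (size, size), (0, 0, 0, 0))
    draw = ImageDraw.Draw(img)
    for _, pts, rgba in layers:
        draw.polygon(pts, fill=rgba)
    px = np.asarray(img, dtype=np.uint8).copy()
    top = px[: size // 2]
    px[size - size // 2:] = top[::-1, ::-1]
    return TextureImage(px)


def composite_body_texture(pattern: TextureImage,
                           fractal: TextureImage | None = None,
                           placement: tuple[int, int] | None = None,
                           scale: float = 0.5) -> TextureImage:
    """Alpha-composite a fractal over a pattern at the body-center placement.

    The fractal's alpha channel acts as the blending mask; with no fractal the
    pattern is returned unchanged.  ``placement`` is the fractal center in
    pattern pixel coordinates (defaults to the canvas center) and must lie on
    the canvas.
    """
    if fractal is None:
        return pattern
    w, h = pattern.width, pattern.height
    if placement is None:
        placement = (w // 2, h // 2)
    px, py = placement
    if not (0 <= px < w and 0 <= py < h):
        raise ValueError(f"placement {placement} outside the {w}x{h} canvas")
    target = int(round(min(w, h) * scale))
    fr = fractal.to_pil()
    if fr.size != (target, target):
        fr = fr.resize((target, target), Image.NEAREST)
    base = pattern.to_pil()
    overlay = Image.new("RGBA", base.size, (0, 0, 0, 0))
    overlay.paste(fr, (px - target // 2, py - target // 2))
    return TextureImage.from_pil(Image.alpha_composite(base, overlay))
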