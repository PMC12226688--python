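"""Deterministic 2D preview rendering: orthographic z-buffer rasterizer.

The preview camera looks along -y (the object's front) with an orthographic
projection.  Auto-framing scales the object's bounding sphere to a fixed
fraction of the frame, so objects of any pre-normalization size appear at the
same apparent size.  Shading is Lambertian with a single fixed directional
light plus an ambient term (homogeneous lighting: no shadows, no specular),
with per-pixel texture lookup through the planar UVs.  Rendering is a pure
function of (mesh, textures, config): repeated runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import NONE, FeatureCatalogue, ObjectSpec, default_catalogue
from .geometry import TriMesh
from .textures import (
    TextureImage,
    color_from_name,
    composite_body_texture,
    lch_to_srgb,
    make_fractal,
    make_pattern,
)

_DEFAULT_LIGHT = np.array([-1.0, -1.0, 2.0]) / np.sqrt(6.0)

#: fractal size classes as a fraction of the texture canvas
FRACTAL_SCALES = {"small": 0.35, "regular": 0.5, "large": 0.65}
#: fractal placement classes as the vertical center in canvas fractions
FRACTAL_POSITIONS = {"center": 0.5, "upper": 0.3, "lower": 0.7}

WHITE = (255, 255, 255)


@dataclass
class RenderConfig:
    """Preview rendering parameters."""

    size: int = 512
    light_direction: np.ndarray = field(default_factory=lambda: _DEFAULT_LIGHT.copy())
    ambient: float = 0.25
    diffuse: float = 0.75
    framing: float = 0.8
    background: tuple[int, int, int] = WHITE

    def __post_init__(self) -> None:
        if not 0.0 < self.framing <= 1.0:
            raise ValueError("framing must lie in (0, 1]")
        d = np.asarray(self.light_direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("light direction must be non-zero")
        self.light_direction = d / n


def object_textures(spec: ObjectSpec, catalogue: FeatureCatalogue | None = None,
                    texture_size: int = 600, stripe_width: int = 75
                    ) -> dict[str, TextureImage | tuple[int, int, int]]:
    """Resolve a spec into per-part textures.

    The body gets its pattern (neutral gray + the body color) with the fractal
    composited at its center when present; the head gets its own pattern;
    arms, ears, and beak are plain white, as in the preconfigured objects.
    """
    catalogue = catalogue or default_catalogue()
    v = spec.values
    body = make_pattern(v["body_pattern"], color_from_name(v["body_color"]),
                        size=texture_size, stripe_width=stripe_width)
    if v["fractal_identity"] != NONE:
        fractal = make_fractal(seed=int(v["fractal_identity"][1:]),
                               size=max(128, texture_size // 2))
        placement = (texture_size // 2,
                     int(texture_size * FRACTAL_POSITIONS[v["fractal_position"]]))
        body = composite_body_texture(body, fractal, placement=placement,
                                      scale=FRACTAL_SCALES[v["fractal_size"]])
    head = make_pattern(v["head_pattern"], color_from_name(v["head_color"]),
                        size=texture_size, stripe_width=stripe_width)
    return {"body": body, "head": head, "arm": WHITE, "ear": WHITE, "beak": WHITE}


def render_preview(mesh: TriMesh, textures: dict | None = None,
                   config: RenderConfig | None = None) -> TextureImage:
    """Render an orthographic front view of a normalized, UV-mapped object."""
    config = config or RenderConfig()
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise ValueError("cannot render an empty mesh")
    if mesh.uvs is None:
        raise ValueError("mesh has no UVs; run planar_uv first")
    textures = textures or {}
    size = config.size
    v = mesh.vertices
    radius = float(np.linalg.norm(v, axis=1).max())
    if radius == 0:
        raise ValueError("mesh has zero extent")
    k = config.framing * size / (2.0 * radius)
    px = size / 2.0 + v[:, 0] * k
    py = size / 2.0 - v[:, 2] * k  # image rows grow downward
    depth = v[:, 1]                # camera at +y: larger y is nearer

    color = np.empty((size, size, 3), dtype=np.uint8)
    color[...] = config.background
    zbuf = np.full((size, size), -np.inf)

    normals = mesh.face_normals()
    light = config.light_direction
    uv = mesh.uvs
    tex_cache: dict[str, tuple[np.ndarray | None, np.ndarray]] = {}
    for label, tex in textures.items():
        if isinstance(tex, TextureImage):
            tex_cache[label] = (tex.pixels[..., :3], np.array(WHITE, dtype=float))
        else:
            tex_cache[label] = (None, np.array(tex, dtype=float))

    for f in range(mesh.n_faces):
        i0, i1, i2 = mesh.faces[f]
        x0, x1, x2 = px[i0], px[i1], px[i2]
        y0, y1, y2 = py[i0], py[i1], py[i2]
        xmin = max(int(np.floor(min(x0, x1, x2))), 0)
        xmax = min(int(np.ceil(max(x0, x1, x2))), size - 1)
        ymin = max(int(np.floor(min(y0, y1, y2))), 0)
        ymax = min(int(np.ceil(max(y0, y1, y2))), size - 1)
        if xmin > xmax or ymin > ymax:
            continue
        denom = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
        if abs(denom) < 1e-12:
            continue
        ys, xs = np.mgrid[ymin:ymax + 1, xmin:xmax + 1]
        cxp = xs + 0.5
        cyp = ys + 0.5
        w0 = ((y1 - y2) * (cxp - x2) + (x2 - x1) * (cyp - y2)) / denom
        w1 = ((y2 - y0) * (cxp - x2) + (x0 - x2) * (cyp - y2)) / denom
        w2 = 1.0 - w0 - w1
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        d = w0 * depth[i0] + w1 * depth[i1] + w2 * depth[i2]
        tile = zbuf[ymin:ymax + 1, xmin:xmax + 1]
        visible = inside & (d > tile)
        if not visible.any():
            continue
        n = normals[f]
        if n[1] < 0:  # two-sided shading: face the camera
            n = -n
        intensity = config.ambient + config.diffuse * max(0.0, float(n @ light))
        label = mesh.part_labels[f]
        tex_px, flat = tex_cache.get(label, (None, np.array(WHITE, dtype=float)))
        if tex_px is None:
            rgb = np.broadcast_to(flat, visible.shape + (3,))
        else:
            u = w0 * uv[i0, 0] + w1 * uv[i1, 0] + w2 * uv[i2, 0]
            vv = w0 * uv[i0, 1] + w1 * uv[i1, 1] + w2 * uv[i2, 1]
            th, tw = tex_px.shape[:2]
            tx = np.clip((u * (tw - 1)).astype(int), 0, tw - 1)
            ty = np.clip(((1.0 - vv) * (th - 1)).astype(int), 0, th - 1)
            rgb = tex_px[ty, tx].astype(float)
        shaded = np.clip(rgb * intensity, 0, 255).astype(np.uint8)
        tile[visible] = d[visible]
        region = color[ymin:ymax + 1, xmin:xmax + 1]
        region[visible] = shaded[visible]

    out = np.empty((size, size, 4), dtype=np.uint8)
    out[..., :3] = color
    out[..., 3] = 255
    return TextureImage(out)
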