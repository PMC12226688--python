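"""Quantitative evaluation of the similarity score against image similarity.

The study mirrors the score-validation design: draw random objects, render
front-view previews, sample object pairs, and relate the normalized feature
similarity score of each pair to the structural similarity (SSIM) of their
preview images with an ordinary least-squares fit.  SSIM follows the standard
formulation (Gaussian window of 11 taps, sigma 1.5, K1 = 0.01, K2 = 0.03,
dynamic range 255, population statistics), computed on grayscale images.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .features import default_catalogue, random_spec
from .geometry import assemble, normalize, planar_uv
from .render import RenderConfig, object_textures, render_preview
from .similarity import WeightTable, normalized_score
from .textures import TextureImage

#: grayscale conversion weights (ITU-R BT.709 primaries)
_GRAY = np.array([0.2125, 0.7154, 0.0721])

_SSIM_WIN = 11
_SSIM_SIGMA = 1.5
_K1, _K2 = 0.01, 0.03


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


def _to_gray(img) -> np.ndarray:
    if isinstance(img, TextureImage):
        img = img.pixels
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _GRAY
    return arr


def _gaussian_kernel(win: int, sigma: float) -> np.ndarray:
    r = win // 2
    x = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    return g / g.sum()


def _blur(x: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Separable convolution; edge padding (the SSIM mean crops the border)."""
    r = len(g) // 2
    xp = np.pad(x, r, mode="edge")
    out = np.zeros_like(xp)
    for k, w in enumerate(g):
        out[:, r:-r] += w * xp[:, k:k + x.shape[1]]
    out2 = np.zeros_like(xp)
    for k, w in enumerate(g):
        out2[r:-r, :] += w * out[k:k + x.shape[0], :]
    return out2[r:-r, r:-r]


def ssim(img_a, img_b, data_range: float = 255.0, channels: str = "rgb") -> float:
    """Mean structural similarity of two images, in [-1, 1].

    Inputs may be RGBA/RGB rasters or 2D arrays of equal shape.  For color
    input, ``channels="rgb"`` (default) averages the per-channel SSIM over
    R, G, B — the stimulus color design holds lightness constant, so a
    grayscale reduction (``channels="gray"``) is blind to hue differences.
    Local statistics use an 11-tap Gaussian window (sigma 1.5); the mean is
    taken over windows fully inside the image.
    """
    a = _as_planes(img_a, channels)
    b = _as_planes(img_b, channels)
    if a.shape != b.shape:
        raise ValueError(f"image dimensions differ: {a.shape} vs {b.shape}")
    return float(np.mean([_ssim_single(pa, pb, data_range)
                          for pa, pb in zip(a, b)]))


def _as_planes(img, channels: str) -> np.ndarray:
    if isinstance(img, TextureImage):
        img = img.pixels
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 2:
        return arr[None]
    if channels == "gray":
        return (arr[..., :3] @ _GRAY)[None]
    return np.moveaxis(arr[..., :3], -1, 0)


def _ssim_single(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    g = _gaussian_kernel(_SSIM_WIN, _SSIM_SIGMA)
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    mu_a = _blur(a, g)
    mu_b = _blur(b, g)
    var_a = _blur(a * a, g) - mu_a * mu_a
    var_b = _blur(b * b, g) - mu_b * mu_b
    cov = _blur(a * b, g) - mu_a * mu_b
    s = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / \
        ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2))
    pad = (_SSIM_WIN - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def linear_regression(x, y) -> RegressionFit:
    """Ordinary least squares in closed form; r^2 = squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least two points")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise ValueError("x is constant; slope undefined")
    sxy = float(((x - xm) * (y - ym)).sum())
    syy = float(((y - ym) ** 2).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = 0.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return RegressionFit(slope=float(slope), intercept=float(intercept),
                         r_squared=float(min(r2, 1.0)))


@dataclass
class StudyResult:
    """Per-pair table plus the fitted score-vs-image-similarity regression."""

    pairs: list[tuple[int, int]]
    scores: np.ndarray   # normalized similarity score per pair
    metric: np.ndarray   # image similarity (SSIM by default) per pair
    fit: RegressionFit

    def to_csv(self) -> str:
        out = io.StringIO()
        out.write("pair_a,pair_b,normalized_score,image_similarity\n")
        for (i, j), s, m in zip(self.pairs, self.scores, self.metric):
            out.write(f"{i},{j},{s:.10g},{m:.10g}\n")
        return out.getvalue()


def similarity_vs_ssim_study(n_objects: int, n_pairs: int, seed: int,
                             metric=None, render_size: int = 128,
                             mesh_segments: int = 24, mesh_rings: int = 12,
                             texture_size: int = 300, stripe_width: int = 75
                             ) -> StudyResult:
    """Relate the feature-similarity score to image similarity of previews.

    Generates ``n_objects`` random objects, renders deterministic front-view
    previews, samples ``n_pairs`` distinct pairs, and regresses the image
    similarity (default: in-package SSIM; any callable ``metric(img_a,
    img_b) -> float`` may be substituted, e.g. an embedding similarity) on
    the normalized feature similarity score.  Fully reproducible given
    ``seed``.
    """
    max_pairs = n_objects * (n_objects - 1) // 2
    if n_pairs > max_pairs:
        raise ValueError(f"n_pairs={n_pairs} exceeds the {max_pairs} distinct pairs")
    metric = metric or ssim
    catalogue = default_catalogue()
    weights = WeightTable.default(catalogue)
    specs = [random_spec(catalogue, seed, index=i, object_id=f"obj{i:03d}")
             for i in range(n_objects)]
    config = RenderConfig(size=render_size)
    images = []
    for spec in specs:
        mesh = planar_uv(normalize(assemble(spec, catalogue,
                                            segments=mesh_segments,
                                            rings=mesh_rings)))
        tex = object_textures(spec, catalogue, texture_size=texture_size,
                              stripe_width=stripe_width)
        images.append(render_preview(mesh, tex, config))

    all_pairs = [(i, j) for i in range(n_objects) for j in range(i + 1, n_objects)]
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 77)))
    chosen = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    pairs = [all_pairs[int(k)] for k in chosen]
    scores = np.array([normalized_score(specs[i], specs[j], weights, catalogue)
                       for i, j in pairs])
    sims = np.array([float(metric(images[i], images[j])) for i, j in pairs])
    fit = linear_regression(scores, sims)
    return StudyResult(pairs=pairs, scores=scores, metric=sims, fit=fit)
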