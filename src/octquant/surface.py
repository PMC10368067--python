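"""Retina-surface extraction from a noisy B-scan.

Classical multi-step pipeline: (optional) suppression of bright particles
by local median inpainting, per-band grayscale normalization on narrow
vertical columns (default 10 px) to defeat lateral gain variation,
threshold binarization with small-region removal and Gaussian smoothing,
largest-component retina mask, and finally the surface curve as the
topmost mask row per column (the vitreous lies above the retina in a
B-scan).  Thresholds are heuristic presets, deliberately exposed: OCT
stacks vary considerably in grey level and any fixed threshold needs
occasional adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

__all__ = [
    "SurfaceParams",
    "SurfaceCurve",
    "NoRetinaError",
    "suppress_particles",
    "normalize_columns",
    "binarize_and_clean",
    "retina_mask",
    "surface_curve",
]


class NoRetinaError(RuntimeError):
    """Raised when no retina band can be found in a slice."""


@dataclass
class SurfaceParams:
    column_width: int = 10
    threshold: float = 0.5
    min_region_area: int = 200
    gaussian_sigma: float = 3.0
    inpaint_window: int = 9
    closing_radius: int = 2

    def __post_init__(self) -> None:
        if self.column_width < 1:
            raise ValueError("column_width must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.min_region_area < 0:
            raise ValueError("min_region_area must be >= 0")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")


@dataclass
class SurfaceCurve:
    """One real surface row index per image column; NaN marks columns where
    no retina was observed before interpolation."""

    rows: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)


def suppress_particles(image: np.ndarray, particle_mask: np.ndarray, inpaint_window: int = 9) -> np.ndarray:
    """Replace masked (particle) pixels by the median of unmasked pixels in
    a centered ``inpaint_window`` square (global unmasked median fallback);
    unmasked pixels pass through unchanged."""
    img = np.asarray(image, dtype=float)
    mask = np.asarray(particle_mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("particle mask shape does not match image")
    if mask.all():
        raise ValueError("particle mask covers the entire image")
    if not mask.any():
        return img.copy()
    out = img.copy()
    half = max(inpaint_window // 2, 1)
    global_median = float(np.median(img[~mask]))
    ys, xs = np.nonzero(mask)
    H, W = img.shape
    for y, x in zip(ys, xs):
        y0, y1 = max(y - half, 0), min(y + half + 1, H)
        x0, x1 = max(x - half, 0), min(x + half + 1, W)
        patch = img[y0:y1, x0:x1]
        pmask = mask[y0:y1, x0:x1]
        vals = patch[~pmask]
        out[y, x] = float(np.median(vals)) if vals.size else global_median
    return out


def normalize_columns(image: np.ndarray, column_width: int = 10) -> np.ndarray:
    """Independently rescale narrow vertical bands to [0, 1] by robust
    (1st/99th percentile) min-max; constant bands map to 0.  This removes
    per-band gain so one global threshold can binarize the whole scan."""
    img = np.asarray(image, dtype=float)
    if column_width < 1:
        raise ValueError("column_width must be >= 1")
    out = np.empty_like(img)
    W = img.shape[1]
    for x0 in range(0, W, column_width):
        band = img[:, x0 : x0 + column_width]
        lo, hi = np.percentile(band, [1.0, 99.0])
        if hi - lo <= 1e-12:
            out[:, x0 : x0 + column_width] = 0.0
        else:
            out[:, x0 : x0 + column_width] = np.clip((band - lo) / (hi - lo), 0.0, 1.0)
    return out


def binarize_and_clean(image: np.ndarray, params: SurfaceParams) -> np.ndarray:
    """Threshold, drop small 2-D components (8-connectivity), then Gaussian
    smooth the mask and re-threshold at 0.5."""
    img = np.asarray(image, dtype=float)
    mask = img >= params.threshold
    if params.min_region_area > 0 and mask.any():
        # drop components with area < min_region_area (8-connectivity)
        mask = morphology.remove_small_objects(mask, max_size=params.min_region_area - 1, connectivity=2)
    smoothed = ndimage.gaussian_filter(mask.astype(float), sigma=params.gaussian_sigma)
    return smoothed >= 0.5


def retina_mask(
    image: np.ndarray,
    particle_mask: np.ndarray | None = None,
    params: SurfaceParams | None = None,
) -> np.ndarray:
    """Full pipeline: particle suppression -> band normalization ->
    binarize/clean -> keep largest component -> morphological closing."""
    params = params or SurfaceParams()
    img = np.asarray(image, dtype=float)
    if particle_mask is not None:
        img = suppress_particles(img, particle_mask, params.inpaint_window)
    norm = normalize_columns(img, params.column_width)
    mask = binarize_and_clean(norm, params)
    if not mask.any():
        raise NoRetinaError("no retina found: binarized mask is empty")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(sizes)) + 1)
    if params.closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(params.closing_radius))
    return mask


def surface_curve(mask: np.ndarray) -> SurfaceCurve:
    """Topmost mask row per column; empty columns are linearly interpolated
    from their nearest valid neighbours (nearest-value extension at the
    ends)."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("cannot extract a surface from an empty mask")
    H, W = m.shape
    rows = np.full(W, np.nan)
    any_col = m.any(axis=0)
    rows[any_col] = m.argmax(axis=0)[any_col]
    valid = ~np.isnan(rows)
    if not valid.all():
        xs = np.arange(W)
        rows = np.interp(xs, xs[valid], rows[valid])
    return SurfaceCurve(rows)
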