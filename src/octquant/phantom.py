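"""Synthetic OCT phantoms with full ground truth.

A phantom volume emulates the geometry of a murine retinal OCT stack: a
bright, smoothly curved retina band over a dark vitreous, small bright
box-shaped particles planted strictly above the surface, and multiplicative
gamma speckle applied after the geometry is rendered.  Every phantom
carries its ground truth (per-slice surface curve, 3-D particle mask,
centroids and per-slice rectangles), so each downstream stage — surface
extraction, MPP detection, 3-D reconstruction, spatial statistics — can be
tested by parameter recovery without external data.

The module also provides the point-process simulators (CSR and Thomas)
used as null and positive controls for the clustering analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mpp import Rectangle
from .spatstat import PointPattern3D, StudyWindow

__all__ = [
    "ParticleSpec",
    "PhantomParams",
    "PhantomVolume",
    "PlacementError",
    "generate_phantom",
    "simulate_point_pattern",
]


class PlacementError(RuntimeError):
    """Raised when the requested particles cannot be placed non-overlapping
    above the retina surface within the retry budget."""


@dataclass
class ParticleSpec:
    """Geometry and placement of the planted particles.

    Particles are axis-aligned bright boxes spanning a contiguous slice
    range, so the vertical-rectangle mark of the MPP detector is exactly
    recoverable.  ``placement`` is "csr" (uniform in the admissible
    vitreous region) or "thomas" (Poisson parents with Gaussian-scattered
    offspring, the clustered positive control).
    """

    n_particles: int = 15
    width_range_px: tuple[int, int] = (3, 6)
    length_range_px: tuple[int, int] = (3, 6)
    depth_range_slices: tuple[int, int] = (2, 4)
    intensity: float = 0.9
    placement: str = "csr"
    thomas_params: tuple[int, float, float] | None = None  # (n_parents, mean_offspring, cluster_sd_px)
    min_gap_px: int = 6
    max_tries: int = 1000

    def __post_init__(self) -> None:
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        for lo, hi in (self.width_range_px, self.length_range_px, self.depth_range_slices):
            if lo > hi or lo < 1:
                raise ValueError("size ranges must be ordered and >= 1")
        if not 0 < self.intensity <= 1:
            raise ValueError("intensity must be in (0, 1]")
        if self.placement not in ("csr", "thomas"):
            raise ValueError("placement must be 'csr' or 'thomas'")
        if self.placement == "thomas" and self.thomas_params is None:
            self.thomas_params = (3, self.n_particles / 3.0, 12.0)


@dataclass
class PhantomParams:
    """Geometry, intensity and noise of the rendered stack.

    The surface row at column x in slice z is
    baseline + sine_amp * sin(2 pi x / sine_period) + quad_amp * ((x - W/2)/(W/2))^2
    + slice_shift_px * sin(pi z / (S-1)), a smooth single-valued curve per
    column as in a B-scan.
    """

    height_px: int = 256
    width_px: int = 256
    n_slices: int = 12
    surface_baseline_frac: float = 0.62
    surface_sine_amp: float = 8.0
    surface_sine_period: float | None = None
    surface_quad_amp: float = 6.0
    slice_shift_px: float = 2.0
    retina_thickness_px: int = 48
    background_level: float = 0.10
    retina_level: float = 0.70
    speckle_shape: float = 30.0
    particle_spec: ParticleSpec = field(default_factory=ParticleSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.height_px, self.width_px, self.n_slices) < 1:
            raise ValueError("height_px, width_px, n_slices must be >= 1")
        if self.retina_level <= self.background_level:
            raise ValueError("retina_level must exceed background_level")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")

    def surface_rows(self) -> np.ndarray:
        """Ground-truth surface row per (slice, column), shape (S, W)."""
        x = np.arange(self.width_px, dtype=float)
        period = self.surface_sine_period or self.width_px
        curve = (
            self.surface_baseline_frac * self.height_px
            + self.surface_sine_amp * np.sin(2 * np.pi * x / period)
            + self.surface_quad_amp * ((x - self.width_px / 2) / max(self.width_px / 2, 1)) ** 2
        )
        z = np.arange(self.n_slices, dtype=float)
        shift = self.slice_shift_px * np.sin(np.pi * z / max(self.n_slices - 1, 1))
        rows = curve[None, :] + shift[:, None]
        return np.clip(rows, 1.0, self.height_px - 2.0)


@dataclass
class PhantomVolume:
    """A rendered phantom with its complete ground truth."""

    volume: np.ndarray  # (S, H, W) floats in [0, 1]
    gt_surface: np.ndarray  # (S, W) surface row per column
    gt_particle_mask: np.ndarray  # (S, H, W) bool
    gt_centroids: PointPattern3D  # (z, y, x) box centroids
    gt_rectangles: list[list[Rectangle]]  # per-slice marks
    params: PhantomParams


def _boxes_clash(box_a, box_b, gap: int) -> bool:
    """Overlap test on boxes dilated by ``gap`` in y/x and 1 slice in z."""
    (za0, za1, ya0, ya1, xa0, xa1) = box_a
    (zb0, zb1, yb0, yb1, xb0, xb1) = box_b
    return (
        za0 < zb1 + 1
        and zb0 < za1 + 1
        and ya0 < yb1 + gap
        and yb0 < ya1 + gap
        and xa0 < xb1 + gap
        and xb0 < xa1 + gap
    )


def _place_particles(params: PhantomParams, rng: np.random.Generator):
    spec = params.particle_spec
    surf = params.surface_rows()
    boxes: list[tuple[int, int, int, int, int, int]] = []
    clearance = spec.min_gap_px  # keep the crown clear of the retina band
    parents = None
    if spec.placement == "thomas":
        n_par, _, sd = spec.thomas_params
        parents = np.column_stack(
            [
                rng.uniform(0, params.n_slices, n_par),
                rng.uniform(2, max(surf.min() - clearance, 3), n_par),
                rng.uniform(2, params.width_px - 2, n_par),
            ]
        )
    tries = 0
    while len(boxes) < spec.n_particles:
        if tries >= spec.max_tries:
            raise PlacementError(
                f"could not place {spec.n_particles} non-overlapping particles above "
                f"the retina surface after {spec.max_tries} tries "
                f"(placed {len(boxes)}); relax sizes, gap or count"
            )
        tries += 1
        w = int(rng.integers(spec.width_range_px[0], spec.width_range_px[1] + 1))
        l = int(rng.integers(spec.length_range_px[0], spec.length_range_px[1] + 1))
        d = int(rng.integers(spec.depth_range_slices[0], spec.depth_range_slices[1] + 1))
        if d > params.n_slices:
            raise PlacementError("particle depth exceeds the number of slices")
        if spec.placement == "csr":
            z0 = int(rng.integers(0, params.n_slices - d + 1))
            x0 = int(rng.integers(1, max(params.width_px - w - 1, 2)))
            y_top_limit = surf[z0 : z0 + d, x0 : x0 + w].min() - clearance - l
            if y_top_limit <= 1:
                continue
            y0 = int(rng.integers(1, int(y_top_limit) + 1))
        else:
            _, _, sd = spec.thomas_params
            parent = parents[rng.integers(0, len(parents))]
            z0 = int(round(parent[0] + rng.normal(0, max(sd / 8.0, 0.5)))) - d // 2
            y0 = int(round(parent[1] + rng.normal(0, sd))) - l // 2
            x0 = int(round(parent[2] + rng.normal(0, sd))) - w // 2
            if not (0 <= z0 <= params.n_slices - d and 1 <= x0 <= params.width_px - w - 1):
                continue
            if y0 < 1:
                continue
            if y0 + l + clearance > surf[z0 : z0 + d, x0 : x0 + w].min():
                continue
        box = (z0, z0 + d, y0, y0 + l, x0, x0 + w)
        if any(_boxes_clash(box, other, spec.min_gap_px) for other in boxes):
            continue
        boxes.append(box)
    return boxes, surf


def generate_phantom(params: PhantomParams) -> PhantomVolume:
    """Render a phantom stack; deterministic for a fixed seed.

    Geometry first (background, retina band below the surface curve,
    particle boxes), then multiplicative gamma speckle (mean 1, shape
    ``speckle_shape``), clipped to [0, 1].
    """
    rng = np.random.default_rng(params.seed)
    spec = params.particle_spec
    S, H, W = params.n_slices, params.height_px, params.width_px
    if spec.n_particles > 0:
        boxes, surf = _place_particles(params, rng)
    else:
        boxes, surf = [], params.surface_rows()

    vol = np.full((S, H, W), params.background_level)
    rows = np.arange(H)[None, :, None]
    surf3 = surf[:, None, :]
    band = (rows >= surf3) & (rows < surf3 + params.retina_thickness_px)
    vol[band] = params.retina_level

    mask = np.zeros((S, H, W), dtype=bool)
    centroids = []
    gt_rects: list[list[Rectangle]] = [[] for _ in range(S)]
    for (z0, z1, y0, y1, x0, x1) in boxes:
        vol[z0:z1, y0:y1, x0:x1] = spec.intensity
        mask[z0:z1, y0:y1, x0:x1] = True
        centroids.append(((z0 + z1 - 1) / 2.0, (y0 + y1 - 1) / 2.0, (x0 + x1 - 1) / 2.0))
        l, w = y1 - y0, x1 - x0
        for z in range(z0, z1):
            gt_rects[z].append(Rectangle(row=y0 + l // 2, col=x0 + w // 2, w=w, l=l))

    speckle = rng.gamma(shape=params.speckle_shape, scale=1.0 / params.speckle_shape, size=vol.shape)
    noisy = np.clip(vol * speckle, 0.0, 1.0)
    pts = np.asarray(centroids, dtype=float).reshape(len(centroids), 3)
    return PhantomVolume(
        volume=noisy,
        gt_surface=surf,
        gt_particle_mask=mask,
        gt_centroids=PointPattern3D(pts),
        gt_rectangles=gt_rects,
        params=params,
    )


def simulate_point_pattern(
    kind: str,
    n_or_params,
    window: StudyWindow,
    seed: int = 0,
) -> PointPattern3D:
    """Simulate a 3-D point pattern in a spherical window.

    kind="csr": ``n_or_params`` is the point count; points i.i.d. uniform
    in the ball.  kind="thomas": ``n_or_params`` is (n_parents,
    mean_offspring, cluster_sd); parents uniform in the ball, offspring
    isotropic Gaussian around parents, offspring outside the window
    discarded.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    center = np.asarray(window.center, dtype=float)

    def uniform_ball(m: int) -> np.ndarray:
        v = rng.normal(size=(m, 3))
        v /= np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-300)
        r = window.radius * rng.random(m) ** (1.0 / 3.0)
        return center + v * r[:, None]

    if kind == "csr":
        n = int(n_or_params)
        if n < 0:
            raise ValueError("n must be nonnegative")
        if n == 0:
            return PointPattern3D(np.empty((0, 3)))
        return PointPattern3D(uniform_ball(n))
    if kind == "thomas":
        n_parents, mean_offspring, cluster_sd = n_or_params
        if n_parents <= 0 or mean_offspring <= 0 or cluster_sd <= 0:
            raise ValueError("thomas parameters must be positive")
        parents = uniform_ball(int(n_parents))
        pts = []
        for p in parents:
            k = rng.poisson(mean_offspring)
            if k > 0:
                pts.append(p + rng.normal(scale=cluster_sd, size=(k, 3)))
        if not pts:
            return PointPattern3D(np.empty((0, 3)))
        pts = np.vstack(pts)
        keep = np.linalg.norm(pts - center, axis=1) <= window.radius
        return PointPattern3D(pts[keep])
    raise ValueError("kind must be 'csr' or 'thomas'")
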