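"""3-D spatial point-pattern analysis of particle centroids.

The central tool is Ripley's K-function inside a spherical study window:

    K_hat(r) = |W| / (n(n-1)) * sum_i sum_{j!=i} 1{||x_i - x_j|| <= r} / c_ij

where |W| = 4/3 pi R^3 is the window volume and c_ij is the isotropic edge
correction — the fraction of the surface area of the sphere of radius
||x_i - x_j|| centered at x_i that lies inside the window.  For a spherical
window this fraction has a closed form (a spherical cap).  Under complete
spatial randomness (CSR) K(r) = 4/3 pi r^3, the volume of the ball of
radius r, which serves as the null reference; pointwise Monte-Carlo
envelopes over seeded CSR simulations provide the significance bands used
by the clustering verdict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PointPattern3D",
    "StudyWindow",
    "RipleyEstimate",
    "ProjectedDensity",
    "cap_fraction",
    "ripley_k",
    "csr_envelope",
    "clustering_verdict",
    "projection_density",
    "default_radii",
]


@dataclass
class PointPattern3D:
    """A finite set of points in (z, y, x) coordinates."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array of (z, y, x)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        self.points = pts

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass
class StudyWindow:
    """Spherical study window W with center (z, y, x) and radius R."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("window radius must be positive")
        self.center = tuple(float(c) for c in self.center)

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(np.asarray(points, float) - np.asarray(self.center), axis=-1)
        return d <= self.radius * (1 + 1e-12)

    @classmethod
    def around(cls, pattern: PointPattern3D, radius: float) -> "StudyWindow":
        """Window centered at the pattern centroid (the default placement)."""
        if pattern.n == 0:
            raise ValueError("cannot center a window on an empty pattern")
        return cls(tuple(pattern.points.mean(axis=0)), radius)


@dataclass
class RipleyEstimate:
    radii: np.ndarray
    k_values: np.ndarray
    csr_reference: np.ndarray
    envelope_lo: np.ndarray | None = None
    envelope_hi: np.ndarray | None = None
    n_points: int = 0
    window: StudyWindow | None = None


def default_radii(r_max: float = 70.0, n: int = 64) -> np.ndarray:
    """Evenly spaced radii in (0, r_max] (the study range is 0–70 px)."""
    return np.linspace(r_max / n, r_max, n)


def cap_fraction(point, d: float, window: StudyWindow) -> float:
    """Fraction of the surface of the sphere of radius ``d`` centered at
    ``point`` that lies inside the spherical window.

    With rho the distance from the point to the window center and R the
    window radius: 1 when rho + d <= R, otherwise the spherical-cap area
    fraction (1 + (R^2 - rho^2 - d^2) / (2 rho d)) / 2, clamped to (0, 1].
    """
    p = np.asarray(point, dtype=float)
    rho = float(np.linalg.norm(p - np.asarray(window.center)))
    if rho > window.radius * (1 + 1e-9):
        raise ValueError("point lies outside the study window")
    if d < 0:
        raise ValueError("d must be nonnegative")
    if d == 0 or rho + d <= window.radius:
        return 1.0
    if rho == 0:
        return 1.0 if d <= window.radius else 1e-12
    f = 0.5 * (1.0 + (window.radius**2 - rho**2 - d**2) / (2.0 * rho * d))
    return float(min(max(f, 1e-12), 1.0))


def _cap_fractions(rho: np.ndarray, d: np.ndarray, R: float) -> np.ndarray:
    """Vectorized spherical-cap fraction, clamped to (0, 1]."""
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 0.5 * (1.0 + (R**2 - rho**2 - d**2) / (2.0 * rho * d))
    f = np.where((d == 0) | (rho + d <= R), 1.0, f)
    return np.clip(f, 1e-12, 1.0)


def ripley_k(
    points: PointPattern3D | np.ndarray,
    window: StudyWindow,
    radii: np.ndarray | None = None,
    edge_correction: bool = True,
) -> RipleyEstimate:
    """Edge-corrected Ripley K estimate over ``radii``.

    Points outside the window are dropped with a warning; fewer than two
    remaining points is an error.  ``edge_correction=False`` sets c == 1
    (the naive estimator, negatively biased near the boundary — exposed for
    bias diagnostics only).
    """
    if not isinstance(points, PointPattern3D):
        points = PointPattern3D(points)
    radii = default_radii() if radii is None else np.asarray(radii, dtype=float)
    if radii.ndim != 1 or np.any(np.diff(radii) <= 0) or np.any(radii < 0):
        raise ValueError("radii must be strictly increasing and nonnegative")
    inside = window.contains(points.points)
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} point(s) outside the study window were dropped",
            stacklevel=2,
        )
    pts = points.points[inside]
    n = pts.shape[0]
    if n < 2:
        raise ValueError("Ripley K requires at least two points inside the window")
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    rho = np.linalg.norm(pts - np.asarray(window.center), axis=-1)
    iu, ju = np.nonzero(~np.eye(n, dtype=bool))
    d_pairs = dist[iu, ju]
    if edge_correction:
        w_pairs = 1.0 / _cap_fractions(rho[iu], d_pairs, window.radius)
    else:
        w_pairs = np.ones_like(d_pairs)
    order = np.argsort(d_pairs, kind="stable")
    d_sorted = d_pairs[order]
    cumw = np.concatenate(([0.0], np.cumsum(w_pairs[order])))
    idx = np.searchsorted(d_sorted, radii, side="right")
    k = window.volume / (n * (n - 1)) * cumw[idx]
    return RipleyEstimate(
        radii=radii,
        k_values=k,
        csr_reference=4.0 / 3.0 * np.pi * radii**3,
        n_points=n,
        window=window,
    )


def csr_envelope(
    n: int,
    window: StudyWindow,
    radii: np.ndarray,
    n_sim: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise (alpha/2, 1-alpha/2) envelopes of K_hat under CSR.

    Quantiles use the 'lower'/'higher' order-statistic convention, so at
    n_sim = 20 and alpha = 0.05 the envelopes are the simulation min/max.
    """
    from .phantom import simulate_point_pattern

    if n < 2:
        raise ValueError("envelope requires n >= 2 points")
    if n_sim < 20:
        raise ValueError("need at least 20 simulations for a useful envelope")
    ks = np.empty((n_sim, len(radii)))
    for s in range(n_sim):
        pat = simulate_point_pattern("csr", n, window, seed=seed + s)
        ks[s] = ripley_k(pat, window, radii).k_values
    lo = np.quantile(ks, alpha / 2, axis=0, method="lower")
    hi = np.quantile(ks, 1 - alpha / 2, axis=0, method="higher")
    return lo, hi


def clustering_verdict(estimate: RipleyEstimate, r_range: tuple[float, float]) -> bool:
    """True iff K_hat exceeds the upper envelope (or, lacking envelopes, the
    CSR reference 4/3 pi r^3) at every tabulated radius in ``r_range`` —
    the operational reading of "consistently exceeds CSR"."""
    r_min, r_max = r_range
    sel = (estimate.radii >= r_min) & (estimate.radii <= r_max)
    if not sel.any():
        raise ValueError("r_range contains no tabulated radii")
    ref = estimate.envelope_hi if estimate.envelope_hi is not None else estimate.csr_reference
    return bool(np.all(estimate.k_values[sel] > np.asarray(ref)[sel]))


@dataclass
class ProjectedDensity:
    """Gaussian kernel density of a projected point pattern on a 2-D grid."""

    density: np.ndarray
    coords0: np.ndarray
    coords1: np.ndarray

    @property
    def cell_area(self) -> float:
        d0 = self.coords0[1] - self.coords0[0] if len(self.coords0) > 1 else 1.0
        d1 = self.coords1[1] - self.coords1[0] if len(self.coords1) > 1 else 1.0
        return float(d0 * d1)

    @property
    def mass(self) -> float:
        return float(self.density.sum() * self.cell_area)


_PLANES = {"xy": (1, 2), "xz": (0, 2), "yz": (0, 1)}


def projection_density(
    points: PointPattern3D | np.ndarray,
    plane: str = "xy",
    grid_shape: tuple[int, int] = (128, 128),
    bandwidth: float = 5.0,
) -> ProjectedDensity:
    """Project points onto a coordinate plane and evaluate a Gaussian KDE on
    a regular grid (each kernel normalized to unit mass, so the grid sums to
    approximately n for interior patterns).  Used for the per-day particle
    heatmaps over the retina surface (the xy projection)."""
    if not isinstance(points, PointPattern3D):
        points = PointPattern3D(points)
    if points.n == 0:
        raise ValueError("cannot form a density from an empty pattern")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if plane not in _PLANES:
        raise ValueError(f"plane must be one of {sorted(_PLANES)}")
    a0, a1 = _PLANES[plane]
    p0 = points.points[:, a0]
    p1 = points.points[:, a1]
    pad = 4.0 * bandwidth
    g0 = np.linspace(p0.min() - pad, p0.max() + pad, grid_shape[0])
    g1 = np.linspace(p1.min() - pad, p1.max() + pad, grid_shape[1])
    # sum of separable Gaussian kernels, each integrating to one
    k0 = np.exp(-0.5 * ((g0[:, None] - p0[None, :]) / bandwidth) ** 2)
    k1 = np.exp(-0.5 * ((g1[:, None] - p1[None, :]) / bandwidth) ** 2)
    dens = (k0 / (bandwidth * np.sqrt(2 * np.pi))) @ (k1 / (bandwidth * np.sqrt(2 * np.pi))).T
    return ProjectedDensity(density=dens, coords0=g0, coords1=g1)
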