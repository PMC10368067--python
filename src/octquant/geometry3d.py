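"""3-D particle reconstruction: stacking, labeling, filtering, centroids
and distances to the retina surface.

Per-slice detection masks are gathered into one volume, labeled with 3-D
connected components (26-connectivity by default), and filtered: particles
present on a single slice are discarded as speckle false positives (the
longitudinal resolution implies a real particle spans several B-scans),
and an optional per-slice bounding-box gate keeps only particles seen by
an independent detector.  Particle height above the retina comes from the
Euclidean distance transform of the negated retina mask, sampled at each
centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Particle",
    "stack_masks",
    "label_components",
    "filter_particles",
    "particle_summaries",
    "distance_map",
    "particle_distances",
]


@dataclass
class Particle:
    label: int
    voxel_count: int
    slice_extent: int
    centroid: tuple[float, float, float]  # (z, y, x), scaled by spacing
    distance_to_surface: float | None = None


def stack_masks(masks, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> np.ndarray:
    """Stack ordered per-slice 2-D masks into an (S, H, W) boolean volume."""
    if len(masks) == 0:
        raise ValueError("need at least one slice mask")
    shape = np.asarray(masks[0]).shape
    arrs = []
    for i, m in enumerate(masks):
        a = np.asarray(m, dtype=bool)
        if a.shape != shape:
            raise ValueError(f"slice {i} has shape {a.shape}, expected {shape}")
        arrs.append(a)
    vol = np.stack(arrs, axis=0)
    vol = np.asarray(vol)
    return vol


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


def label_components(volume: np.ndarray, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """3-D connected-component labeling; labels follow raster order of each
    component's first voxel (scipy's convention)."""
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6 or 26")
    vol = np.asarray(volume, dtype=bool)
    if vol.ndim != 3:
        raise ValueError("volume must be 3-D")
    labels, n = ndimage.label(vol, structure=_STRUCTS[connectivity])
    return labels, int(n)


def _slice_extents(labels: np.ndarray, n: int) -> np.ndarray:
    """Number of distinct slices occupied by each label 1..n."""
    extents = np.zeros(n + 1, dtype=int)
    for z in range(labels.shape[0]):
        present = np.unique(labels[z])
        extents[present[present > 0]] += 1
    return extents


def filter_particles(
    labels: np.ndarray,
    n_labels: int,
    min_slices: int = 2,
    boxes: dict[int, list[tuple[int, int, int, int]]] | None = None,
) -> tuple[np.ndarray, int]:
    """Remove labels spanning fewer than ``min_slices`` slices and, when
    ``boxes`` is given (slice index -> list of half-open (y0, x0, y1, x1)
    boxes), labels with no voxel inside any box.  Survivors are relabeled
    compactly, preserving first-voxel raster order."""
    if min_slices < 1:
        raise ValueError("min_slices must be >= 1")
    labels = np.asarray(labels)
    keep = np.ones(n_labels + 1, dtype=bool)
    keep[0] = False
    if min_slices > 1:
        extents = _slice_extents(labels, n_labels)
        keep &= extents >= min_slices
    if boxes is not None:
        gated = np.zeros(n_labels + 1, dtype=bool)
        for z, blist in boxes.items():
            if not (0 <= z < labels.shape[0]):
                continue
            for (y0, x0, y1, x1) in blist:
                region = labels[z, max(y0, 0) : y1, max(x0, 0) : x1]
                present = np.unique(region)
                gated[present[present > 0]] = True
        keep &= gated
    mapping = np.zeros(n_labels + 1, dtype=labels.dtype)
    surviving = np.nonzero(keep)[0]
    mapping[surviving] = np.arange(1, len(surviving) + 1)
    return mapping[labels], int(len(surviving))


def particle_summaries(
    labels: np.ndarray,
    n_labels: int,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[Particle]:
    """One Particle per label: voxel count, slice extent, mean centroid in
    voxel coordinates scaled by ``spacing``."""
    labels = np.asarray(labels)
    if n_labels == 0:
        return []
    idx = np.arange(1, n_labels + 1)
    counts = ndimage.sum_labels(np.ones_like(labels, dtype=float), labels, idx).astype(int)
    centroids = ndimage.center_of_mass(np.ones_like(labels, dtype=float), labels, idx)
    extents = _slice_extents(labels, n_labels)
    out = []
    sp = np.asarray(spacing, dtype=float)
    for lab, cnt, cen in zip(idx, counts, centroids):
        scaled = tuple(float(c * s) for c, s in zip(cen, sp))
        out.append(Particle(label=int(lab), voxel_count=int(cnt), slice_extent=int(extents[lab]), centroid=scaled))
    return out


def distance_map(retina_mask: np.ndarray, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> np.ndarray:
    """Euclidean distance from every voxel to the nearest retina-mask voxel
    (the negated-mask distance transform); zero on the mask itself."""
    mask = np.asarray(retina_mask, dtype=bool)
    if not mask.any():
        raise ValueError("retina mask is empty")
    return ndimage.distance_transform_edt(~mask, sampling=spacing)


def particle_distances(
    particles: list[Particle],
    dmap: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mode: str = "linear",
) -> list[Particle]:
    """Sample the distance map at each particle centroid (trilinear by
    default, nearest-voxel selectable); preserves input order."""
    if mode not in ("linear", "nearest"):
        raise ValueError("mode must be 'linear' or 'nearest'")
    dmap = np.asarray(dmap, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    out = []
    for p in particles:
        coords = np.asarray(p.centroid, dtype=float) / sp
        if np.any(coords < -0.5) or np.any(coords > np.asarray(dmap.shape) - 0.5):
            raise ValueError(f"centroid {p.centroid} outside distance-map bounds {dmap.shape}")
        order = 1 if mode == "linear" else 0
        val = ndimage.map_coordinates(dmap, coords[:, None], order=order, mode="nearest")[0]
        out.append(Particle(p.label, p.voxel_count, p.slice_extent, p.centroid, float(val)))
    return out
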