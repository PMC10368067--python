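"""Reading and writing OCT stacks and tabular results.

Volumes are multi-page TIFF stacks or directories of lexicographically
ordered PNG/TIFF slices; intensities are rescaled to [0, 1] on load
(uint8 / 255, uint16 / 65535; floats pass through clipped).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["OCTVolume", "load_volume", "save_volume", "save_mask_stack"]

_SLICE_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class OCTVolume:
    """An ordered stack of grayscale B-scans in [0, 1]."""

    data: np.ndarray  # (S, H, W) float
    bit_depth: int | None = None
    source: str | None = None

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


def _to_unit(arr: np.ndarray, name: str) -> tuple[np.ndarray, int | None]:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) -> luminance
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{name}: expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0, 8
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0, 16
    out = np.clip(arr.astype(float), 0.0, 1.0)
    return out, None


def load_volume(path: str | Path) -> OCTVolume:
    """Load a multi-page TIFF or a directory of per-slice images."""
    import imageio.v3 as iio
    import tifffile

    path = Path(path)
    slices: list[np.ndarray] = []
    depth: int | None = None
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES)
        if not files:
            raise ValueError(f"no PNG/TIFF slices found in {path}")
        shape = None
        for f in files:
            try:
                arr = iio.imread(f)
            except Exception as exc:  # noqa: BLE001 - re-raise naming the slice
                raise ValueError(f"unreadable slice {f.name}: {exc}") from exc
            img, d = _to_unit(np.asarray(arr), f.name)
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(f"slice {f.name} has shape {img.shape}, expected {shape}")
            depth = d if depth is None else depth
            slices.append(img)
    else:
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
        if pages.ndim == 2:
            pages = pages[None]
        for i, page in enumerate(pages):
            img, d = _to_unit(np.asarray(page), f"page {i}")
            depth = d if depth is None else depth
            slices.append(img)
    return OCTVolume(data=np.stack(slices, axis=0), bit_depth=depth, source=str(path))


def save_volume(path: str | Path, volume: np.ndarray, bit_depth: int = 16) -> None:
    """Write a [0, 1] float stack as a multi-page integer TIFF."""
    import tifffile

    vol = np.clip(np.asarray(volume, dtype=float), 0.0, 1.0)
    if bit_depth == 8:
        data = np.round(vol * 255).astype(np.uint8)
    elif bit_depth == 16:
        data = np.round(vol * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    tifffile.imwrite(path, data)


def save_mask_stack(directory: str | Path, masks: np.ndarray, prefix: str = "mask") -> list[Path]:
    """Write per-slice boolean masks as 8-bit PNGs named ``prefix_0000.png``."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for z, m in enumerate(np.asarray(masks, dtype=bool)):
        p = directory / f"{prefix}_{z:04d}.png"
        iio.imwrite(p, (m.astype(np.uint8) * 255))
        paths.append(p)
    return paths
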