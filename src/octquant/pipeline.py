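"""End-to-end pipeline: surface extraction -> vitreous ROI -> MPP detection
-> 3-D reconstruction -> particle counting, distances and clustering
analysis, with deterministic seeded execution and sidecar provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry3d import (
    distance_map,
    filter_particles,
    label_components,
    particle_distances,
    particle_summaries,
    stack_masks,
)
from .mpp import MPPParams, detect_slice
from .spatstat import (
    PointPattern3D,
    StudyWindow,
    clustering_verdict,
    csr_envelope,
    projection_density,
    ripley_k,
)
from .surface import NoRetinaError, SurfaceParams, retina_mask, surface_curve

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_outputs"]


@dataclass
class RipleyConfig:
    r_max: float = 70.0
    n_radii: int = 64
    n_sim: int = 50
    alpha: float = 0.05
    window_radius: float | None = None  # default: image width
    center: tuple[float, float, float] | None = None  # default: pattern centroid
    # null model for the envelopes: "vitreous_csr" resamples uniform points
    # from the observed vitreous region (same support as the data, so the
    # verdict measures clustering, not confinement); "window_csr" samples
    # the whole spherical window.
    null_model: str = "vitreous_csr"
    # lower bound above the particle hard-core scale (real particles have
    # finite size, so centroids cannot approach arbitrarily closely)
    verdict_r_range: tuple[float, float] = (15.0, 45.0)


@dataclass
class PipelineConfig:
    surface: SurfaceParams = field(default_factory=SurfaceParams)
    mpp: MPPParams = field(default_factory=MPPParams)
    min_slices: int = 2
    connectivity: int = 26
    roi_clearance_px: int = 2
    boxes: dict[int, list[tuple[int, int, int, int]]] | None = None
    ripley: RipleyConfig = field(default_factory=RipleyConfig)
    distance_bin_px: float = 10.0
    seed: int = 0


@dataclass
class PipelineResult:
    n_particles: int
    particles: list
    surface: np.ndarray  # (S, W) surface row per column
    particle_masks: np.ndarray  # (S, H, W) bool
    labels: np.ndarray
    ripley: object | None
    clustering: bool | None
    distance_bins: dict[str, int]
    report: dict


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    if d.get("boxes"):
        d["boxes"] = {int(k): [list(map(int, b)) for b in v] for k, v in d["boxes"].items()}
    return d


def _vitreous_envelope(
    vitreous_mask: np.ndarray,
    n: int,
    window,
    radii: np.ndarray,
    n_sim: int,
    alpha: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise K envelopes under uniform random placement over the
    vitreous voxels — the homogeneous null on the data's own support."""
    voxels = np.argwhere(vitreous_mask).astype(float)
    if len(voxels) < n:
        raise RuntimeError("vitreous region smaller than the particle count")
    rng = np.random.default_rng(seed)
    ks = np.empty((n_sim, len(radii)))
    for s in range(n_sim):
        idx = rng.choice(len(voxels), size=n, replace=False)
        pts = voxels[idx] + rng.uniform(-0.5, 0.5, size=(n, 3))
        with np.errstate(all="ignore"):
            ks[s] = ripley_k(PointPattern3D(pts), window, radii).k_values
    lo = np.quantile(ks, alpha / 2, axis=0, method="lower")
    hi = np.quantile(ks, 1 - alpha / 2, axis=0, method="higher")
    return lo, hi


def run_pipeline(volume: np.ndarray, config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage on an (S, H, W) volume in [0, 1].

    Per-slice: extract the retina mask and surface curve, restrict the MPP
    detector to the vitreous strictly above the surface (minus a small
    clearance), and rasterize the detections.  Volume-level: stack, label
    (3-D connected components), drop single-slice particles, summarize,
    measure centroid heights above the retina via the distance transform,
    and — with at least two particles — run the edge-corrected Ripley K
    analysis with CSR envelopes.
    """
    config = config or PipelineConfig()
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("volume must be (S, H, W)")
    S, H, W = vol.shape
    rows_idx = np.arange(H)[:, None]

    surf = np.zeros((S, W))
    det_masks = np.zeros((S, H, W), dtype=bool)
    retina3d = np.zeros((S, H, W), dtype=bool)
    for z in range(S):
        try:
            rmask = retina_mask(vol[z], params=config.surface)
        except NoRetinaError as exc:
            raise RuntimeError(f"surface stage failed on slice {z}: {exc}") from exc
        curve = surface_curve(rmask)
        surf[z] = curve.rows
        retina3d[z] = rows_idx >= curve.rows[None, :]
        roi = rows_idx < (curve.rows[None, :] - config.roi_clearance_px)
        mpp_params = replace(config.mpp, seed=config.mpp.seed + z)
        try:
            _, mask = detect_slice(vol[z], mpp_params, roi_mask=roi)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"detection stage failed on slice {z}: {exc}") from exc
        det_masks[z] = mask

    stacked = stack_masks(list(det_masks))
    labels, n0 = label_components(stacked, connectivity=config.connectivity)
    labels, n = filter_particles(labels, n0, min_slices=config.min_slices, boxes=config.boxes)
    particles = particle_summaries(labels, n)
    if n > 0:
        dmap = distance_map(retina3d)
        particles = particle_distances(particles, dmap)

    bins: dict[str, int] = {}
    for p in particles:
        b = int((p.distance_to_surface or 0.0) // config.distance_bin_px)
        key = f"{b * config.distance_bin_px:g}-{(b + 1) * config.distance_bin_px:g}"
        bins[key] = bins.get(key, 0) + 1

    ripley_est = None
    verdict = None
    skip_reason = None
    if n >= 2:
        pts = PointPattern3D(np.array([p.centroid for p in particles]))
        rcfg = config.ripley
        radius = rcfg.window_radius if rcfg.window_radius is not None else float(W)
        window = (
            StudyWindow(rcfg.center, radius)
            if rcfg.center is not None
            else StudyWindow.around(pts, radius)
        )
        radii = np.linspace(rcfg.r_max / rcfg.n_radii, rcfg.r_max, rcfg.n_radii)
        ripley_est = ripley_k(pts, window, radii)
        if rcfg.null_model == "vitreous_csr":
            vitreous = ~retina3d & (rows_idx[None, :, :] < surf[:, None, :] - config.roi_clearance_px)
            lo, hi = _vitreous_envelope(
                vitreous, ripley_est.n_points, window, radii,
                n_sim=rcfg.n_sim, alpha=rcfg.alpha, seed=config.seed,
            )
        else:
            lo, hi = csr_envelope(
                ripley_est.n_points, window, radii, n_sim=rcfg.n_sim, alpha=rcfg.alpha, seed=config.seed
            )
        ripley_est.envelope_lo, ripley_est.envelope_hi = lo, hi
        verdict = clustering_verdict(ripley_est, rcfg.verdict_r_range)
    else:
        skip_reason = f"clustering analysis skipped: {n} particle(s), need >= 2"

    report = {
        "n_slices": S,
        "n_components_raw": n0,
        "n_particles": n,
        "distance_bins": dict(sorted(bins.items())),
        "clustering_verdict": verdict,
        "ripley_skip_reason": skip_reason,
        "seed": config.seed,
    }
    return PipelineResult(
        n_particles=n,
        particles=particles,
        surface=surf,
        particle_masks=det_masks,
        labels=labels,
        ripley=ripley_est,
        clustering=verdict,
        distance_bins=bins,
        report=report,
    )


def write_outputs(result: PipelineResult, out_dir: str | Path, config: PipelineConfig) -> dict[str, Path]:
    """Write surface, particle and K-curve CSVs, the xy heatmap, the JSON
    report, and a sidecar with config hash, seed and version.  Outputs are
    byte-stable for a fixed volume, config and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    S, W = result.surface.shape
    surf_df = pd.DataFrame(
        {
            "slice": np.repeat(np.arange(S), W),
            "col": np.tile(np.arange(W), S),
            "row": result.surface.ravel(),
        }
    )
    paths["surface"] = out / "surface.csv"
    surf_df.to_csv(paths["surface"], index=False, float_format="%.4f")

    rows = [
        {
            "label": p.label,
            "voxel_count": p.voxel_count,
            "slice_extent": p.slice_extent,
            "z": p.centroid[0],
            "y": p.centroid[1],
            "x": p.centroid[2],
            "distance": p.distance_to_surface,
        }
        for p in result.particles
    ]
    paths["particles"] = out / "particles.csv"
    pd.DataFrame(rows, columns=["label", "voxel_count", "slice_extent", "z", "y", "x", "distance"]).to_csv(
        paths["particles"], index=False, float_format="%.4f"
    )

    if result.ripley is not None:
        est = result.ripley
        kdf = pd.DataFrame(
            {
                "r": est.radii,
                "K": est.k_values,
                "csr": est.csr_reference,
                "lo": est.envelope_lo,
                "hi": est.envelope_hi,
            }
        )
        paths["kcurve"] = out / "ripley_k.csv"
        kdf.to_csv(paths["kcurve"], index=False, float_format="%.6g")

        pts = PointPattern3D(np.array([p.centroid for p in result.particles]))
        dens = projection_density(pts, plane="xy", grid_shape=(96, 96), bandwidth=5.0)
        paths["heatmap_csv"] = out / "heatmap_xy.csv"
        np.savetxt(paths["heatmap_csv"], dens.density, delimiter=",", fmt="%.6g")
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(4, 4))
            ax.imshow(dens.density, origin="lower", cmap="inferno")
            ax.set_title("particle density (xy projection)")
            fig.savefig(out / "heatmap_xy.png", dpi=100)
            plt.close(fig)
            paths["heatmap_png"] = out / "heatmap_xy.png"
        except Exception:  # noqa: BLE001 - plotting is best-effort
            pass

    paths["report"] = out / "report.json"
    with open(paths["report"], "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)

    cfg = _config_dict(config)
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    sidecar = {
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
    }
    paths["sidecar"] = out / "run_sidecar.json"
    with open(paths["sidecar"], "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True, default=str)
    return paths
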