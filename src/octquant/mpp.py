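"""Marked-point-process detection of bright vitreous particles in a B-scan.

Particles are modelled as a configuration of non-overlapping axis-aligned
"vertical" rectangles.  Each rectangle ``{row, col, w, l}`` carries a data
term derived from the contrast between its interior and the surrounding
crown of background pixels; a hard-core prior forbids overlap.  Detection
is the configuration minimizing the total energy

    E(omega) = sum_i D(r_i)   subject to  r_i ∩ r_j = ∅ for i != j,

where D is the quality function applied to the normalized contrast
statistic.  The infinite overlap penalty is realized as a hard constraint:
overlapping configurations are never evaluated arithmetically.

The sampler is a multiple-births-and-deaths scheme with geometric annealing
followed by a deterministic local-search polish; a brute-force subset
enumerator over small candidate pools serves as the exactness oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "Rectangle",
    "Configuration",
    "MPPParams",
    "OptimizerParams",
    "contrast_statistic",
    "quality",
    "rectangle_energy",
    "overlaps",
    "configuration_energy",
    "candidate_data_terms",
    "brute_force_minimize",
    "greedy_minimize",
    "minimize_energy",
    "detect_slice",
    "rasterize",
]


@dataclass(frozen=True, order=True)
class Rectangle:
    """Axis-aligned vertical rectangle mark.

    ``row``/``col`` are the 0-based center pixel; the footprint is the
    half-open block ``[row - l//2, row - l//2 + l) x [col - w//2, col - w//2 + w)``.
    ``l`` is the vertical (row) extent, ``w`` the horizontal one.
    """

    row: int
    col: int
    w: int
    l: int

    @property
    def row0(self) -> int:
        return self.row - self.l // 2

    @property
    def col0(self) -> int:
        return self.col - self.w // 2

    @property
    def row1(self) -> int:
        return self.row0 + self.l

    @property
    def col1(self) -> int:
        return self.col0 + self.w

    def inside(self, shape: tuple[int, int]) -> bool:
        return self.row0 >= 0 and self.col0 >= 0 and self.row1 <= shape[0] and self.col1 <= shape[1]

    @property
    def area(self) -> int:
        return self.w * self.l


@dataclass
class Configuration:
    """A finite set of rectangles; admissible once pairwise non-overlapping."""

    rectangles: list[Rectangle] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rectangles)

    def __iter__(self):
        return iter(self.rectangles)

    def is_admissible(self) -> bool:
        rects = self.rectangles
        for i in range(len(rects)):
            for j in range(i + 1, len(rects)):
                if overlaps(rects[i], rects[j]):
                    return False
        return True


@dataclass
class OptimizerParams:
    """Annealing schedule for the births-and-deaths sampler."""

    n_iter: int = 200
    t0: float = 1.0
    cooling: float = 0.97
    birth_rate: float = 10.0
    convergence_window: int = 30


@dataclass
class MPPParams:
    """Detector parameters.

    x0 is the contrast threshold of the quality function: statistics above
    x0 map to negative (rewarding) energies under the corrected form.
    """

    x0: float = 6.0
    wmin: int = 3
    wmax: int = 7
    lmin: int = 3
    lmax: int = 7
    crown_width: int = 2
    bright_only: bool = True
    grid_stride: int = 1
    quality_form: str = "corrected"
    max_candidates: int = 20000
    optimizer: OptimizerParams = field(default_factory=OptimizerParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.x0 <= 0:
            raise ValueError("x0 must be positive")
        if self.wmin > self.wmax or self.lmin > self.lmax:
            raise ValueError("mark ranges must satisfy wmin <= wmax and lmin <= lmax")
        if self.crown_width < 1:
            raise ValueError("crown_width must be >= 1")
        if self.grid_stride < 1:
            raise ValueError("grid_stride must be >= 1")


def _as_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def contrast_statistic(image: np.ndarray, rect: Rectangle, crown_width: int = 2) -> float:
    """Normalized interior/crown contrast of ``rect``.

    x = (mu_in - mu_crown)^2 / (var_in + var_crown) with population
    variances.  The crown is the ring of pixels within ``crown_width``
    (Chebyshev) of the footprint, excluding the footprint, clipped to the
    image.  Zero total variance returns 0 for equal means and +inf (a
    "perfect contrast" sentinel) otherwise.
    """
    arr = _as_image(image)
    if not rect.inside(arr.shape):
        raise ValueError(f"rectangle {rect} exceeds image bounds {arr.shape}")
    inner = arr[rect.row0 : rect.row1, rect.col0 : rect.col1]
    rr0 = max(rect.row0 - crown_width, 0)
    cc0 = max(rect.col0 - crown_width, 0)
    rr1 = min(rect.row1 + crown_width, arr.shape[0])
    cc1 = min(rect.col1 + crown_width, arr.shape[1])
    block = arr[rr0:rr1, cc0:cc1]
    n_crown = block.size - inner.size
    if n_crown <= 0:
        raise ValueError("crown is empty: rectangle (plus clipping) fills the image")
    s_crown = block.sum() - inner.sum()
    sq_crown = (block**2).sum() - (inner**2).sum()
    mu_c = s_crown / n_crown
    var_c = max(sq_crown / n_crown - mu_c**2, 0.0)
    mu_i = inner.mean()
    var_i = float(np.var(inner))
    denom = var_i + var_c
    diff = mu_i - mu_c
    if denom <= 0.0:
        return 0.0 if math.isclose(mu_i, mu_c, rel_tol=1e-12, abs_tol=1e-12) else math.inf
    return diff * diff / denom


def quality(x: float, x0: float, form: str = "corrected") -> float:
    """Quality function mapping contrast x to an energy contribution.

    ``printed``:   Q(x) = 1 - x/x0 for x < x0, exp(-(x-x0)/x0) otherwise —
    discontinuous at x0 and everywhere positive.
    ``corrected`` (default): the second branch is exp(-(x-x0)/x0) - 1,
    continuous at x0 with range (-1, 1]; high contrast becomes a negative,
    rewarding, energy.
    """
    if x0 <= 0:
        raise ValueError("x0 must be positive")
    if x < 0:
        raise ValueError("contrast statistic must be nonnegative")
    if x < x0:
        return 1.0 - x / x0
    if math.isinf(x):
        # perfect-contrast sentinel: limit of the second branch
        return 0.0 if form == "printed" else -1.0
    val = math.exp(-(x - x0) / x0)
    return val if form == "printed" else val - 1.0


def rectangle_energy(image: np.ndarray, rect: Rectangle, params: MPPParams) -> float:
    """Data term D(r) = Q(contrast(r)); bright-only gate returns the worst
    quality (1) when the interior is not brighter than its crown."""
    arr = _as_image(image)
    if params.bright_only:
        inner = arr[rect.row0 : rect.row1, rect.col0 : rect.col1]
        rr0 = max(rect.row0 - params.crown_width, 0)
        cc0 = max(rect.col0 - params.crown_width, 0)
        rr1 = min(rect.row1 + params.crown_width, arr.shape[0])
        cc1 = min(rect.col1 + params.crown_width, arr.shape[1])
        block = arr[rr0:rr1, cc0:cc1]
        n_crown = block.size - inner.size
        if n_crown > 0:
            mu_c = (block.sum() - inner.sum()) / n_crown
            if inner.mean() <= mu_c:
                return 1.0
    x = contrast_statistic(arr, rect, params.crown_width)
    return quality(x, params.x0, params.quality_form)


def overlaps(ri: Rectangle, rj: Rectangle) -> bool:
    """True iff the half-open footprints intersect (shared edges do not)."""
    return (
        ri.row0 < rj.row1
        and rj.row0 < ri.row1
        and ri.col0 < rj.col1
        and rj.col0 < ri.col1
    )


def configuration_energy(image: np.ndarray, config: Configuration, params: MPPParams) -> float:
    """Total energy of an admissible configuration (sum of data terms)."""
    if not config.is_admissible():
        raise ValueError("inadmissible configuration: overlapping rectangle pair")
    return float(sum(rectangle_energy(image, r, params) for r in config))


# ---------------------------------------------------------------------------
# candidate generation (vectorized data terms over the center grid)


def _sat(arr: np.ndarray) -> np.ndarray:
    """Summed-area table with a zero border row/col."""
    out = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1))
    out[1:, 1:] = arr.cumsum(0).cumsum(1)
    return out


def _box_sum(sat: np.ndarray, r0, c0, r1, c1):
    """Sum over half-open boxes [r0,r1) x [c0,c1); bounds already clipped."""
    return sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0]


def candidate_data_terms(
    image: np.ndarray,
    params: MPPParams,
    roi_mask: np.ndarray | None = None,
    negative_only: bool = True,
):
    """Compute data terms over the grid of candidate rectangles.

    Returns (rectangles, energies); candidates whose center falls outside
    ``roi_mask`` (if given) are dropped.  Only candidates with a negative
    data term can lower the configuration energy, so by default only those
    are materialized; pass ``negative_only=False`` for the full grid.
    """
    arr = _as_image(image)
    H, W = arr.shape
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != arr.shape:
            raise ValueError("roi_mask shape does not match image")
    sat = _sat(arr)
    sat2 = _sat(arr**2)
    cw = params.crown_width
    stride = params.grid_stride
    rects: list[Rectangle] = []
    energies: list[float] = []
    for l, w in product(range(params.lmin, params.lmax + 1), range(params.wmin, params.wmax + 1)):
        if l > H or w > W:
            continue
        # top-left corners at which the footprint fits
        r0s = np.arange(0, H - l + 1)
        c0s = np.arange(0, W - w + 1)
        centers_r = r0s + l // 2
        centers_c = c0s + w // 2
        keep_r = (centers_r % stride) == 0
        keep_c = (centers_c % stride) == 0
        r0s, centers_r = r0s[keep_r], centers_r[keep_r]
        c0s, centers_c = c0s[keep_c], centers_c[keep_c]
        if r0s.size == 0 or c0s.size == 0:
            continue
        R0 = r0s[:, None]
        C0 = c0s[None, :]
        s_in = _box_sum(sat, R0, C0, R0 + l, C0 + w)
        q_in = _box_sum(sat2, R0, C0, R0 + l, C0 + w)
        n_in = float(l * w)
        rr0 = np.maximum(R0 - cw, 0)
        cc0 = np.maximum(C0 - cw, 0)
        rr1 = np.minimum(R0 + l + cw, H)
        cc1 = np.minimum(C0 + w + cw, W)
        s_blk = _box_sum(sat, rr0, cc0, rr1, cc1)
        q_blk = _box_sum(sat2, rr0, cc0, rr1, cc1)
        n_blk = (rr1 - rr0) * (cc1 - cc0)
        n_cr = n_blk - n_in
        mu_i = s_in / n_in
        var_i = np.maximum(q_in / n_in - mu_i**2, 0.0)
        mu_c = (s_blk - s_in) / n_cr
        var_c = np.maximum((q_blk - q_in) / n_cr - mu_c**2, 0.0)
        diff = mu_i - mu_c
        denom = var_i + var_c
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.where(denom > 0, diff**2 / np.where(denom > 0, denom, 1.0), np.where(np.abs(diff) < 1e-12, 0.0, np.inf))
        x0 = params.x0
        low = x < x0
        if params.quality_form == "printed":
            D = np.where(low, 1.0 - x / x0, np.exp(np.where(low, 0.0, -(x - x0)) / x0))
            D = np.where(np.isinf(x), 0.0, D)
        else:
            D = np.where(low, 1.0 - x / x0, np.exp(np.where(low, 0.0, -(x - x0)) / x0) - 1.0)
            D = np.where(np.isinf(x), -1.0, D)
        if params.bright_only:
            D = np.where(diff <= 0, 1.0, D)
        if roi_mask is not None:
            in_roi = roi_mask[np.ix_(centers_r, centers_c)]
        else:
            in_roi = np.ones(D.shape, dtype=bool)
        if negative_only:
            in_roi = in_roi & (D < 0)
        ridx, cidx = np.nonzero(in_roi)
        for a, b in zip(ridx, cidx):
            rects.append(Rectangle(int(centers_r[a]), int(centers_c[b]), w, l))
            energies.append(float(D[a, b]))
    return rects, np.asarray(energies)


# ---------------------------------------------------------------------------
# optimizers


def _overlap_bitmasks(rects: list[Rectangle]) -> list[int]:
    n = len(rects)
    masks = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if overlaps(rects[i], rects[j]):
                masks[i] |= 1 << j
                masks[j] |= 1 << i
    return masks


def brute_force_minimize(
    image: np.ndarray,
    candidates: list[Rectangle],
    params: MPPParams,
    max_candidates: int = 20,
) -> Configuration:
    """Exhaustive global minimizer over all admissible candidate subsets.

    Test oracle only: exponential in the pool size (hard cap
    ``max_candidates``).  Ties are broken toward fewer rectangles, then the
    lexicographically smallest sorted rectangle tuple.
    """
    n = len(candidates)
    if n > max_candidates:
        raise ValueError(f"brute force capped at {max_candidates} candidates, got {n}")
    D = [rectangle_energy(image, r, params) for r in candidates]
    ov = _overlap_bitmasks(candidates)
    best_energy = 0.0
    best_key: tuple = (0, ())
    best_mask = 0
    # DP over bitmasks: admissibility and energy from the subset minus its lowest bit
    energy = np.zeros(1 << n)
    admissible = np.ones(1 << n, dtype=bool)
    for mask in range(1, 1 << n):
        low = (mask & -mask).bit_length() - 1
        rest = mask & (mask - 1)
        admissible[mask] = admissible[rest] and not (ov[low] & rest)
        if not admissible[mask]:
            continue
        e = energy[rest] + D[low]
        energy[mask] = e
        if e < best_energy - 1e-12:
            best_energy, best_mask = e, mask
            best_key = None
        elif abs(e - best_energy) <= 1e-12:
            key = (bin(mask).count("1"), tuple(sorted(candidates[i] for i in range(n) if mask >> i & 1)))
            if best_key is None:
                best_key = (bin(best_mask).count("1"), tuple(sorted(candidates[i] for i in range(n) if best_mask >> i & 1)))
            if key < best_key:
                best_mask, best_key = mask, key
    return Configuration([candidates[i] for i in range(n) if best_mask >> i & 1])


def greedy_minimize(rects: list[Rectangle], energies: np.ndarray) -> Configuration:
    """Greedy baseline: accept candidates by ascending data term while
    negative and non-overlapping."""
    order = np.argsort(energies, kind="stable")
    chosen: list[Rectangle] = []
    for i in order:
        if energies[i] >= 0:
            break
        r = rects[i]
        if all(not overlaps(r, c) for c in chosen):
            chosen.append(r)
    return Configuration(chosen)


def _local_polish(rects, energies, selected: set[int], conflicts: dict[int, set[int]]) -> set[int]:
    """Deterministic 1-add / 1-for-k swap descent to a local minimum."""
    improved = True
    neg = [i for i in range(len(rects)) if energies[i] < 0]
    while improved:
        improved = False
        for i in neg:
            if i in selected:
                continue
            blockers = conflicts[i] & selected
            gain = energies[i] - sum(energies[j] for j in blockers)
            if gain < -1e-12:
                selected -= blockers
                selected.add(i)
                improved = True
        for i in list(selected):
            if energies[i] > 1e-12:
                selected.discard(i)
                improved = True
    return selected


def minimize_energy(
    image: np.ndarray,
    params: MPPParams,
    roi_mask: np.ndarray | None = None,
    candidates: list[Rectangle] | None = None,
) -> Configuration:
    """Minimize the configuration energy by multiple births and deaths.

    Each iteration proposes a Poisson number of births from the candidate
    pool, then sweeps objects worst-first with a temperature-dependent death
    probability; overlaps are resolved by killing the worse member of each
    clashing pair (hard-core prior).  The best admissible configuration seen
    is polished by deterministic local search and compared against the
    greedy baseline; the better of the two is returned, so the result is
    never worse than greedy.
    """
    arr = _as_image(image)
    if candidates is None:
        rects, energies = candidate_data_terms(arr, params, roi_mask)
    else:
        rects = list(candidates)
        energies = np.array([rectangle_energy(arr, r, params) for r in rects])
        if roi_mask is not None:
            keep = [k for k, r in enumerate(rects) if roi_mask[r.row, r.col]]
            rects = [rects[k] for k in keep]
            energies = energies[keep]
    neg = np.nonzero(energies < 0)[0]
    rects = [rects[i] for i in neg]
    energies = energies[neg]
    if len(rects) == 0:
        return Configuration([])
    if len(rects) > params.max_candidates:
        keep = np.argsort(energies, kind="stable")[: params.max_candidates]
        keep.sort()
        rects = [rects[i] for i in keep]
        energies = energies[keep]
    n = len(rects)
    conflicts: dict[int, set[int]] = {i: set() for i in range(n)}
    # sweep-line-free pairwise pass; pools are sparse after the D<0 filter
    for i in range(n):
        ri = rects[i]
        for j in range(i + 1, n):
            if overlaps(ri, rects[j]):
                conflicts[i].add(j)
                conflicts[j].add(i)

    rng = np.random.default_rng(params.seed)
    opt = params.optimizer
    current: set[int] = set()
    best: set[int] = set()
    best_e = 0.0
    t = opt.t0
    stale = 0
    for _ in range(opt.n_iter):
        # births
        n_birth = rng.poisson(opt.birth_rate)
        if n_birth > 0:
            born = rng.integers(0, n, size=n_birth)
            current |= set(int(b) for b in born)
        # resolve overlaps: keep the better (lower-energy) member of each clash
        order = sorted(current, key=lambda i: (energies[i], rects[i]))
        alive: set[int] = set()
        for i in order:
            if not (conflicts[i] & alive):
                alive.add(i)
        # deaths: worst first, probability from energy gain at temperature t
        for i in sorted(alive, key=lambda i: -energies[i]):
            d = energies[i]
            p = 1.0 / (1.0 + math.exp(min(-d / max(t, 1e-9), 50.0)))
            if rng.random() < p:
                alive.discard(i)
        current = alive
        e = float(sum(energies[i] for i in current))
        if e < best_e - 1e-12:
            best_e = e
            best = set(current)
            stale = 0
        else:
            stale += 1
        t *= opt.cooling
        if stale >= opt.convergence_window and t < 1e-3:
            break
    best = _local_polish(rects, energies, best, conflicts)
    best_e = float(sum(energies[i] for i in best))
    greedy = greedy_minimize(rects, energies)
    greedy_idx = {rects.index(r) for r in greedy}
    greedy_e = float(sum(energies[i] for i in greedy_idx))
    if greedy_e < best_e - 1e-12:
        best = greedy_idx
    chosen = sorted(best, key=lambda i: rects[i])
    return Configuration([rects[i] for i in chosen])


def rasterize(config: Configuration, shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of the configuration's footprints."""
    mask = np.zeros(shape, dtype=bool)
    for r in config:
        mask[r.row0 : r.row1, r.col0 : r.col1] = True
    return mask


def detect_slice(
    image: np.ndarray,
    params: MPPParams,
    roi_mask: np.ndarray | None = None,
) -> tuple[Configuration, np.ndarray]:
    """Detect particles in one B-scan, optionally restricted to a region of
    interest (e.g. the vitreous above the retina surface).  Returns the
    fitted configuration and its rasterized binary mask."""
    arr = _as_image(image)
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != arr.shape:
            raise ValueError("roi_mask shape does not match image")
        if not roi_mask.any():
            return Configuration([]), np.zeros(arr.shape, dtype=bool)
    config = minimize_energy(arr, params, roi_mask=roi_mask)
    return config, rasterize(config, arr.shape)
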