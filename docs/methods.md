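# Methods

This note documents the models, parameter choices and numerical conventions
behind `octquant`, and what the phantom-based tests do and do not establish.

## Marked-point-process detector

A B-scan is an H×W grid of grayscale values in [0, 1]. Particles are
modelled as "vertical" axis-aligned rectangles {row, col, w, l}: `l` is the
vertical (row) extent, `w` the horizontal one, coordinates are 0-based and
footprints are half-open blocks `[row−l//2, row−l//2+l) × [col−w//2,
col−w//2+w)`. A configuration is admissible when footprints are pairwise
disjoint; rectangles that share only an edge do not overlap under the
half-open convention. The ∞ overlap penalty is a hard constraint — the
sampler never forms inadmissible configurations and the energy of an
inadmissible configuration is an error, not a float.

**Contrast statistic.** x = (μ_in − μ_crown)² / (σ²_in + σ²_crown), with
population variances (divide by count). The crown is the ring of pixels
within `crown_width` (default 2 px, Chebyshev distance) of the footprint,
excluding it, clipped at image borders. If both variances vanish, x is 0
for equal means and +∞ ("perfect contrast") otherwise; +∞ maps to the
best value of whichever quality form is active. The statistic is sign-blind
(the mean difference is squared), so a `bright_only` gate (default on)
assigns the worst quality to rectangles not brighter than their crown —
the detector targets bright vitreous particles, not dark holes.

**Quality function.** Two forms are provided. The *printed* form,
Q(x) = 1 − x/x₀ for x < x₀ and exp(−(x−x₀)/x₀) otherwise, is discontinuous
at x₀ (left limit 0, right value 1) and everywhere positive — under a pure
sum-of-data-terms energy the empty configuration would always win, so this
form is kept only for reference. The *corrected* default subtracts 1 in the
second branch: continuous at x₀ (value 0), range (−1, 1], strictly
decreasing, negative exactly when x > x₀. x₀ is the contrast threshold
separating "background fluctuation" from "object".

**Optimization.** Candidates are all rectangles on an integer center grid
(stride 1 by default) with w, l in [wmin, wmax] × [lmin, lmax]; their data
terms are computed in one vectorized pass per (w, l) via summed-area tables,
and only negative-energy candidates enter the pool (positive terms can
never lower the energy). The sampler is multiple births and deaths: each
iteration proposes a Poisson number of births from the pool, resolves
overlaps by keeping the better member of each clash, then sweeps objects
worst-first with death probability 1/(1 + exp(−D/T)) at temperature T
(geometric cooling, default T₀ = 1, factor 0.97, 200 iterations). The best
configuration seen is finished by a deterministic local search (1-add and
1-for-k swap descent) and compared against a greedy baseline (accept by
ascending data term while negative and disjoint); the better of the two is
returned, so the result is provably never worse than greedy. On pools small
enough for exhaustive subset enumeration the sampler reaches the global
minimum in effectively every seeded trial — the brute-force enumerator is
retained as the oracle for that contract.

**Defaults** (frozen once against phantom data, mirroring the practice of
tuning on a few images and reusing the values): x₀ = 6, w, l ∈ [3, 7],
crown width 2, stride 1. The minimum mark size of 3 matters: variance
estimates over 2×2 interiors are so noisy that background speckle
occasionally reaches x > x₀, producing false positives; at 3×3 and above
the background maximum on phantoms stays near x ≈ 4 while planted particles
score x ≈ 35–85.

## Retina surface

Pipeline per slice: (1) optional particle suppression — masked pixels
replaced by the median of unmasked neighbours in a 9×9 window; (2) per-band
normalization — vertical bands of 10 columns independently rescaled to
[0, 1] by 1st/99th-percentile min–max, defeating lateral gain variation so
one global threshold works; (3) binarization at 0.5, removal of 2-D
components below 200 px (8-connectivity), Gaussian smoothing of the mask
(σ = 3 px) re-thresholded at 0.5; (4) largest connected component kept and
closed with a radius-2 disk; (5) the surface is the topmost mask row per
column (the vitreous lies above the retina), with empty columns linearly
interpolated. All thresholds are exposed: real OCT stacks vary enough in
grey level that fixed presets need occasional adjustment, which is the
known limitation of any classical thresholding pipeline. On phantoms at
default speckle the surface MAE is ≈ 0.7 px (contract: ≤ 2 px).

## 3-D reconstruction and distances

Per-slice masks are stacked in order; 3-D connected components use
26-connectivity by default (6 selectable) with scipy's raster-order
labeling. Filtering removes labels spanning fewer than `min_slices = 2`
slices — a real particle, given the longitudinal resolution, must appear
in several adjacent B-scans, so single-slice detections are treated as
speckle — and optionally labels with no voxel inside any provided
per-slice bounding box (half-open y0, x0, y1, x1; boxes may come from any
external detector). Centroids are arithmetic voxel means scaled by the
voxel spacing. Particle height above the retina is the exact Euclidean
distance transform of the negated retina mask sampled at the centroid by
trilinear interpolation (nearest-voxel selectable); the transform route is
orientation-free, unlike a perpendicular projection onto the surface.

## Spatial statistics

K̂(r) = |W|/(n(n−1)) Σᵢ Σ_{j≠i} 1{dᵢⱼ ≤ r} / c(xᵢ, dᵢⱼ) inside a spherical
window (center, radius R), |W| = 4πR³/3. The isotropic edge correction
c is the fraction of the surface of the sphere of radius d centered at xᵢ
lying inside the window — for a spherical window the closed-form cap
fraction ½(1 + (R² − ρ² − d²)/(2ρd)) for ρ + d > R, else 1, clamped to
(0, 1] (it reaches exactly 0 only at the unattainable d = ρ + R). Pairs are
summed per ordered direction so each point's own correction applies.
Under CSR the corrected estimator is unbiased for 4πr³/3 (verified to
within Monte-Carlo error at n = 200, R = 70); the uncorrected estimator
(c ≡ 1) underestimates K by ≈ 30% at r = 40 in the same geometry.

Radii default to 64 even steps over (0, 70] px, the range over which the
particle analysis is reported. The window center defaults to the pattern
centroid (overridable); points outside the window are dropped with a
warning rather than an error, since real centroids need not fit any fixed
sphere. Envelopes are pointwise (α/2, 1−α/2) order-statistic quantiles
('lower'/'higher' convention, so 20 simulations at α = 0.05 give the
simulation min/max) over seeded CSR simulations. The clustering verdict is
deliberately conservative: true only when K̂ exceeds the upper envelope at
*every* tabulated radius in the requested range.

Projected density heatmaps place a unit-mass Gaussian kernel (default
bandwidth 5 px) at each point projected onto the xy / xz / yz plane, on a
grid padded by 4 bandwidths so the grid mass equals n to well within 1%.

## Phantom generator

The phantom emulates the geometry that drives every stage: a bright retina
band (intensity 0.70) of thickness 48 px under a smooth single-valued
surface (baseline 0.62·H plus a sine of amplitude 8 px, a quadratic bow of
6 px and a gentle per-slice shift), a dark vitreous (0.10), and bright
axis-aligned box particles (0.90, widths/lengths 3–6 px, spanning 2–4
contiguous slices) placed strictly above the surface with a 6-px clearance
and non-overlap enforced by rejection sampling (retry cap 1000, explicit
error on failure). Placement is uniform (CSR) or Thomas-clustered (parents
uniform, Gaussian offspring). Speckle is multiplicative gamma noise with
mean 1 and shape 30 (≈ 18% intensity CV), applied after geometry; the
result is clipped to [0, 1]. All randomness flows from one seeded
generator, so phantoms are bit-reproducible.

What the phantom does *not* model: the A-scan point-spread function,
attenuation and shadowing below bright structures, multi-layer retinal
texture, motion artefacts, or intensity statistics of any particular OCT
device (no quantitative noise/contrast figures were available to match).
Passing phantom tests therefore demonstrates correctness of the
algorithms under controlled geometry and speckle, not clinical performance
on device data, where threshold re-tuning is expected.

The separate point-pattern simulators (CSR in a ball by radial inversion,
Thomas with Poisson offspring counts) are the null and positive controls
for the clustering analysis and are seeded independently of the phantom.

## Pipeline and the clustering null

`run_pipeline` chains: per-slice surface extraction → detection restricted
to the vitreous strictly above the surface (2-px clearance) → stacking →
3-D labeling → single-slice filtering → centroids → distances → Ripley
analysis, with per-slice detector seeds derived from the base seed and all
text outputs byte-stable.

The study window follows the convention of using the image width as the
sphere radius with the pattern centroid as center. For the *verdict*,
however, a whole-sphere CSR null is misleading on B-scan geometry: the
admissible region for particles is a thin slab above the retina, so even
uniformly placed particles look "clustered" relative to points scattered
through the full sphere — the comparison measures confinement, not
aggregation. The pipeline therefore defaults to a `vitreous_csr` null:
envelope simulations resample n points uniformly from the observed
vitreous voxels, i.e. the same support as the data, so the verdict isolates
genuine aggregation. The whole-window null remains selectable
(`RipleyConfig.null_model = "window_csr"`). The default verdict range
(15, 45) px starts above the generator's hard-core scale — planted
particles are a few pixels wide with enforced gaps, so centroid pairs
closer than ~12 px cannot occur and K̂ is structurally 0 there; real
particles have finite size with the same consequence. With these defaults,
clustered (Thomas) phantoms are flagged and uniform ones are not, in 10/10
seeded runs each.

## Evaluation conventions

Detection against point annotations: each predicted component containing
at least one ground-truth point is one true positive; additional points in
the same component count as false negatives (merged detections are
penalized, consistent with discouraging blob merging); empty components
are false positives; points in no component are false negatives. Metrics
with zero denominators are reported as explicitly undefined, never as 0.
Centroid-to-centroid scoring (used against planted ground truth) matches
greedily by ascending distance, one-to-one, within a stated tolerance.

## Problem sizes

Phantoms used throughout the tests and the acceptance script are 256×256
B-scans in stacks of 8–12 slices with 12–40 particles; point-process
experiments use n ≈ 200 points in a radius-70 sphere with 40–100 envelope
simulations; optimizer oracle instances are 64×64 with ≤ 12 candidates.
These sizes give stable statistics for every contract while keeping the
full suite and the acceptance script each under a minute of single-CPU
time.
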