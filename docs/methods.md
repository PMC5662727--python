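# Methods

## The model

A labelled soma is modelled as a solid intensity ellipsoid with semi-axes
a ≥ b ≥ c on the scale of 3–8 μm, imaged on an anisotropic voxel grid
(defaults 1 × 1 × 2 μm; 0.32 × 0.32 × 2 μm is equally supported). The
localization problem is treated as sparse recovery: given the binary
foreground f extracted from the stack, find a minimal set of balls whose
superposition explains it,

    min_{w ≥ 0}  ½‖Σᵢ wᵢ φᵢ − f‖² + λ‖w‖₁ ,

with one atom φ_{c,r} per (candidate centre c, radius r). Because neuronal
positions are sparse in 3D, the L1 penalty concentrates weight on one ball
per soma and assigns negligible weight to thin neurite fragments, which no
ball of radius ≥ 2 μm can represent efficiently. The fit target is the
binary foreground rather than raw intensity: it makes atom normalization
scale-free and the procedure invariant to overall brightness.

## Pipeline stages and parameters

**Foreground extraction.** Otsu thresholding on the full-stack 256-bin
histogram (a fixed threshold is available for reproducibility studies),
then 6-connected erosion (default 1 repetition, voxel-space, i.e. not
isotropic in μm on anisotropic grids — deliberate and documented), then
removal of 26-connected components below 20 voxels. Erosion disconnects
thin bridges between touching somas; the component-size floor removes noise
specks (a 5-μm soma occupies ≈ 260 voxels at 1 × 1 × 2 μm, far above the
floor).

**Candidate seeding.** Local maxima of the Euclidean distance transform
computed with physical sampling (μm), merged within 2 μm to their centroid.
Every foreground component retains at least one candidate (its interior
distance maximum).

**L1 fit.** Radius set {2, 3, 4, 5, 6, 8, 10} μm spanning the expected soma
scale; atoms are unit-normalized ball indicators on the voxel grid. Solver:
non-negative ISTA (proximal gradient) with step 1/L, where L is the largest
absolute row sum of the atom Gram matrix (an upper bound on its spectral
radius); stopping at 1e−4 relative objective change or 500 iterations. The
objective is convex, so the iteration is provably convergent and the
objective non-increasing (asserted in tests). λ defaults to 0.1·max|φᵀf|,
making it scale-relative; the acceptance threshold on fitted weights is
0.2. Per candidate only the largest-weight radius survives (one ball per
soma — mixtures would double-count), followed by greedy weight-descending
non-maximum suppression at 8 μm (ties broken by lexicographic centre
order, so results are order-independent and deterministic; there is no RNG
anywhere in the fit).

**Block-wise processing.** Cores are half-open tiles (default 512³ μm)
padded by a halo (default 24 μm ≈ two maximal soma diameters); a block
keeps only detections whose centre lies in its core, so a soma straddling a
seam is counted exactly once by the block that owns its centre. Per-block
Otsu thresholds can differ from the global one; on phantoms with adequate
halo the block-wise and whole-volume runs match 1:1 within 3 μm (tested).
Blocks with no intensity contrast at all are treated as empty rather than
as an error.

**Planar-counting emulation.** The z-axis is split into consecutive slabs
(default 50 μm), each maximum-intensity-projected and processed by the 2D
analogue of the same pipeline (2D Otsu, 4-connected erosion, 2D distance
transform, the same merge distances) — deliberately reusing the 3D
parameters so that any count difference isolates the dimensionality effect,
not detector tuning. Counts are summed over slabs.

**Morphometry.** Somas are segmented by region growing from the detection
centre: voxels ≥ 0.5 × the 3×3×3 centre-neighbourhood mean, 26-connected
to the centre, within a hard 15-μm ball. Longest/shortest radii are
half-extents of the voxel cloud projected on the principal axes of its
coordinate covariance (the definition is rotation-invariant and suits
ovoid/spindle profiles; Feret diameters or fitted-ellipsoid axes were the
open alternatives). The average radius is the arithmetic mean of the three
half-extents. Surface area counts exposed voxel faces, which systematically
overestimates smooth surfaces (≤ 1.5× for spheres at default pitch,
tested); it is used for relative comparisons between somas measured on the
same grid, not as an unbiased estimate. Volume is voxel count × voxel
volume. Masks smaller than 4 voxels are rejected as degenerate.

**Evaluation.** Detection-truth matching is an optimal one-to-one
assignment (Hungarian algorithm) restricted to pairs within 5 μm (≈ one
soma radius; the matching radius is a free parameter). Recall R = B/B1 and
precision P = B/B2 are computed in exact rational arithmetic; note that a
matched count of 57 out of 59 detections is 96.61%, which rounds to 96.6%,
not 96.7% — the package reports the exact ratio. The Wilcoxon signed-rank
test drops zero differences, midranks ties, and uses W = min(W⁺, W⁻). The
default mode is the normal approximation without continuity correction,
z = (W − n(n+1)/4)/√(n(n+1)(2n+1)/24), p = 2Φ(z), matching legacy
statistical-package behaviour: at n = 5 with all differences positive it
gives p = 0.043, whereas the exact distribution cannot go below
2/2⁵ = 0.0625. The exact mode enumerates all 2ⁿ sign patterns (n ≤ 20).
The two modes agree on average within 0.02 for n ≥ 15, but individual
draws can differ by about half the point mass of the observed W (the
price of omitting the continuity correction). Group comparisons use
classical one-way ANOVA.

## What the phantom generator does and does not emulate

It emulates: anisotropic voxel grids, variable soma density, per-soma size
jitter and random orientation, disjoint-but-z-aligned soma pairs (centre
gap in [2c + 2, 2c + 6] μm along z — disjoint in 3D, overlapping in
projection), neurite-like random-walk tubes at intermediate intensity,
uniform background and additive Gaussian noise, with partial-volume
anti-aliasing at ellipsoid boundaries (2×2×2 subvoxel sampling) so that
coarse z-sampling does not produce blocky shells. Placement is rejection
sampling with a minimum centre separation (cap 10,000·n attempts; failure
reports the achieved count).

It does not emulate: optical point-spread blur, Poisson photon statistics,
photobleaching, mosaic stitching seams, illumination gradients, or
realistic neurite branching. Consequently, passing tests demonstrate the
correctness and internal consistency of the algorithms — exact recovery at
moderate density, the projection undercount, block-seam handling, density
bookkeeping — not detection performance on real tissue, where contrast and
clutter are harsher. Default intensities (background 10, soma 200, noise
σ = 5) give a contrast amply above threshold; soma semi-axes default to
(6, 5, 4) μm ± 20%, chosen from the qualitative 3–8 μm soma-radius range of
the labelled interneurons this pipeline targets — uncalibrated, since no
quantitative size statistics are available.

## Problem sizes

Tests and examples run on 100³–200·100² μm volumes (≈ 0.5–1 M voxels); the
localization-accuracy check uses a full 512³ μm cube at 1 × 1 × 2 μm
(67 M voxels, ≈ 200 somas at 1,500 somas/mm³, processed in 256³ μm blocks
in about two minutes on one core). The density-recovery study uses a
two-region atlas seeded at 40,000 and 10,000 cells/mm³ with recovery judged
at 3√N counting tolerance. The headline Wilcoxon statistic is recomputed
from five 100³ μm cubes with 1–5 axial pairs each (`scripts/acceptance.py`).

## Known limitations

- Detection centres are candidate positions (distance-transform maxima),
  not sub-voxel refined; centre error is bounded by the merge radius and is
  ≤ 1 lateral voxel on clean spheres.
- The radius estimate is quantized to the configured radius set.
- Surface area inherits the exposed-face overestimate above.
- Otsu assumes a bimodal global histogram; extremely sparse foregrounds in
  a noisy block can inflate the threshold (mitigated by the component-size
  floor and by block-wise processing).
- At densities approaching the minimum-separation packing limit, rejection
  sampling fails rather than degrading silently.
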