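# somascope

Stereological (full-3D) soma localization, counting and morphometry for
fluorescence image stacks — and a quantitative demonstration of why planar
cell counting in z-projections undercounts.

Counting labelled neurons in projected tissue sections is biased: cell
bodies that are disjoint in 3D but aligned along the optical axis merge in a
maximum-intensity projection and are counted once. `somascope` implements
the alternative — locate every soma in the full volume — as a desk-scale
pipeline:

1. **Phantom generation** — synthetic anisotropic stacks (e.g. 1 × 1 × 2 μm
   voxels) of ellipsoidal somas with known ground truth, optional
   disjoint-but-z-aligned soma pairs, neurite clutter and Gaussian noise.
2. **Foreground extraction** — global Otsu (or fixed) thresholding,
   6-connected erosion, small-component removal.
3. **Sparse L1 localization** — candidate centres from the anisotropy-aware
   Euclidean distance transform, then a non-negative L1-penalized fit

   $$\min_{w \ge 0}\ \tfrac12 \lVert \textstyle\sum_i w_i\,\varphi_i - f \rVert_2^2 + \lambda \lVert w \rVert_1$$

   where each atom $\varphi_{c,r}$ is the unit-normalized indicator of a
   ball of radius $r \in \{2,3,4,5,6,8,10\}$ μm at candidate $c$, and $f$ is
   the binary foreground. Sparsity keeps one ball per soma and ignores
   neurites. Large volumes are processed block-wise (default 512³ μm cores
   with a halo; half-open core ownership removes seam duplicates).
4. **Morphometry** — per-soma region growing, then longest/shortest/average
   radii (principal-axis half-extents), their ratio, surface area, volume,
   mean brightness.
5. **Quantification & evaluation** — per-region counts and densities
   (cells/mm³) against a label volume; recall $R = B/B_1$ and precision
   $P = B/B_2$ via optimal (Hungarian) matching; Wilcoxon signed-rank test
   (exact enumeration or normal approximation) for 3D-vs-planar counts;
   one-way ANOVA for group comparisons. Somas export to soma-only SWC
   (`id 1 x y z radius -1`) and CSV.

## Worked example

```bash
python examples/03_stereology_vs_planar.py
```

```
cube 1: 3D count  10   z-projection count   9
cube 2: 3D count  12   z-projection count  10
cube 3: 3D count  14   z-projection count  13
cube 4: 3D count  16   z-projection count  13
cube 5: 3D count  18   z-projection count  13
Wilcoxon signed-rank: W = 0.0, two-sided p = 0.043
```

Five 100³ μm data cubes contain increasing numbers of z-aligned soma pairs.
The 3D count (sparse L1 localization, which here recovers the generator's
ground truth exactly) exceeds the planar count in every cube because pairs
inside one 50-μm slab collapse to a single blob in the projection. With all
five differences positive, the signed-rank statistic is W = 0 and the
two-sided normal-approximation p-value is 0.043 — planar counting
undercounts significantly.

The other examples cover phantom generation (`01`), localization accuracy
(`02`: recall = precision = 1.000 on a 15-soma phantom with neurite
clutter), morphometry (`04`: recovered radii ≈ the generator's 6/5/4 μm
semi-axes) and per-region densities (`05`: seeded 40,000 and 10,000
cells/mm³ recovered exactly).

A thin CLI mirrors the library: `somascope phantom|locate|evaluate|wilcoxon|run`.

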