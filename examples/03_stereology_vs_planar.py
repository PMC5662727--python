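"""Why 3D (stereological) counting beats planar z-projection counting.

Somas that are disjoint in 3D but aligned along z merge in a 50-μm slab
maximum-intensity projection and are counted once. Five data cubes with
increasing numbers of axial pairs are counted both ways, and the paired
difference is tested with the Wilcoxon signed-rank test.
"""

import numpy as np

import somascope as sc

pairs = []
for i, n_pairs in enumerate([1, 2, 3, 4, 5]):
    spec = sc.PhantomSpec(
        shape_um=(100.0, 100.0, 100.0),
        n_somas=8 + 2 * n_pairs,
        axial_pair_fraction=2 * n_pairs / (8 + 2 * n_pairs),
        noise_sigma=5.0,
        seed=50 + i,
    )
    stack, _ = sc.generate_phantom(spec)
    n3 = sc.count_cells_3d(sc.locate_somas(stack))
    n2 = sc.count_cells_2d_projection(stack, slab_thickness_um=50.0)
    pairs.append((n3, n2))
    print(f"cube {i + 1}: 3D count {n3:3d}   z-projection count {n2:3d}")

W, p = sc.wilcoxon_signed_rank(np.array(pairs, float), mode="normal_approx")
print(f"Wilcoxon signed-rank: W = {W}, two-sided p = {p:.3f}")
# p < 0.05 ⇒ planar counting systematically undercounts: every z-aligned
# pair inside one slab collapses to a single blob in the projection.
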