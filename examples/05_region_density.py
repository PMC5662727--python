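"""Per-region cell counts and densities (cells/mm³).

A two-region synthetic atlas is populated at 40,000 and 10,000 somas/mm³;
after localization, each detection is assigned the region of the voxel
containing its centre, and density = count / region volume.
"""

import somascope as sc

atlas, dens = sc.generate_region_atlas(
    (200.0, 100.0, 100.0), (1.0, 1.0, 2.0), n_regions=2,
    densities_per_mm3=[40_000.0, 10_000.0],
)
centres, true_counts = sc.sample_atlas_centres(atlas, dens, min_separation_um=12.0, seed=5)
spec = sc.PhantomSpec(
    shape_um=(200.0, 100.0, 100.0),
    voxel_size_um=(1.0, 1.0, 2.0),
    centres_um=centres,
    n_somas=None,
    radius_dist=((4.5, 4.0, 3.5), 0.1),
    noise_sigma=5.0,
    seed=5,
)
stack, _ = sc.generate_phantom(spec)
detections = sc.locate_somas_blockwise(stack, block_size_um=(100.0, 100.0, 100.0), halo_um=20.0)

assignment = sc.assign_regions(detections, atlas)
for s in sc.region_stats(assignment, atlas):
    if s.label > 0:
        print(
            f"{s.region}: {s.cell_count} cells in {s.volume_mm3:.4f} mm3 "
            f"-> {s.density_cells_per_mm3:,.0f} cells/mm3 "
            f"(true count {true_counts.get(s.label, 0)})"
        )
# Recovered densities should match the seeded 40k/10k within counting noise.
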