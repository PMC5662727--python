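"""L1 soma localization, candidate seeding, 3D vs planar counting."""

import numpy as np
import pytest

import somascope as sc
from somascope.localize import build_ball_basis, ista_solve
from somascope.stack import BinaryMask3D


class TestSeedCandidates:
    def test_empty_mask_gives_no_candidates(self):
        mask = BinaryMask3D(np.zeros((5, 5, 5), bool), (1, 1, 2))
        assert sc.seed_candidates(mask) == []

    def test_single_sphere_yields_one_central_candidate(self, sphere_phantom):
        stack, truth = sphere_phantom
        mask = sc.extract_foreground(stack, erosion_reps=0, min_component_voxels=20)
        cands = sc.seed_candidates(mask)
        assert len(cands) >= 1
        true_c = np.asarray(truth.somas[0].centre_um)
        d = min(np.linalg.norm(np.asarray(c) - true_c) for c in cands)
        assert d <= 1.0 + 1e-9  # within one lateral voxel

    def test_fused_spheres_give_one_candidate_per_lobe(self):
        # two spheres r=4 μm whose surfaces are bridged by a thin neck
        nz, ny, nx = 24, 24, 40
        m = np.zeros((nz, ny, nx), bool)
        zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)
        for cx in (14.0, 26.0):
            m |= (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - cx) ** 2 <= 4.0**2
        m[11:14, 11:14, 14:27] = True  # 2-μm-scale neck
        cands = sc.seed_candidates(BinaryMask3D(m, (1, 1, 1)))
        assert len(cands) >= 2
        xs = sorted(c[0] for c in cands)
        assert xs[0] < 20 < xs[-1]  # one candidate in each lobe


class TestIsta:
    def test_objective_non_increasing_every_iteration(self, small_phantom):
        stack, _ = small_phantom
        mask = sc.extract_foreground(stack)
        cands = sc.seed_candidates(mask)
        phi = build_ball_basis(
            cands, sc.L1Config(), mask.voxels.shape, mask.voxel_size_um
        )
        f = mask.voxels.ravel().astype(float)
        lam = 0.1 * float(np.abs(phi.T @ f).max())
        _, objs = ista_solve(phi, f, lam, max_iter=60)
        assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))

    def test_huge_lambda_kills_all_weights(self, small_phantom):
        stack, _ = small_phantom
        mask = sc.extract_foreground(stack)
        cands = sc.seed_candidates(mask)
        dets = sc.fit_l1_model(stack, mask, cands, sc.L1Config(lambda_=1e9))
        assert dets == []


class TestFitL1Model:
    def test_single_sphere_recovered_with_correct_radius(self, sphere_phantom):
        stack, truth = sphere_phantom
        mask = sc.extract_foreground(stack, erosion_reps=0)
        cands = sc.seed_candidates(mask)
        dets = sc.fit_l1_model(stack, mask, cands)
        assert len(dets) == 1
        d = dets[0]
        err = np.linalg.norm(np.asarray(d.centre_um) - truth.somas[0].centre_um)
        assert err <= 1.0 + 1e-9
        assert d.radius_um in (4.0, 5.0, 6.0)

    def test_two_disjoint_z_aligned_spheres_both_found(self):
        spec = sc.PhantomSpec(
            shape_um=(40.0, 40.0, 60.0),
            centres_um=[(20.0, 20.0, 24.0), (20.0, 20.0, 36.0)],
            n_somas=None,
            radius_dist=((4.0, 4.0, 4.0), 0.0),
            noise_sigma=0.0,
            seed=0,
        )
        stack, _ = sc.generate_phantom(spec)
        dets = sc.locate_somas(stack, sc.PreprocessConfig(erosion_reps=0))
        assert len(dets) == 2

    def test_empty_candidates_give_empty_result(self, small_phantom):
        stack, _ = small_phantom
        mask = sc.extract_foreground(stack)
        assert sc.fit_l1_model(stack, mask, []) == []

    def test_detection_count_non_increasing_in_lambda(self, small_phantom):
        stack, _ = small_phantom
        mask = sc.extract_foreground(stack)
        cands = sc.seed_candidates(mask)
        counts = []
        base = 0.1 * float(
            np.abs(
                build_ball_basis(
                    cands, sc.L1Config(), mask.voxels.shape, mask.voxel_size_um
                ).T
                @ mask.voxels.ravel().astype(float)
            ).max()
        )
        for mult in (0.5, 1.0, 4.0, 16.0, 64.0):
            dets = sc.fit_l1_model(
                stack, mask, cands, sc.L1Config(lambda_=base * mult)
            )
            counts.append(len(dets))
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_given_fixed_inputs(self, small_phantom):
        stack, _ = small_phantom
        a = sc.locate_somas(stack)
        b = sc.locate_somas(stack)
        assert [(d.centre_um, d.radius_um, d.weight) for d in a] == [
            (d.centre_um, d.radius_um, d.weight) for d in b
        ]


class TestBlockwise:
    def test_single_block_layout_equals_whole_volume(self, small_phantom):
        stack, _ = small_phantom
        whole = sc.locate_somas(stack)
        blocky = sc.locate_somas_blockwise(
            stack, block_size_um=(512, 512, 512), halo_um=0
        )
        assert [(d.centre_um, d.radius_um) for d in whole] == [
            (d.centre_um, d.radius_um) for d in blocky
        ]

    def test_split_volume_matches_whole_run_one_to_one(self):
        spec = sc.PhantomSpec(shape_um=(160, 100, 100), n_somas=20, seed=7)
        stack, _ = sc.generate_phantom(spec)
        whole = sc.locate_somas(stack)
        blocky = sc.locate_somas_blockwise(
            stack, block_size_um=(80, 100, 100), halo_um=24
        )
        assert len(whole) == len(blocky)
        pairs = sc.match_detections(
            np.array([d.centre_um for d in blocky]),
            np.array([d.centre_um for d in whole]),
            3.0,
        )
        assert len(pairs) == len(whole)

    def test_soma_on_seam_counted_once(self):
        spec = sc.PhantomSpec(
            shape_um=(80.0, 40.0, 40.0),
            centres_um=[(40.0, 20.0, 20.0)],  # exactly on the x seam
            n_somas=None,
            radius_dist=((5.0, 5.0, 5.0), 0.0),
            noise_sigma=0.0,
            seed=0,
        )
        stack, _ = sc.generate_phantom(spec)
        dets = sc.locate_somas_blockwise(
            stack, block_size_um=(40, 40, 40), halo_um=16
        )
        assert len(dets) == 1


class TestCounting:
    def test_count_3d_is_detection_count(self, small_detections):
        assert sc.count_cells_3d([]) == 0
        assert sc.count_cells_3d(small_detections) == len(small_detections)

    def test_well_separated_phantom_counted_exactly(
        self, small_phantom, small_detections
    ):
        _, truth = small_phantom
        assert sc.count_cells_3d(small_detections) == len(truth)

    def test_projection_count_empty_stack(self):
        stack = sc.ImageStack3D(np.zeros((25, 40, 40)), (1, 1, 2))
        assert sc.count_cells_2d_projection(stack, 50.0) == 0

    def test_z_aligned_pair_merges_in_projection(self):
        spec = sc.PhantomSpec(
            shape_um=(40.0, 40.0, 48.0),
            centres_um=[(20.0, 20.0, 18.0), (20.0, 20.0, 30.0)],
            n_somas=None,
            radius_dist=((4.0, 4.0, 4.0), 0.0),
            noise_sigma=0.0,
            seed=0,
        )
        stack, _ = sc.generate_phantom(spec)
        dets = sc.locate_somas(stack, sc.PreprocessConfig(erosion_reps=0))
        n2 = sc.count_cells_2d_projection(
            stack, 50.0, sc.PreprocessConfig(erosion_reps=0)
        )
        assert sc.count_cells_3d(dets) == 2
        assert n2 == 1  # the pair overlaps in the slab projection

    def test_separated_somas_counted_in_projection(self, small_phantom):
        stack, truth = small_phantom
        n2 = sc.count_cells_2d_projection(stack, 50.0)
        # lateral collisions across a 50 μm slab may merge a few; most remain
        assert n2 >= 0.7 * len(truth)

    def test_sub_z_step_slab_raises(self, small_phantom):
        stack, _ = small_phantom
        with pytest.raises(ValueError):
            sc.count_cells_2d_projection(stack, 1.0)

    def test_phantom_with_axial_pairs_3d_exceeds_2d(self):
        spec = sc.PhantomSpec(
            shape_um=(100, 100, 100),
            n_somas=12,
            axial_pair_fraction=0.7,
            noise_sigma=5.0,
            seed=3,
        )
        stack, truth = sc.generate_phantom(spec)
        dets = sc.locate_somas(stack)
        assert sc.count_cells_3d(dets) > sc.count_cells_2d_projection(stack, 50.0)
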