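"""Matching, recall/precision, Wilcoxon signed-rank, ANOVA, brightness."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import somascope as sc


def _bruteforce_match(detected, truth, max_dist):
    """Oracle: enumerate all one-to-one assignments, maximise matches then
    minimise total distance."""
    nd, nt = len(detected), len(truth)
    best = (0, math.inf)
    k = min(nd, nt)
    for det_idx in itertools.permutations(range(nd), k):
        for tru_idx in itertools.combinations(range(nt), k):
            for tru_perm in itertools.permutations(tru_idx):
                pairs = [
                    (d, t)
                    for d, t in zip(det_idx, tru_perm)
                    if np.linalg.norm(detected[d] - truth[t]) <= max_dist
                ]
                total = sum(
                    np.linalg.norm(detected[d] - truth[t]) for d, t in pairs
                )
                cand = (len(pairs), total)
                if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                    best = cand
    return best


class TestMatching:
    def test_identical_point_sets_match_perfectly(self):
        pts = np.random.default_rng(0).uniform(0, 50, (8, 3))
        pairs = sc.match_detections(pts, pts, 5.0)
        assert len(pairs) == 8
        assert all(r == c for r, c in pairs)

    def test_far_detection_left_unmatched(self):
        truth = np.array([[0, 0, 0], [10, 0, 0]], float)
        det = np.array([[0.5, 0, 0], [10.5, 0, 0], [100, 100, 100]], float)
        pairs = sc.match_detections(det, truth, 5.0)
        assert len(pairs) == 2
        n_match, total = _bruteforce_match(det, truth, 5.0)
        assert n_match == 2

    def test_optimal_beats_greedy_on_crossed_pairs(self):
        # greedy pairs the closest first and strands the second detection
        truth = np.array([[0, 0, 0], [4, 0, 0]], float)
        det = np.array([[3, 0, 0], [4.5, 0, 0]], float)
        pairs = sc.match_detections(det, truth, 5.0)
        assert len(pairs) == 2  # optimal keeps both within threshold
        n_match, best_total = _bruteforce_match(det, truth, 5.0)
        total = sum(
            np.linalg.norm(det[r] - truth[c]) for r, c in pairs
        )
        assert n_match == 2
        assert total == pytest.approx(best_total)

    def test_matching_symmetric_under_swap(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 40, (6, 3))
        b = a + rng.normal(0, 1.0, a.shape)
        ab = sc.match_detections(a, b, 5.0)
        ba = sc.match_detections(b, a, 5.0)
        assert sorted((r, c) for r, c in ab) == sorted((c, r) for r, c in ba)


class TestRecallPrecision:
    def test_worked_example_57_of_59(self):
        res = sc.recall_precision(B1=57, B2=59, B=57)
        assert res.recall == 1.0
        assert res.precision == pytest.approx(57 / 59)
        assert round(res.precision, 4) == 0.9661

    def test_perfect_and_zero_cases(self):
        assert sc.recall_precision(10, 10, 10).recall == 1.0
        r = sc.recall_precision(5, 5, 0)
        assert r.recall == 0.0 and r.precision == 0.0

    def test_zero_reference_raises_not_nan(self):
        with pytest.raises(ValueError):
            sc.recall_precision(0, 5, 0)
        with pytest.raises(ValueError):
            sc.recall_precision(5, 0, 0)

    def test_inconsistent_matched_count_raises(self):
        with pytest.raises(ValueError):
            sc.recall_precision(5, 5, 6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 100), st.integers(1, 100), st.integers(1, 20))
    def test_scale_free(self, b1, b2, k):
        b = min(b1, b2)
        r1 = sc.recall_precision(b1, b2, b)
        r2 = sc.recall_precision(k * b1, k * b2, k * b)
        assert r1.recall == pytest.approx(r2.recall)
        assert r1.precision == pytest.approx(r2.precision)


def _wilcoxon_bruteforce_exact(diffs):
    """Independent oracle: 2ⁿ enumeration using scipy midranks."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    n = len(d)
    wp_obs = ranks[d > 0].sum()
    wm_obs = ranks[d < 0].sum()
    w_obs = min(wp_obs, wm_obs)
    hits = 0
    for bits in range(2**n):
        signs = np.array([1 if bits >> i & 1 else -1 for i in range(n)])
        wp = ranks[signs > 0].sum()
        if min(wp, ranks.sum() - wp) <= w_obs + 1e-12:
            hits += 1
    return w_obs, hits / 2**n


class TestWilcoxon:
    def test_five_uniform_positive_pairs_normal_approx(self):
        pairs = np.array([[59, 55], [48, 45], [73, 70], [35, 33], [62, 61]], float)
        W, p = sc.wilcoxon_signed_rank(pairs, mode="normal_approx")
        assert W == 0
        z = -7.5 / math.sqrt(13.75)
        assert p == pytest.approx(2 * stats.norm.cdf(z))
        assert round(p, 3) == 0.043

    def test_five_uniform_positive_pairs_exact(self):
        pairs = np.array([[59, 55], [48, 45], [73, 70], [35, 33], [62, 61]], float)
        W, p = sc.wilcoxon_signed_rank(pairs, mode="exact")
        assert W == 0
        assert p == pytest.approx(2 / 32)

    def test_symmetric_differences_give_p_near_one(self):
        pairs = np.array([[3, 1], [1, 3], [5, 2], [2, 5]], float)
        _, p = sc.wilcoxon_signed_rank(pairs, mode="normal_approx")
        assert p == pytest.approx(1.0)

    def test_all_zero_differences_raise(self):
        with pytest.raises(ValueError):
            sc.wilcoxon_signed_rank(np.array([[1.0, 1.0], [2.0, 2.0]]))

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_equals_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 9)
        diffs = rng.integers(-5, 6, n).astype(float)
        if not np.any(diffs != 0):
            diffs[0] = 1.0
        pairs = np.column_stack([diffs, np.zeros(n)])
        W, p = sc.wilcoxon_signed_rank(pairs, mode="exact")
        W_ref, p_ref = _wilcoxon_bruteforce_exact(diffs)
        assert W == pytest.approx(W_ref)
        assert p == pytest.approx(p_ref)

    @pytest.mark.parametrize("n", [15, 18, 20])
    def test_exact_and_normal_agree_on_average_for_moderate_n(self, n):
        # the approximation (no continuity correction) under-covers the
        # observed point's mass, so single draws can differ by ~half that
        # mass; on random data the mean discrepancy stays below 0.02
        rng = np.random.default_rng(12)
        gaps = []
        for _ in range(40):
            diffs = rng.normal(0.3, 1.0, n)
            diffs[diffs == 0] = 0.1
            pairs = np.column_stack([diffs, np.zeros_like(diffs)])
            _, p_e = sc.wilcoxon_signed_rank(pairs, mode="exact")
            _, p_n = sc.wilcoxon_signed_rank(pairs, mode="normal_approx")
            gaps.append(abs(p_e - p_n))
        assert np.mean(gaps) < 0.02

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(1.0, 2.0, 12)
        y = rng.normal(0.0, 2.0, 12)
        _, p = sc.wilcoxon_signed_rank(np.column_stack([x, y]), "normal_approx")
        ref = stats.wilcoxon(x, y, correction=False, method="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestAnova:
    def test_identical_groups_no_effect(self):
        g = np.array([1.0, 2.0, 3.0])
        f, p = sc.anova_oneway([g, g.copy()])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # SSB = 1.5 (df 1), SSW = 4 (df 4) → F = 1.5
        f, _ = sc.anova_oneway([np.array([1.0, 2, 3]), np.array([2.0, 3, 4])])
        assert f == pytest.approx(1.5)

    def test_well_separated_groups_tiny_p(self):
        rng = np.random.default_rng(0)
        a = 0.0 + rng.normal(0, 1e-3, 3)
        b = 10.0 + rng.normal(0, 1e-3, 3)
        _, p = sc.anova_oneway([a, b])
        assert p < 1e-6

    def test_degenerate_constant_groups_raise(self):
        with pytest.raises(ValueError):
            sc.anova_oneway([np.zeros(3), np.full(3, 10.0)])


class TestBrightnessCompare:
    def test_identical_intensity_phantoms_usually_not_significant(self):
        rng = np.random.default_rng(100)
        n_ok = 0
        reps = 20
        for _ in range(reps):
            groups = [rng.normal(200, 8, 30), rng.normal(200, 8, 30)]
            _, p = sc.brightness_compare(groups, n_sample=20, seed=int(rng.integers(1 << 30)))
            n_ok += p > 0.05
        assert n_ok >= 0.9 * reps

    def test_different_intensities_detected(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(100, 5, 30), rng.normal(200, 5, 30)]
        _, p = sc.brightness_compare(groups, n_sample=20, seed=0)
        assert p < 0.01

    def test_full_population_sample_mean_is_population_mean(self):
        vals = np.arange(20, dtype=float)
        means, _ = sc.brightness_compare([vals, vals + 1], n_sample=20, seed=0)
        assert means[0] == pytest.approx(vals.mean())

    def test_insufficient_somas_raise(self):
        with pytest.raises(ValueError):
            sc.brightness_compare([np.ones(5), np.ones(30)], n_sample=20, seed=0)
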