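"""Validation statistics for automated cell counting.

Detections are matched to ground truth one-to-one (Hungarian assignment on
the distance matrix, thresholded at a matching radius).  With B1 true somas,
B2 automatic detections and B matched pairs, recall R = B/B1 and precision
P = B/B2.  The stereology-vs-planar comparison uses the Wilcoxon signed-rank
test; the normal-approximation mode (no continuity correction) reproduces
legacy statistical-package behaviour, while the exact mode enumerates all 2ⁿ
sign patterns.  Group comparisons (morphology, brightness) use one-way ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment


@dataclass
class EvaluationResult:
    """Counts and derived recall/precision for one evaluation volume."""

    B1: int  # manual / true count
    B2: int  # automatic count
    B: int  # matched count
    recall: float
    precision: float
    match_dist_um: float | None = None


def match_detections(
    detected: np.ndarray,
    truth: np.ndarray,
    max_dist_um: float = 5.0,
) -> list[tuple[int, int]]:
    """Optimal one-to-one matching of detected to true centres.

    Solves the assignment problem minimizing total distance over pairs
    within ``max_dist_um`` (Hungarian algorithm; pairs beyond the radius are
    forbidden).  Returns (detected_index, truth_index) pairs.  Optimality
    matters: greedy matching can strand a point when two candidates cross
    within the threshold.
    """
    if max_dist_um <= 0:
        raise ValueError("max_dist_um must be > 0")
    detected = np.asarray(detected, dtype=float).reshape(-1, 3)
    truth = np.asarray(truth, dtype=float).reshape(-1, 3)
    if len(detected) == 0 or len(truth) == 0:
        return []
    d = np.linalg.norm(detected[:, None, :] - truth[None, :, :], axis=2)
    big = max_dist_um * (len(detected) + len(truth) + 1) * 10.0
    cost = np.where(d <= max_dist_um, d, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if d[r, c] <= max_dist_um]


def recall_precision(B1: int, B2: int, B: int, match_dist_um: float | None = None) -> EvaluationResult:
    """R = B/B1 and P = B/B2, computed in exact rational arithmetic."""
    if B1 < 0 or B2 < 0 or B < 0:
        raise ValueError("counts must be non-negative")
    if B > min(B1, B2):
        raise ValueError(f"matched count B={B} exceeds min(B1={B1}, B2={B2})")
    if B1 == 0 or B2 == 0:
        raise ValueError("recall/precision undefined for zero reference counts")
    recall = Fraction(B, B1)
    precision = Fraction(B, B2)
    return EvaluationResult(
        B1=B1,
        B2=B2,
        B=B,
        recall=float(recall),
        precision=float(precision),
        match_dist_um=match_dist_um,
    )


def evaluate_detections(
    detected: np.ndarray,
    truth: np.ndarray,
    max_dist_um: float = 5.0,
) -> EvaluationResult:
    """Match and score detections against ground-truth centres (B1 = truth)."""
    pairs = match_detections(detected, truth, max_dist_um)
    return recall_precision(
        B1=int(np.asarray(truth).reshape(-1, 3).shape[0]),
        B2=int(np.asarray(detected).reshape(-1, 3).shape[0]),
        B=len(pairs),
        match_dist_um=max_dist_um,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of |d| and the sign pattern, zero differences dropped."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = stats.rankdata(np.abs(d))  # midranks for ties
    return ranks, np.sign(d)


def wilcoxon_signed_rank(
    pairs: np.ndarray, mode: str = "normal_approx"
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    ``pairs`` is (n, 2); differences are first − second.  W = min(W⁺, W⁻)
    over the midranks of |d| (zeros dropped).  ``exact`` enumerates all 2ⁿ
    sign patterns (n ≤ 20); ``normal_approx`` uses
    z = (W − n(n+1)/4) / sqrt(n(n+1)(2n+1)/24) with no continuity
    correction and p = 2Φ(z), matching legacy statistical packages.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    diffs = pairs[:, 0] - pairs[:, 1]
    ranks, signs = _signed_ranks(diffs)
    n = len(ranks)
    w_plus = float(ranks[signs > 0].sum())
    w_minus = float(ranks[signs < 0].sum())
    W = min(w_plus, w_minus)

    if mode == "normal_approx":
        mean = n * (n + 1) / 4.0
        sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        z = (W - mean) / sd
        p = 2.0 * stats.norm.cdf(z)
        return W, min(1.0, float(p))
    if mode == "exact":
        if n > 20:
            raise ValueError("exact enumeration limited to n <= 20")
        # enumerate W⁺ over all 2ⁿ sign patterns (vectorized doubling)
        w_plus_all = np.zeros(1)
        for r in ranks:
            w_plus_all = np.concatenate([w_plus_all, w_plus_all + r])
        total = float(ranks.sum())
        w_min_all = np.minimum(w_plus_all, total - w_plus_all)
        p = float(np.mean(w_min_all <= W + 1e-12))
        return W, p
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# group comparisons


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrs):
        raise ValueError("each group needs at least two observations")
    if all(np.var(a) == 0 for a in arrs):
        raise ValueError("zero within-group variance in every group")
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)


def brightness_compare(
    brightness_per_stack: list[np.ndarray],
    n_sample: int = 20,
    seed: int = 0,
) -> tuple[list[float], float]:
    """Compare sampled mean soma brightness across volumes.

    Draws ``n_sample`` somas per volume (without replacement, seeded),
    returns the per-volume sample means and the one-way ANOVA p-value across
    the sampled groups.
    """
    rng = np.random.default_rng(seed)
    samples = []
    for vals in brightness_per_stack:
        vals = np.asarray(vals, dtype=float)
        if len(vals) < n_sample:
            raise ValueError(
                f"need at least {n_sample} somas per volume, got {len(vals)}"
            )
        take = rng.choice(len(vals), size=n_sample, replace=False)
        samples.append(vals[take])
    means = [float(s.mean()) for s in samples]
    _, p = anova_oneway(samples)
    return means, p
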