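"""Double-positive counting against exhaustive enumeration, and exact
Mann–Whitney p-values against brute-force arrangement enumeration."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

import pixplore as px
from pixplore.io import Roi
from pixplore.quantify import default_positivity_threshold


def _stack(channels: dict):
    markers = list(channels)
    data = np.stack([np.asarray(channels[m], float) for m in markers])
    return px.ChannelStack(data, px.MarkerPanel.from_markers(markers))


def _full_roi(shape, name="roi", group="LF"):
    return Roi(name=name, mask=np.ones(shape, bool), group=group)


def brute_force_mw_p(a, b, direction="greater"):
    """Enumerate all C(n1+n2, n1) group assignments of the pooled sample."""
    pooled = np.concatenate([a, b])
    n = pooled.size
    ranks = np.argsort(np.argsort(pooled)) + 1.0  # no ties assumed
    n1 = len(a)
    u_obs = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    count = 0
    total = 0
    for combo in combinations(range(n), n1):
        u = np.sum(ranks[list(combo)]) - n1 * (n1 + 1) / 2
        if direction == "greater":
            count += u >= u_obs
        else:
            count += u <= u_obs
        total += 1
    return count / total


class TestCountDoublePositive:
    def test_dead_channels_count_zero(self):
        stack = _stack({"a": np.zeros((5, 5)), "b": np.zeros((5, 5))})
        res = px.count_double_positive(stack, "a", "b", _full_roi((5, 5)))
        assert res.positive_count == 0
        assert res.fraction == 0.0

    def test_planted_pixels_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, (10, 10))
        b = rng.uniform(0, 1, (10, 10))
        plant = [(0, 0), (2, 3), (4, 4), (5, 9), (7, 1), (8, 8), (9, 0)]
        for r, c in plant:
            a[r, c] = 10.0
            b[r, c] = 10.0
        stack = _stack({"a": a, "b": b})
        res = px.count_double_positive(
            stack, "a", "b", _full_roi((10, 10)), thresholds=(5.0, 5.0)
        )
        # oracle: per-pixel loop
        expected = sum(
            1
            for r in range(10)
            for c in range(10)
            if a[r, c] >= 5.0 and b[r, c] >= 5.0
        )
        assert res.positive_count == expected == 7
        assert res.fraction == pytest.approx(0.07)

    def test_threshold_boundary_is_inclusive(self):
        a = np.zeros((2, 2))
        a[0, 0] = 3.0
        stack = _stack({"a": a, "b": a.copy()})
        res = px.count_double_positive(
            stack, "a", "b", _full_roi((2, 2)), thresholds=(3.0, 3.0)
        )
        assert res.positive_count == 1

    def test_count_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        stack = _stack(
            {"a": rng.gamma(2, 5, (12, 12)), "b": rng.gamma(2, 5, (12, 12))}
        )
        roi = _full_roi((12, 12))
        counts = [
            px.count_double_positive(stack, "a", "b", roi, thresholds=(t, 4.0)).positive_count
            for t in (1.0, 5.0, 9.0, 20.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_empty_roi_rejected(self):
        stack = _stack({"a": np.ones((3, 3)), "b": np.ones((3, 3))})
        roi = Roi(name="r", mask=np.zeros((3, 3), bool), group="LF")
        with pytest.raises(ValueError, match="empty"):
            px.count_double_positive(stack, "a", "b", roi)

    def test_unknown_marker_rejected(self):
        stack = _stack({"a": np.ones((3, 3)), "b": np.ones((3, 3))})
        with pytest.raises(ValueError, match="CD99"):
            px.count_double_positive(stack, "a", "CD99", _full_roi((3, 3)))

    def test_default_threshold_uses_percentile_rule(self):
        rng = np.random.default_rng(2)
        channel = rng.gamma(2, 5, (20, 20))
        t = default_positivity_threshold(channel)
        assert t == pytest.approx(np.percentile(channel, 98) * 0.5)


class TestMannWhitney:
    def test_identical_constant_groups_give_half(self):
        res = px.mann_whitney_one_tailed([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.p_one_tailed == 0.5
        assert res.u == 4.5  # null mean n1*n2/2

    def test_complete_separation_seven_vs_five(self):
        res = px.mann_whitney_one_tailed(
            [5, 6, 7, 8, 9, 10, 11], [0, 1, 2, 3, 4], direction="greater"
        )
        assert res.method == "exact"
        assert res.p_one_tailed == pytest.approx(1 / comb(12, 5), rel=1e-12)
        assert res.u == 35.0  # n1*n2

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 3), (7, 5), (8, 8)])
    def test_exact_p_matches_bruteforce_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        a = rng.uniform(size=n1)
        b = rng.uniform(size=n2)
        res = px.mann_whitney_one_tailed(a, b)
        assert res.method == "exact"
        assert res.p_one_tailed == pytest.approx(brute_force_mw_p(a, b), rel=1e-12)

    def test_large_or_tied_samples_use_normal_approximation(self):
        rng = np.random.default_rng(3)
        res = px.mann_whitney_one_tailed(rng.normal(size=15), rng.normal(size=15))
        assert res.method == "normal-approximation"
        res_tied = px.mann_whitney_one_tailed([1, 2, 2], [2, 3])
        assert res_tied.method == "normal-approximation"

    def test_direction_flips_tail(self):
        a, b = [5.0, 6.0, 7.0, 8.0], [1.0, 2.0, 3.0, 4.0]
        hi = px.mann_whitney_one_tailed(a, b, "greater").p_one_tailed
        lo = px.mann_whitney_one_tailed(a, b, "less").p_one_tailed
        assert hi < 0.05 < lo

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            px.mann_whitney_one_tailed([], [1.0])

    def test_null_rejection_rate_calibrated(self):
        # exact test at the 7-vs-5 design: achievable alpha nearest 0.05 is
        # 39/792 ≈ 0.049; simulated rejection rate must sit in [0.03, 0.07]
        rng = np.random.default_rng(12345)
        n_sim, rejections = 10_000, 0
        for _ in range(n_sim):
            a = rng.normal(size=7)
            b = rng.normal(size=5)
            if px.mann_whitney_one_tailed(a, b).p_one_tailed <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07


class TestGroupComparison:
    def test_planted_lf_effect_reaches_significance(self, lf_scene):
        _, stack, gt = lf_scene
        results = px.quantify_rois(stack, "CD161", "CD69", list(gt.roi_set))
        assert len(results) == 12
        lf = [r.fraction for r in results if r.group == "LF"]
        ctrl = [r.fraction for r in results if r.group == "non-LF"]
        assert len(lf) == 7 and len(ctrl) == 5
        assert min(lf) > max(ctrl)
        test = px.compare_groups(results, "LF", "non-LF", "greater")
        assert test.method == "exact"
        assert test.p_one_tailed < 0.01

    def test_missing_group_rejected(self, lf_scene):
        _, stack, gt = lf_scene
        results = px.quantify_rois(stack, "CD161", "CD69", list(gt.roi_set))
        with pytest.raises(ValueError, match="XX"):
            px.compare_groups(results, "LF", "XX")
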