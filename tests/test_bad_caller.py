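import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.special import logsumexp

from asbkit.bad_caller import (BadCaller, BadGrid, BadSegment, SnvObservation,
                               assign_bad, evaluate_map, segment_region,
                               split_by_gaps, trunc_binom_log_likelihood)
from conftest import simulate_observations


def exact_min_stat_probability(x: int, n: int, bad: Fraction) -> Fraction:
    """Exact-rational oracle for P(min(C_ref, C_alt) = x | n, BAD).

    Enumerates the truncated support of the equal-weight two-binomial
    haplotype mixture with rational arithmetic.
    """
    p = Fraction(1, 1) / (bad + 1)

    def f(k, prob):
        return math.comb(n, k) * prob**k * (1 - prob)**(n - k)

    def g(k):
        return Fraction(f(k, p) + f(k, 1 - p), 2)

    num = g(x) if x == n - x else g(x) + g(n - x)
    z = sum(g(k) for k in range(5, n - 4))
    return num / z


class TestTruncBinomLikelihood:
    def test_forced_support_single_point(self):
        # n=10 leaves k=5 as the whole truncated support: probability one
        for bad in (1.0, 2.0, 6.0):
            assert trunc_binom_log_likelihood(SnvObservation(1, 5, 10), bad) \
                == pytest.approx(0.0, abs=1e-12)

    def test_exact_enumeration_diploid(self):
        # n=12, x=5, BAD=1: [C(12,5)+C(12,7)] / [C(12,5)+C(12,6)+C(12,7)]
        got = math.exp(trunc_binom_log_likelihood(SnvObservation(1, 5, 12), 1.0))
        assert got == pytest.approx(1584 / 2508, rel=1e-12)

    def test_exact_enumeration_triploid(self):
        got = math.exp(trunc_binom_log_likelihood(SnvObservation(1, 5, 12), 2.0))
        expected = exact_min_stat_probability(5, 12, Fraction(2))
        assert got == pytest.approx(float(expected), rel=1e-12)

    @pytest.mark.parametrize("n", [10, 11, 17, 24, 40])
    @pytest.mark.parametrize("bad", [1.0, 4 / 3, 2.0, 6.0])
    def test_normalisation_over_support(self, n, bad):
        total = sum(
            math.exp(trunc_binom_log_likelihood(SnvObservation(1, x, n), bad))
            for x in range(5, n // 2 + 1))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_empty_support_raises(self):
        with pytest.raises(ValueError):
            trunc_binom_log_likelihood((1, 4, 9), 1.0)


class TestSplitByGaps:
    def _obs(self, positions):
        return [SnvObservation(p, 10, 30) for p in positions]

    def test_single_long_gap_splits_in_two(self):
        positions = list(range(1, 5_000_000, 1000)) + \
            list(range(15_000_000, 20_000_000, 1000))
        regions, excluded = split_by_gaps(self._obs(positions), "chr1",
                                          gap_bp=1_000_000)
        assert len(regions) == 2
        assert [e.reason for e in excluded] == ["gap"]

    def test_tiny_region_is_excluded(self):
        positions = [1, 1000, 2000, 5_000_000, 5_001_000]
        regions, excluded = split_by_gaps(self._obs(positions), "chr1",
                                          gap_bp=1_000_000)
        assert len(regions) == 1 and len(regions[0]) == 3
        assert any(e.reason == "too_few_snvs" for e in excluded)

    def test_no_gap_one_region(self):
        regions, excluded = split_by_gaps(self._obs(range(1, 10000, 500)),
                                          "chr1", gap_bp=1_000_000)
        assert len(regions) == 1 and excluded == []


def brute_force_segmentation(obs, grid, penalty, min_seg=3):
    """Exhaustive changepoint search (oracle for small n)."""
    n = len(obs)
    x = np.array([o.x for o in obs])
    tot = np.array([o.n for o in obs])
    ll = np.array([[trunc_binom_log_likelihood((0, xi, ni), b)
                    for b in grid.values] for xi, ni in zip(x, tot)])
    log_prior = grid.log_prior

    def seg_score(i, j):
        return logsumexp(log_prior + ll[i:j].sum(axis=0))

    best = -np.inf
    for k in range(0, n // min_seg):
        for cuts in itertools.combinations(range(min_seg, n - min_seg + 1), k):
            edges = (0, *cuts, n)
            if any(b - a < min_seg for a, b in zip(edges, edges[1:])):
                continue
            score = sum(seg_score(a, b) for a, b in zip(edges, edges[1:]))
            best = max(best, score - penalty * k)
    return best


def dp_objective(segments, grid, penalty):
    score = sum(logsumexp(grid.log_prior + s.log_likelihood) for s in segments)
    return score - penalty * (len(segments) - 1)


class TestSegmentation:
    def test_homogeneous_region_single_segment(self, rng):
        obs, _ = simulate_observations([1.0], 200, 60, rng)
        segs = segment_region(obs)
        assert len(segs) == 1
        assert segs[0].assigned_bad == 1.0

    def test_changepoint_located_within_two_snvs(self, piecewise_observations):
        obs, _ = piecewise_observations
        segs = segment_region(obs, changepoint_penalty=10.0)
        assert len(segs) == 2
        assert [s.assigned_bad for s in segs] == [1.0, 2.0]
        counts = [s.snv_count for s in segs]
        assert abs(counts[0] - 50) <= 2

    def test_infinite_penalty_means_no_changepoints(self, piecewise_observations):
        obs, _ = piecewise_observations
        segs = segment_region(obs, changepoint_penalty=1e9)
        assert len(segs) == 1

    def test_matches_brute_force_on_small_regions(self, rng):
        grid = BadGrid((1.0, 2.0, 3.0))
        for trial in range(30):
            n = int(rng.integers(3, 13))
            cov = int(rng.integers(12, 60))
            obs = []
            for i in range(n):
                x = int(rng.integers(5, cov // 2 + 1))
                obs.append(SnvObservation(i * 1000 + 1, x, cov))
            penalty = float(rng.uniform(0, 4))
            segs = segment_region(obs, grid, penalty)
            got = dp_objective(segs, grid, penalty)
            want = brute_force_segmentation(obs, grid, penalty)
            assert got == pytest.approx(want, abs=1e-9), f"trial {trial}"

    def test_segment_boundaries_tile_the_region(self, piecewise_observations):
        obs, _ = piecewise_observations
        segs = segment_region(obs, changepoint_penalty=10.0)
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start
        assert segs[0].start == obs[0].pos - 1
        assert segs[-1].end == obs[-1].pos


class TestAssignBad:
    def test_balanced_high_coverage_is_diploid(self, rng):
        obs, _ = simulate_observations([1.0], 150, 60, rng)
        segs = segment_region(obs)
        assert segs[0].assigned_bad == 1.0
        assert segs[0].posterior.sum() == pytest.approx(1.0)

    def test_exact_one_to_two_ratio_is_bad_two(self):
        obs = [SnvObservation(i * 100 + 1, 20, 60) for i in range(30)]
        segs = segment_region(obs)
        assert segs[0].assigned_bad == 2.0

    def test_uninformative_ties_break_to_smallest(self):
        grid = BadGrid((1.0, 2.0, 3.0))
        seg = BadSegment("chr1", 0, 100, 3, np.zeros(3))
        assert assign_bad(seg, grid).assigned_bad == 1.0


class TestClassifierScore:
    def _map(self, rng, bads=(1.0,), n=100, cov=60):
        obs, _ = simulate_observations(list(bads), n, cov, rng)
        return BadCaller({"chr1": obs}).fit()

    def test_sign_tracks_assignment(self, rng):
        badmap = self._map(rng)
        pos = badmap.segments[0].start + 1
        assert badmap.classifier_score("chr1", pos, 1.0) > 0
        assert badmap.classifier_score("chr1", pos, 2.0) < 0

    def test_score_identity(self, rng):
        badmap = self._map(rng)
        seg = badmap.segments[0]
        grid = badmap.grid
        s = badmap.classifier_score("chr1", seg.start + 1, 1.0)
        others = np.delete(seg.log_likelihood, 0)
        assert s + others.max() == pytest.approx(seg.log_likelihood[0])

    def test_equal_likelihoods_score_zero(self):
        grid = BadGrid((1.0, 2.0))
        seg = BadSegment("chr1", 0, 100, 3, np.zeros(2))
        from asbkit.bad_caller import BadMap
        badmap = BadMap([assign_bad(seg, grid)], grid=grid)
        assert badmap.classifier_score("chr1", 50, 1.0) == 0.0

    def test_outside_map_is_nan(self, rng):
        badmap = self._map(rng)
        assert math.isnan(badmap.classifier_score("chrX", 1, 1.0))


def kendall_tau_b_brute(x, y):
    """O(n^2) concordant/discordant-pair tau with tie correction."""
    n = len(x)
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    denom = math.sqrt((conc + disc + ties_x) * (conc + disc + ties_y))
    return (conc - disc) / denom


class TestEvaluateMap:
    def _setting(self, rng, n_per=120):
        bads = [1.0, 2.0, 3.0]
        obs, truth_bads = simulate_observations(bads, n_per, 40, rng)
        badmap = BadCaller({"chr1": obs}).fit()
        length = obs[-1].pos
        bounds = np.linspace(0, length, len(bads) + 1).astype(int)
        truth = [("chr1", a, b, bad) for a, b, bad in
                 zip(bounds[:-1], bounds[1:], bads)]
        snvs = [("chr1", o.pos) for o in obs]
        return badmap, truth, snvs

    def test_perfect_prediction(self, rng):
        badmap, truth, snvs = self._setting(rng)
        metrics = evaluate_map(badmap, truth, snvs)
        assert metrics["accuracy"] > 0.95
        assert metrics["kendall_tau_b"] > 0.95
        for per_bad in metrics["per_bad"].values():
            assert per_bad["auroc"] > 0.95

    def test_tau_matches_quadratic_oracle(self, rng):
        badmap, truth, snvs = self._setting(rng, n_per=40)
        metrics = evaluate_map(badmap, truth, snvs)
        from asbkit.bad_caller import _truth_lookup
        tm = _truth_lookup(truth)
        pred = [badmap.bad_at(c, p) for c, p in snvs]
        true = [tm.bad_at(c, p) for c, p in snvs]
        pairs = [(a, b) for a, b in zip(pred, true) if a is not None and b is not None]
        x, y = zip(*pairs)
        assert metrics["kendall_tau_b"] == pytest.approx(
            kendall_tau_b_brute(np.array(x), np.array(y)), abs=1e-12)

    def test_permuted_labels_give_near_zero_tau(self, rng):
        obs, truth_bads = simulate_observations([1.0, 2.0, 3.0], 100, 40, rng)
        badmap = BadCaller({"chr1": obs}).fit()
        perm = rng.permutation(len(obs))
        truth = [("chr1", o.pos - 1, o.pos, truth_bads[j])
                 for o, j in zip(obs, perm)]
        metrics = evaluate_map(badmap, truth, [("chr1", o.pos) for o in obs])
        assert abs(metrics["kendall_tau_b"]) < 0.15

    def test_no_overlap_is_an_error(self, rng):
        badmap, truth, _ = self._setting(rng, n_per=40)
        with pytest.raises(ValueError):
            evaluate_map(badmap, truth, [("chr9", 1)])
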