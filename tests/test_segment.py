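import itertools
import math

import numpy as np
import pytest

from cnascanner.segment import (
    SegmentationConfig,
    auto_lambda,
    bic_joint,
    bic_single,
    estimate_overdispersion,
    joint_segment,
)


def exhaustive_bic(A, B, lam):
    """Brute-force minimum of the joint BIC over all breakpoint subsets."""
    A = np.atleast_2d(A)
    B = np.atleast_2d(B)
    n = A.shape[1]
    best = (np.inf, None)
    for mask in itertools.product([0, 1], repeat=n - 1):
        cuts = [0] + [i + 1 for i, m in enumerate(mask) if m] + [n]
        SA = np.stack([A[:, s:e].sum(axis=1) for s, e in zip(cuts, cuts[1:])], axis=1)
        SB = np.stack([B[:, s:e].sum(axis=1) for s, e in zip(cuts, cuts[1:])], axis=1)
        bic = bic_joint(SA, SB, lam)
        if bic < best[0]:
            best = (bic, cuts)
    return best


def partition_bic(A, B, bounds, lam):
    A = np.atleast_2d(A)
    B = np.atleast_2d(B)
    SA = np.stack([A[:, s : e + 1].sum(axis=1) for s, e in bounds], axis=1)
    SB = np.stack([B[:, s : e + 1].sum(axis=1) for s, e in bounds], axis=1)
    return bic_joint(SA, SB, lam)


class TestBicSingle:
    def test_hand_computed_value(self):
        # one segment, a = b = 100, lambda = 1:
        # -2*(100 log 1/2 + 100 log 1/2) + 1*log(N) with N = sum(a_j) = 100
        expected = 400 * math.log(2) + math.log(100)
        assert bic_single([100], [100], lam=1.0) == pytest.approx(expected)
        assert expected == pytest.approx(281.864, abs=1e-3)

    def test_zero_observed_segment_finite(self):
        # 0 log 0 convention keeps the criterion finite
        assert np.isfinite(bic_single([0, 50], [10, 50], lam=1.0))

    def test_splitting_homogeneous_data_raises_bic(self):
        a = np.full(10, 40.0)
        b = np.full(10, 40.0)
        one = bic_single([a.sum()], [b.sum()], lam=1.0)
        two = bic_single([a[:5].sum(), a[5:].sum()], [b[:5].sum(), b[5:].sum()], lam=1.0)
        assert two > one

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            bic_single([0], [10], lam=1.0)


class TestBicJoint:
    def test_reduces_to_single_at_one_cell(self, rng):
        a = rng.poisson(50, 8).astype(float) + 1
        b = np.full(8, 50.0)
        assert bic_joint(a[None, :], b[None, :], lam=1.7) == pytest.approx(
            bic_single(a, b, lam=1.7)
        )

    def test_duplicated_cell_identity(self, rng):
        """G=2 identical cells: likelihood doubles, penalty uses 2*lam*log(2N)."""
        a = rng.poisson(50, 6).astype(float) + 1
        b = np.full(6, 50.0)
        lam = 1.3
        single = bic_single(a, b, lam)
        m = len(a) - 1
        lik_single = -(single - (m + 1) * lam * math.log(a.sum()))
        expected = -2 * lik_single + (m + 1) * 2 * lam * math.log(2 * a.sum())
        dup = bic_joint(np.stack([a, a]), np.stack([b, b]), lam)
        assert dup == pytest.approx(expected)

    def test_linear_in_lambda(self, rng):
        a = rng.poisson(50, (3, 6)).astype(float) + 1
        b = np.full((3, 6), 50.0)
        m = a.shape[1] - 1
        d1 = bic_joint(a, b, 2.0) - bic_joint(a, b, 1.0)
        assert d1 == pytest.approx((m + 1) * 3 * math.log(a.sum()))

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            bic_joint(np.ones((2, 5)), np.ones((2, 4)), 1.0)


class TestJointSegment:
    def test_recovers_shared_jump_exactly(self):
        """Noiseless two-cell step at bin 6 matches the exhaustive optimum."""
        n = 12
        rate = np.where(np.arange(n) < 6, 100.0, 50.0)
        A = np.stack([rate, rate])
        B = np.full((2, n), 100.0)
        bounds = joint_segment(A, B, SegmentationConfig(lam=1.0))
        assert bounds == [(0, 5), (6, 11)]
        _, cuts = exhaustive_bic(A, B, 1.0)
        assert cuts == [0, 6, 12]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_greedy_within_one_percent_of_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(8, 13)
        rate = np.where(np.arange(n) < n // 2, 60.0, 100.0)
        A = rng.poisson(rate, (2, n)).astype(float) + 1
        B = np.full((2, n), 80.0)
        lam = 1.0
        bounds = joint_segment(A, B, SegmentationConfig(lam=lam))
        greedy = partition_bic(A, B, bounds, lam)
        optimum, _ = exhaustive_bic(A, B, lam)
        assert greedy <= optimum * 1.01 + 1e-9 if optimum > 0 else greedy <= optimum * 0.99

    def test_constant_rates_single_segment(self):
        A = np.full((3, 20), 50.0)
        B = np.full((3, 20), 50.0)
        assert joint_segment(A, B, SegmentationConfig(lam=1.0)) == [(0, 19)]

    def test_huge_lambda_single_segment(self, rng):
        A = rng.poisson(60, (2, 30)).astype(float) + 1
        A[:, 15:] *= 3
        B = np.full((2, 30), 60.0)
        assert joint_segment(A, B, SegmentationConfig(lam=1e6)) == [(0, 29)]

    def test_bic_non_increasing(self, rng):
        A = rng.poisson(70, (2, 40)).astype(float) + 1
        B = np.full((2, 40), 70.0)
        lam = 1.0
        bounds = joint_segment(A, B, SegmentationConfig(lam=lam))
        initial = partition_bic(A, B, [(i, i) for i in range(40)], lam)
        final = partition_bic(A, B, bounds, lam)
        assert final <= initial

    def test_invariant_to_cell_order(self, rng):
        A = rng.poisson([60.0] * 10 + [120.0] * 10, (3, 20)).astype(float) + 1
        B = np.full((3, 20), 90.0)
        cfg = SegmentationConfig(lam=1.0)
        assert joint_segment(A, B, cfg) == joint_segment(A[::-1], B[::-1], cfg)

    def test_partition_covers_all_bins(self, rng):
        A = rng.poisson(50, (2, 25)).astype(float) + 1
        B = np.full((2, 25), 50.0)
        bounds = joint_segment(A, B, SegmentationConfig(lam=1.0))
        flat = [i for s, e in bounds for i in range(s, e + 1)]
        assert flat == list(range(25))

    def test_no_merge_across_chromosomes(self):
        A = np.full((1, 10), 50.0)
        B = np.full((1, 10), 50.0)
        chroms = ["chr1"] * 5 + ["chr2"] * 5
        bounds = joint_segment(A, B, SegmentationConfig(lam=1.0), chrom_ids=chroms)
        assert bounds == [(0, 4), (5, 9)]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            joint_segment(np.empty((1, 0)), np.empty((1, 0)))


class TestAutoLambda:
    def test_poisson_data_close_to_unit_dispersion(self, rng):
        A = rng.poisson(200, (4, 400)).astype(float)
        B = np.full((4, 400), 200.0)
        assert estimate_overdispersion(A, B) == pytest.approx(1.0, rel=0.3)

    def test_overdispersion_scales_lambda(self, rng):
        B = np.full((2, 400), 200.0)
        A1 = rng.poisson(200, (2, 400)).astype(float)
        noisy = 200 * rng.gamma(9, 1 / 9, (2, 400))  # CV 1/3 multiplicative field
        A2 = rng.poisson(noisy).astype(float)
        assert auto_lambda(A2, B) > 5 * auto_lambda(A1, B)
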