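"""Agreement statistics: closed forms, enumeration oracles, invariances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ivoctreg.agreement import (
    angle_differences,
    bland_altman,
    compare_estimates,
    frame_differences,
    lin_ccc,
    median_iqr,
    spearman_r,
    wilcoxon_signed_rank,
    williams_index,
)
from ivoctreg.errors import ParameterError, UndefinedMetricError


class TestFrameDifferences:
    def test_identical_maps_zero(self):
        a = np.arange(10.0)
        assert frame_differences(a, a) == pytest.approx(np.zeros(10))

    def test_constant_offset(self):
        a = np.arange(10.0)
        d = frame_differences(a, a + 2.0)
        med, lo, hi = median_iqr(d)
        assert med == 2.0
        assert med * 0.2 == pytest.approx(0.4)  # mm at 0.2 mm OCT spacing

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(20), rng.random(20)
        assert frame_differences(a, b) == pytest.approx(frame_differences(b, a))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ParameterError):
            frame_differences(np.arange(3.0), np.arange(4.0))


class TestAngleDifferences:
    @pytest.mark.parametrize(
        "a,b,expected", [(350.0, 10.0, 20.0), (0.0, 0.0, 0.0), (0.0, 180.0, 180.0)]
    )
    def test_wraparound(self, a, b, expected):
        assert angle_differences([a], [b])[0] == pytest.approx(expected)

    def test_range(self):
        rng = np.random.default_rng(1)
        d = angle_differences(rng.uniform(0, 360, 100), rng.uniform(0, 360, 100))
        assert (d >= 0).all() and (d <= 180).all()


class TestLinCCC:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2, 3, 5, 8])
        assert lin_ccc(x, x) == pytest.approx(1.0)

    def test_location_shift_closed_form(self):
        # y = x + c: CCC = 2 sigma^2 / (2 sigma^2 + c^2), population moments
        rng = np.random.default_rng(2)
        x = rng.random(50)
        for c in (0.5, 1.0, 3.0):
            sigma2 = x.var()
            assert lin_ccc(x, x + c) == pytest.approx(
                2 * sigma2 / (2 * sigma2 + c**2), rel=1e-12
            )

    def test_perfect_negative(self):
        x = np.array([-2.0, -1, 0, 1, 2])
        assert lin_ccc(x, -x) == pytest.approx(-1.0)

    def test_both_constant_undefined(self):
        with pytest.raises(UndefinedMetricError):
            lin_ccc(np.ones(5), np.ones(5))

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_bounded_by_pearson(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random(20), rng.random(20)
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(lin_ccc(x, y)) <= abs(pearson) + 1e-12


class TestSpearman:
    def test_monotone_transform_perfect(self):
        x = np.array([3.0, 1, 4, 1.5, 9, 2.6])
        assert spearman_r(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversal(self):
        x = np.arange(10.0)
        assert spearman_r(x, x[::-1]) == pytest.approx(-1.0)

    def test_tie_handling_matches_midrank_oracle(self):
        def midranks(v):
            v = np.asarray(v, dtype=float)
            out = np.empty(len(v))
            for i, val in enumerate(v):
                less = (v < val).sum()
                equal = (v == val).sum()
                out[i] = less + (equal + 1) / 2.0
            return out

        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.integers(0, 3, size=5).astype(float)  # heavy ties
            y = rng.integers(0, 3, size=5).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rx, ry = midranks(x), midranks(y)
            expected = np.corrcoef(rx, ry)[0, 1]
            assert spearman_r(x, y) == pytest.approx(expected, rel=1e-12)


class TestWilliamsIndex:
    def test_symmetric_case_is_one(self):
        # all three pairwise mean absolute differences equal 1 -> WI = 1
        e1 = np.array([0.0, 2, 0, 2])
        e2 = np.array([1.0, 1, 1, 1])
        m = np.array([1.0, 3, 1, 3])
        wi, _ = williams_index(m, e1, e2)
        assert wi == pytest.approx(1.0)

    def test_direct_formula(self):
        # D(M,E1)=1, D(M,E2)=3, D(E1,E2)=2 -> WI = 0.5 (1/1 + 1/3) * 2 = 4/3
        m = np.zeros(4)
        e1 = np.full(4, 1.0)
        e2 = np.full(4, 3.0)
        wi, _ = williams_index(m, e1, e2)
        assert wi == pytest.approx(4.0 / 3.0)

    def test_closer_model_exceeds_one(self):
        rng = np.random.default_rng(4)
        truth = rng.random(50) * 10
        e1 = truth + rng.normal(0, 1.0, 50)
        e2 = truth + rng.normal(0, 1.0, 50)
        m = truth + rng.normal(0, 0.1, 50)
        wi, _ = williams_index(m, e1, e2)
        assert wi > 1.0

    def test_expert_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        m, e1, e2 = rng.random(30), rng.random(30), rng.random(30)
        g = np.repeat(np.arange(5), 6)
        a = williams_index(m, e1, e2, groups=g)
        b = williams_index(m, e2, e1, groups=g)
        assert a[0] == pytest.approx(b[0])
        assert a[1] == pytest.approx(b[1])

    def test_jackknife_ci_brackets_estimate(self):
        rng = np.random.default_rng(6)
        m, e1, e2 = rng.random(40), rng.random(40), rng.random(40)
        wi, (lo, hi) = williams_index(m, e1, e2, groups=np.repeat(np.arange(8), 5))
        assert lo <= wi <= hi

    def test_perfect_agreement_undefined(self):
        x = np.arange(5.0)
        with pytest.raises(UndefinedMetricError):
            williams_index(x, x, x + 1)


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 2, 3, 4])
        bias, lo, hi = bland_altman(x, x)
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)

    def test_constant_offset_bias(self):
        x = np.array([1.0, 2, 3, 4])
        bias, lo, hi = bland_altman(x, x - 1.5)
        assert bias == pytest.approx(1.5)
        assert hi - bias == pytest.approx(bias - lo)  # symmetric limits


class TestWilcoxon:
    def test_all_zero_differences_undefined(self):
        a = np.arange(10.0)
        with pytest.raises(UndefinedMetricError):
            wilcoxon_signed_rank(a, a)

    def test_exact_p_matches_sign_enumeration(self):
        # two-sided exact p at n=8 equals enumeration over all 2^8 sign vectors
        rng = np.random.default_rng(7)
        for _ in range(5):
            d = rng.normal(0, 1, 8)
            d = d[d != 0]
            ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
            t_obs = ranks[d > 0].sum()
            dist = np.array(
                [ranks[np.array(signs)].sum() if any(signs) else 0.0
                 for signs in itertools.product([False, True], repeat=len(d))]
            )
            p_lo = np.mean(dist <= t_obs)
            p_hi = np.mean(dist >= t_obs)
            expected = min(1.0, 2 * min(p_lo, p_hi))
            _, p = wilcoxon_signed_rank(d, np.zeros(len(d)))
            assert p == pytest.approx(expected, rel=1e-9)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(8)
        a, b = rng.random(15), rng.random(15)
        _, p1 = wilcoxon_signed_rank(a, b)
        _, p2 = wilcoxon_signed_rank(b, a)
        assert p1 == pytest.approx(p2)


class TestPermutationInvariance:
    def test_all_metrics_order_invariant(self):
        rng = np.random.default_rng(9)
        x, y = rng.random(25) * 10, rng.random(25) * 10
        perm = rng.permutation(25)
        assert lin_ccc(x, y) == pytest.approx(lin_ccc(x[perm], y[perm]))
        assert spearman_r(x, y) == pytest.approx(spearman_r(x[perm], y[perm]))
        assert bland_altman(x, y) == pytest.approx(bland_altman(x[perm], y[perm]))
        assert np.median(frame_differences(x, y)) == pytest.approx(
            np.median(frame_differences(x[perm], y[perm]))
        )


def test_compare_estimates_report():
    rng = np.random.default_rng(10)
    a = np.linspace(0, 100, 60)
    b = a + rng.normal(0, 1.0, 60)
    rot_a = rng.uniform(0, 360, 60)
    rot_b = (rot_a + rng.normal(0, 5, 60)) % 360
    rep = compare_estimates(a, b, rot_a, rot_b)
    assert rep.n_frames == 60
    assert rep.ccc_frames > 0.99
    assert rep.median_frame_diff_mm == pytest.approx(rep.median_frame_diff * 0.2)
    assert 0 <= rep.median_angle_diff_deg <= 180
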