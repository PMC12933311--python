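"""Rotational registration: NCC cost rows, DP path, circular interpolation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ivoctreg.angles import circular_abs_diff_deg
from ivoctreg.circumferential import (
    CircularProfile,
    circular_profile,
    dp_rotation_path,
    interpolate_rotations,
    ncc,
    rotation_cost_row,
    select_landmark_pairs,
)
from ivoctreg.errors import ParameterError
from ivoctreg.pullback import BranchBox, N_ANGLE_BINS, rotate_frame
from conftest import make_frame


def random_profile(rng):
    return CircularProfile(
        radius=1.0 + rng.random(N_ANGLE_BINS),
        branch=np.where(rng.random(N_ANGLE_BINS) > 0.9, rng.random(N_ANGLE_BINS), 0.0),
        calc=(rng.random(N_ANGLE_BINS) > 0.8).astype(float),
    )


def shift_profile(p, k):
    return CircularProfile(np.roll(p.radius, k), np.roll(p.branch, k), np.roll(p.calc, k))


def dp_oracle(R, lam, max_step):
    """Exhaustive enumeration of all K^T rotation paths (feasible steps only)."""
    T, K = R.shape
    bin_deg = 360.0 / K
    best_cost, best_path = np.inf, None
    for ks in itertools.product(range(K), repeat=T):
        cost = R[0, ks[0]]
        ok = True
        for t in range(1, T):
            step = circular_abs_diff_deg(bin_deg * ks[t - 1], bin_deg * ks[t])
            if step > max_step + 1e-9:
                ok = False
                break
            cost += R[t, ks[t]] + lam * (step / 360.0) ** 2
        if ok and cost < best_cost:
            best_cost, best_path = cost, ks
    return best_cost, best_path


def path_cost(R, ks_deg, lam):
    bin_deg = 360.0 / R.shape[1]
    ks = np.round(np.asarray(ks_deg) / bin_deg).astype(int)
    cost = R[0, ks[0]]
    for t in range(1, len(ks)):
        step = circular_abs_diff_deg(bin_deg * ks[t - 1], bin_deg * ks[t])
        cost += R[t, ks[t]] + lam * (step / 360.0) ** 2
    return cost


class TestNCC:
    def test_identical_signal(self, rng):
        a = rng.random(N_ANGLE_BINS)
        assert ncc(a, a) == pytest.approx(1.0)

    def test_negated_signal(self, rng):
        a = rng.random(N_ANGLE_BINS)
        a -= a.mean()
        assert ncc(a, -a) == pytest.approx(-1.0)

    def test_constant_signal_uninformative(self, rng):
        assert ncc(np.full(N_ANGLE_BINS, 3.0), rng.random(N_ANGLE_BINS)) == 0.0


class TestCircularProfile:
    def test_plain_circular_lumen(self):
        p = circular_profile(make_frame(radius=2.0, n_pts=96))
        assert p.radius == pytest.approx(np.full(N_ANGLE_BINS, 2.0), abs=5e-3)
        assert (p.branch == 0).all() and (p.calc == 0).all()

    def test_branch_mass_in_center_bin(self):
        # box centered at 90 degrees from the centroid -> bin 45
        f = make_frame(branches=(BranchBox((0.0, 1.5), 1.0, 1.0),))
        p = circular_profile(f)
        assert p.branch[45] == pytest.approx(1.0)
        assert p.branch.sum() == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=10)
    @given(k=st.integers(1, 179))
    def test_rotation_shifts_all_channels(self, k):
        f = make_frame(
            radius=1.5,
            branches=(BranchBox((1.5, 0.1), 0.5, 0.5),),
            calc_bins=range(100, 130),
        )
        p0 = circular_profile(f)
        pk = circular_profile(rotate_frame(f, 2.0 * k))
        assert pk.radius == pytest.approx(np.roll(p0.radius, k), abs=1e-6)
        assert pk.branch == pytest.approx(np.roll(p0.branch, k))
        assert pk.calc == pytest.approx(np.roll(p0.calc, k))


class TestRotationCostRow:
    def test_identical_profiles_argmin_zero(self, rng):
        p = random_profile(rng)
        row = rotation_cost_row(p, p)
        assert row.argmin() == 0
        assert row[0] == pytest.approx(0.0, abs=1e-12)
        assert (row >= -1e-12).all() and (row <= 2 + 1e-12).all()

    def test_shifted_profile_recovered(self, rng):
        # OCT constructed as IVUS shifted by 20 bins -> argmin at 40 degrees
        p = random_profile(rng)
        row = rotation_cost_row(p, shift_profile(p, -20))
        assert row.argmin() == 20

    def test_cost_row_shift_equivariance(self, rng):
        p = random_profile(rng)
        q = random_profile(rng)
        base = rotation_cost_row(p, q)
        for k in (1, 17, 90):
            shifted = rotation_cost_row(p, shift_profile(q, -k))
            assert shifted == pytest.approx(np.roll(base, k), abs=1e-12)

    def test_exhaustive_shift_oracle(self, rng):
        p = random_profile(rng)
        q = random_profile(rng)
        row = rotation_cost_row(p, q, (1.0, 0.5, 2.0))
        w = np.array([1.0, 0.5, 2.0])
        for k in rng.integers(0, N_ANGLE_BINS, size=12):
            parts = [
                ncc(a, np.roll(b, k))
                for a, b in zip(p.channels, q.channels)
            ]
            assert row[k] == pytest.approx(1.0 - np.dot(w, parts) / w.sum(), abs=1e-12)

    def test_invariant_to_radius_offset(self, rng):
        p = random_profile(rng)
        q = random_profile(rng)
        base = rotation_cost_row(p, q)
        p2 = CircularProfile(p.radius + 5.0, p.branch, p.calc)
        q2 = CircularProfile(q.radius + 3.0, q.branch, q.calc)
        assert rotation_cost_row(p2, q2) == pytest.approx(base, abs=1e-9)


class TestSelectLandmarkPairs:
    def _frames(self):
        branch = (BranchBox((1.5, 0.0), 0.5, 0.5),)
        ivus = [
            make_frame("IVUS", 0, 0.0, True, 1.5),
            make_frame("IVUS", 1, 0.5, True, 1.5, branches=branch),
            make_frame("IVUS", 2, 1.0, True, 1.5, branches=branch),
        ]
        oct_frames = [
            make_frame("OCT", 0, 0.0, True, 1.5),
            make_frame("OCT", 1, 0.2, True, 1.5, branches=branch),
            make_frame("OCT", 2, 0.4, True, 1.5),
        ]
        return ivus, oct_frames

    def test_both_modality_rule(self):
        ivus, oct_frames = self._frames()
        pairs = select_landmark_pairs(np.array([0.0, 1.0, 2.0]), ivus, oct_frames)
        # only pair 1 has the branch visible in both frames
        assert [p[0] for p in pairs] == [1]

    def test_either_rule_accepts_one_sided(self):
        ivus, oct_frames = self._frames()
        pairs = select_landmark_pairs(
            np.array([0.0, 1.0, 2.0]), ivus, oct_frames, rule="either"
        )
        assert [p[0] for p in pairs] == [1, 2]

    def test_eccentricity_fallback(self):
        from conftest import star_polygon
        from ivoctreg.pullback import CalciumArc, Frame
        import numpy as np

        def ecc_frame(modality, i, ecc):
            th = np.deg2rad(2.0 * np.arange(96))
            r = 1.5 * (1 + ecc * np.cos(2 * np.deg2rad(360 * np.arange(96) / 96)))
            c = star_polygon(r)
            return Frame(modality, i, 0.5 * i, True, c, (), CalciumArc(np.zeros(180)))

        ivus = [ecc_frame("IVUS", 0, 0.0), ecc_frame("IVUS", 1, 0.3)]
        oct_frames = [ecc_frame("OCT", 0, 0.0), ecc_frame("OCT", 1, 0.3)]
        pairs = select_landmark_pairs(np.array([0.0, 1.0]), ivus, oct_frames)
        assert len(pairs) == 1
        assert pairs[0][0] == 1  # the most eccentric pair


class TestDPRotationPath:
    def test_no_penalty_is_per_row_argmin(self, rng):
        R = rng.random((5, N_ANGLE_BINS))
        rot = dp_rotation_path(R, lambda_shape=0.0, max_step_deg=360.0)
        assert rot == pytest.approx(2.0 * R.argmin(axis=1))

    def test_single_row(self, rng):
        R = rng.random((1, N_ANGLE_BINS))
        assert dp_rotation_path(R)[0] == pytest.approx(2.0 * R.argmin())

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            T, K = rng.integers(1, 5), 8
            R = rng.random((T, K))
            lam = float(rng.uniform(0, 20))
            max_step = float(rng.choice([45.0, 90.0, 360.0]))
            got = dp_rotation_path(R, lam, max_step)
            oracle_cost, _ = dp_oracle(R, lam, max_step)
            assert path_cost(R, got, lam) == pytest.approx(oracle_cost, rel=1e-12)

    def test_infinite_lambda_gives_constant_rotation(self):
        rng = np.random.default_rng(13)
        R = rng.random((4, 8))
        rot = dp_rotation_path(R, lambda_shape=1e12, max_step_deg=360.0)
        assert len(set(rot.tolist())) == 1
        # the constant minimizing the summed cost column-wise
        assert rot[0] == pytest.approx(45.0 * R.sum(axis=0).argmin())

    def test_negative_parameters_rejected(self, rng):
        R = rng.random((2, 8))
        with pytest.raises(ParameterError):
            dp_rotation_path(R, lambda_shape=-1.0)
        with pytest.raises(ParameterError):
            dp_rotation_path(R, max_step_deg=-5.0)


class TestInterpolateRotations:
    def test_midpoint(self):
        s = interpolate_rotations([0, 2], [10.0, 30.0], 3)
        assert s.rotation_deg == pytest.approx([10.0, 20.0, 30.0])
        assert s.landmark.tolist() == [True, False, True]

    def test_wraparound_shorter_arc(self):
        s = interpolate_rotations([0, 2], [350.0, 10.0], 3)
        assert s.rotation_deg[1] == pytest.approx(0.0)

    def test_single_landmark_constant(self):
        s = interpolate_rotations([3], [77.0], 7)
        assert s.rotation_deg == pytest.approx(np.full(7, 77.0))
        assert s.landmark.sum() == 1

    def test_constant_extension_at_ends(self):
        s = interpolate_rotations([2, 4], [100.0, 120.0], 8)
        assert s.rotation_deg[:2] == pytest.approx([100.0, 100.0])
        assert s.rotation_deg[5:] == pytest.approx([120.0] * 3)
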