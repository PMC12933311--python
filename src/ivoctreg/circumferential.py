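"""Circumferential (rotational) registration of matched IVUS/OCT frames.

Once frames are matched longitudinally, the OCT frame of each pair must be
rotated to the IVUS orientation. Following how analysts work, rotation is
estimated only at *landmark pairs* — pairs where both frames show a side
branch or calcium (features with a well-defined angular signature) — and
linearly interpolated (circularly, along the shorter arc) for the frames in
between.

Per landmark pair, three circular signals sampled in 2-degree increments
around the lumen centroid (radial distance, side-branch mass, calcium
presence) are compared under all 180 candidate rotations via per-channel
normalized cross-correlation; cost = 1 - weighted mean NCC. Stacking one
cost row per landmark pair gives the rotation cost matrix, over which a
dynamic program finds the lowest-cost rotation path subject to a quadratic
shape-regularization penalty on the rotation change between consecutive
landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import circular_abs_diff_deg, circular_interp_deg, wrap_deg
from .errors import ParameterError
from .pullback import (
    N_ANGLE_BINS,
    Frame,
    contour_centroid,
    eccentricity,
    radial_profile,
)

BIN_DEG = 360.0 / N_ANGLE_BINS  # 2 degrees

#: default channel weights (radius, branch, calcium)
DEFAULT_CHANNEL_WEIGHTS = (1.0, 1.0, 1.0)
DEFAULT_LAMBDA_SHAPE = 25.0
DEFAULT_MAX_STEP_DEG = 30.0


@dataclass(frozen=True)
class CircularProfile:
    """Per-2-degree-direction radial distance, branch mass and calcium flag."""

    radius: np.ndarray
    branch: np.ndarray
    calc: np.ndarray

    def __post_init__(self):
        for name in ("radius", "branch", "calc"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_ANGLE_BINS,):
                raise ParameterError(f"{name} channel must have {N_ANGLE_BINS} bins")
            object.__setattr__(self, name, arr)
        if (self.radius <= 0).any():
            raise ParameterError("radius channel must be strictly positive")
        if (self.branch < 0).any():
            raise ParameterError("branch channel must be nonnegative")

    @property
    def channels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.radius, self.branch, self.calc)


@dataclass(frozen=True)
class RotationSeries:
    """Per matched pair: OCT rotation (deg CCW to align with IVUS) + landmark flag."""

    rotation_deg: np.ndarray
    landmark: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation_deg, dtype=float)
        l = np.asarray(self.landmark, dtype=bool)
        if r.shape != l.shape:
            raise ParameterError("rotation and landmark arrays must match")
        if ((r < 0) | (r >= 360)).any():
            raise ParameterError("rotations must lie in [0, 360)")
        object.__setattr__(self, "rotation_deg", r)
        object.__setattr__(self, "landmark", l)


def circular_profile(frame: Frame) -> CircularProfile:
    """Sample a frame's annotations along the 180 bin-center directions.

    The branch channel assigns each box's full area to the bin containing the
    angular position of its center relative to the lumen centroid.
    """
    radius = radial_profile(frame.lumen, N_ANGLE_BINS)
    branch = np.zeros(N_ANGLE_BINS)
    cen = np.asarray(contour_centroid(frame.lumen))
    for box in frame.branches:
        dx, dy = np.asarray(box.center) - cen
        ang = np.rad2deg(np.arctan2(dy, dx)) % 360.0
        branch[int(ang // BIN_DEG) % N_ANGLE_BINS] += box.area
    return CircularProfile(radius, branch, frame.calcium.flags.astype(float))


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson-style normalized cross-correlation in [-1, 1].

    Returns 0 when either signal is constant (an uninformative channel).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("ncc inputs must be 1-D and equal length")
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.sqrt(np.sum(da * da)), np.sqrt(np.sum(db * db))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(np.sum(da * db) / (na * nb), -1.0, 1.0))


def _all_shifts(x: np.ndarray) -> np.ndarray:
    """(180, 180) matrix whose row k is x circularly shifted by k bins."""
    idx = (np.arange(N_ANGLE_BINS)[None, :] - np.arange(N_ANGLE_BINS)[:, None]) % N_ANGLE_BINS
    return x[idx]


def rotation_cost_row(
    p_ivus: CircularProfile,
    p_oct: CircularProfile,
    channel_weights=DEFAULT_CHANNEL_WEIGHTS,
) -> np.ndarray:
    """Cost of each candidate rotation (0, 2, ..., 358 deg) for one pair.

    Rotating the OCT frame counter-clockwise by 2k degrees corresponds to
    circularly shifting its channels by k bins. For each k the per-channel
    NCC with the IVUS profile is combined as a weighted mean s_k; the cost is
    1 - s_k, in [0, 2].
    """
    w = np.asarray(channel_weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ParameterError("channel weights must be nonnegative with positive sum")
    costs = np.zeros(N_ANGLE_BINS)
    total_w = w.sum()
    for weight, a, b in zip(w, p_ivus.channels, p_oct.channels):
        if weight == 0:
            continue
        da = a - a.mean()
        na = np.sqrt(np.sum(da * da))
        shifts = _all_shifts(np.asarray(b, dtype=float))
        db = shifts - shifts.mean(axis=1, keepdims=True)
        nb = np.sqrt(np.sum(db * db, axis=1))
        s = np.zeros(N_ANGLE_BINS)
        ok = (na > 0) & (nb > 0)
        if na > 0:
            s[ok] = np.clip(db[ok] @ da / (na * nb[ok]), -1.0, 1.0)
        costs += weight * (1.0 - s)
    return costs / total_w


def select_landmark_pairs(
    full_map: np.ndarray,
    ivus_frames: list[Frame],
    oct_frames: list[Frame],
    rule: str = "both",
) -> list[tuple[int, int, int]]:
    """Pick the matched pairs eligible for direct rotational estimation.

    ``full_map[i]`` is the continuous OCT original frame index matched to the
    i-th IVUS analysis frame; ``oct_frames`` must be indexable by original
    OCT frame index. A pair qualifies when the IVUS frame and its (nearest)
    matched OCT frame each show a side branch or calcium ("both" rule; the
    "either" rule accepts one-sided evidence). If nothing qualifies, the
    single pair with maximal summed lumen eccentricity is returned.

    Returns (pair position, IVUS list position, OCT original index) triples.
    """
    if rule not in ("both", "either"):
        raise ParameterError(f"unknown landmark rule {rule!r}")
    full_map = np.asarray(full_map, dtype=float)
    if len(full_map) != len(ivus_frames):
        raise ParameterError("full_map and ivus_frames length mismatch")

    def has_feature(f: Frame) -> bool:
        return len(f.branches) > 0 or f.calcium.flags.any()

    out = []
    for pos, fi in enumerate(ivus_frames):
        oj = int(np.clip(round(full_map[pos]), 0, len(oct_frames) - 1))
        fo = oct_frames[oj]
        hit = (has_feature(fi) and has_feature(fo)) if rule == "both" else (
            has_feature(fi) or has_feature(fo)
        )
        if hit:
            out.append((pos, pos, oj))
    if out:
        return out

    # fallback: the most eccentric pair still carries rotational signal
    best, best_ecc = None, -1.0
    for pos, fi in enumerate(ivus_frames):
        oj = int(np.clip(round(full_map[pos]), 0, len(oct_frames) - 1))
        e = eccentricity(radial_profile(fi.lumen)) + eccentricity(
            radial_profile(oct_frames[oj].lumen)
        )
        if e > best_ecc:
            best, best_ecc = (pos, pos, oj), e
    return [best]


def dp_rotation_path(
    R: np.ndarray,
    lambda_shape: float = DEFAULT_LAMBDA_SHAPE,
    max_step_deg: float = DEFAULT_MAX_STEP_DEG,
) -> np.ndarray:
    """Lowest-cost rotation per cost-matrix row under shape regularization.

    A[0][k] = R[0][k]; A[t][k] = R[t][k] + min over feasible j of
    (A[t-1][j] + lambda_shape * (step/360)^2), step = circular difference
    between rotations 2j and 2k degrees, feasible when step <= max_step_deg.
    The answer is read by backtracking from the argmin of the final row.
    Ties prefer the smaller circular step, then the smaller candidate index.

    Returns the rotation in degrees per row, values on the 2-degree grid.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] < 1:
        raise ParameterError("cost matrix must be (T, K) with T >= 1")
    if not np.isfinite(R).all():
        raise ParameterError("cost matrix contains non-finite entries")
    if lambda_shape < 0 or max_step_deg < 0:
        raise ParameterError("lambda_shape and max_step_deg must be >= 0")
    T, K = R.shape
    bin_deg = 360.0 / K

    step = circular_abs_diff_deg(
        bin_deg * np.arange(K)[:, None], bin_deg * np.arange(K)[None, :]
    )  # step[j, k]
    feasible = step <= max_step_deg + 1e-9
    penalty = np.where(feasible, lambda_shape * (step / 360.0) ** 2, np.inf)

    A = np.empty((T, K))
    pred = np.zeros((T, K), dtype=int)
    A[0] = R[0]
    for t in range(1, T):
        trans = A[t - 1][:, None] + penalty  # (j, k)
        # lexicographic argmin over j: value, then circular step, then j
        order = np.lexsort((np.broadcast_to(np.arange(K)[:, None], (K, K)), step, trans), axis=0)
        best_j = order[0]
        pred[t] = best_j
        A[t] = R[t] + trans[best_j, np.arange(K)]
    k = int(np.argmin(A[T - 1]))
    ks = np.empty(T, dtype=int)
    ks[T - 1] = k
    for t in range(T - 1, 0, -1):
        k = pred[t, k]
        ks[t - 1] = k
    return bin_deg * ks


def interpolate_rotations(
    landmark_positions: np.ndarray,
    landmark_rotations_deg: np.ndarray,
    n_pairs: int,
) -> RotationSeries:
    """Circular linear interpolation of landmark rotations to all pairs.

    Between consecutive landmarks the rotation follows the shorter arc,
    parameterized by pair position; before the first and after the last
    landmark it is held constant.
    """
    pos = np.asarray(landmark_positions, dtype=int)
    rot = wrap_deg(np.asarray(landmark_rotations_deg, dtype=float))
    if len(pos) < 1 or len(pos) != len(rot):
        raise ParameterError("need >= 1 landmark with matching rotations")
    if not (np.diff(pos) > 0).all():
        raise ParameterError("landmark positions must be strictly increasing")
    out = np.empty(n_pairs)
    landmark = np.zeros(n_pairs, dtype=bool)
    landmark[pos[(pos >= 0) & (pos < n_pairs)]] = True
    out[: pos[0] + 1] = rot[0]
    for a in range(len(pos) - 1):
        t = np.arange(pos[a], pos[a + 1] + 1)
        out[t] = circular_interp_deg(t, pos[a], rot[a], pos[a + 1], rot[a + 1])
    out[pos[-1]:] = rot[-1]
    return RotationSeries(wrap_deg(out), landmark)
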