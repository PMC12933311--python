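"""Synthetic paired-pullback generator with known ground truth.

The phantom emulates the *annotations* a feature-extraction stage would
produce for a coronary segment imaged by both IVUS and OCT — not the images
themselves. A common ground-truth vessel is defined analytically:

    r(s, theta) = base * (1 - taper * s / L) * (1 + ecc(s) * cos 2*theta)

i.e. a tapering tube with a smoothly varying elliptical cross-section, on
which side-branch ostia and calcium deposits are placed at random,
non-overlapping arc-length intervals. Two acquisitions sample this vessel:

* IVUS: end-diastolic frames every 0.5 mm (the 0.5 mm/s pullback gated at
  ~1 Hz heart rate), with optional residual longitudinal jitter emulating
  cardiac catheter motion that ED gating does not fully remove;
* OCT: frames every 0.2 mm (36 mm/s at 180 fps), each rotated by a Gaussian
  random-walk drift phi_j emulating catheter twist (NURD), with all angular
  annotations — contour orientation, branch angles, calcium arcs — rotated
  accordingly.

Contour vertices receive additive radial noise, and each branch/calcium
annotation can be dropped per frame with a configurable probability,
standing in for feature-extraction misses. The true frame correspondence
and per-frame OCT rotation are returned alongside, so every registration
stage can be scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .angles import wrap_deg
from .errors import PhantomConfigError
from .pullback import BranchBox, CalciumArc, Contour, Frame, N_ANGLE_BINS, Pullback

_CONTOUR_POINTS = 96
_BRANCH_EXTENT_MM = 0.8  # longitudinal extent of an ostium
_CALCIUM_EXTENT_MM = (2.0, 5.0)  # deposit length range
_EVENT_GAP_MM = 0.3
_EVENT_MARGIN_MM = 1.0
_ECC_CYCLES = 1.5  # slow eccentricity modulation along the vessel
_CATHETER_OFFSET_SD_MM = 0.15


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one simulated vessel pair.

    Defaults describe a 40 mm segment with moderate annotation noise:
    0.05 mm contour noise, 1 deg/frame rotational drift, 10% feature
    dropout and 0.05 mm residual cardiac jitter.
    """

    length_mm: float = 40.0
    base_radius_mm: float = 1.5
    taper_rate: float = 0.3
    eccentricity_amp: float = 0.15
    n_branches: int = 4
    branch_width_deg: tuple[float, float] = (20.0, 40.0)
    n_calcium: int = 3
    calcium_arc_deg: tuple[float, float] = (30.0, 90.0)
    ivus_frame_spacing_mm: float = 0.5
    ivus_cardiac_jitter_mm: float = 0.05
    oct_frame_spacing_mm: float = 0.2
    drift_step_sd_deg: float = 1.0
    contour_noise_sd_mm: float = 0.05
    feature_dropout_prob: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.length_mm, self.base_radius_mm, self.ivus_frame_spacing_mm,
               self.oct_frame_spacing_mm) <= 0:
            raise PhantomConfigError("lengths and spacings must be positive")
        if not 0 <= self.feature_dropout_prob <= 1:
            raise PhantomConfigError("feature_dropout_prob must be in [0, 1]")
        if not 0 <= self.taper_rate < 1:
            raise PhantomConfigError("taper_rate must be in [0, 1)")
        if not 0 <= self.eccentricity_amp < 1:
            raise PhantomConfigError("eccentricity_amp must be in [0, 1)")
        if self.length_mm < 10 * max(self.ivus_frame_spacing_mm, self.oct_frame_spacing_mm):
            raise PhantomConfigError("length_mm must be >= 10x the larger frame spacing")
        if min(self.ivus_cardiac_jitter_mm, self.drift_step_sd_deg,
               self.contour_noise_sd_mm) < 0:
            raise PhantomConfigError("noise scales must be >= 0")

    def noiseless(self) -> "PhantomConfig":
        """Copy with all noise sources switched off (same vessel geometry)."""
        return replace(
            self,
            ivus_cardiac_jitter_mm=0.0,
            drift_step_sd_deg=0.0,
            contour_noise_sd_mm=0.0,
            feature_dropout_prob=0.0,
        )


@dataclass(frozen=True)
class BranchEvent:
    s_start: float
    s_end: float
    angle_deg: float
    width_deg: float


@dataclass(frozen=True)
class CalciumEvent:
    s_start: float
    s_end: float
    angle_start_deg: float
    arc_deg: float


@dataclass(frozen=True)
class Vessel:
    """Analytic ground-truth vessel shared by both acquisitions."""

    config: PhantomConfig
    ecc_phase_rad: float
    branches: tuple[BranchEvent, ...]
    calcium: tuple[CalciumEvent, ...]

    def eccentricity_at(self, s) -> np.ndarray:
        # smooth modulation within [0.35, 1] x amp: real lumens are never
        # perfectly circular, and a floor keeps the radial profile informative
        cfg = self.config
        mod = 0.5 * (
            1.0 + np.sin(2 * np.pi * _ECC_CYCLES * np.asarray(s) / cfg.length_mm
                         + self.ecc_phase_rad)
        )
        return cfg.eccentricity_amp * (0.35 + 0.65 * mod)

    def radius(self, s, theta_deg) -> np.ndarray:
        """True lumen radius at arc-length s (mm) and angle theta (deg)."""
        cfg = self.config
        th = np.deg2rad(np.asarray(theta_deg, dtype=float))
        return (
            cfg.base_radius_mm
            * (1.0 - cfg.taper_rate * np.asarray(s) / cfg.length_mm)
            * (1.0 + self.eccentricity_at(s) * np.cos(2.0 * th))
        )


@dataclass(frozen=True)
class GroundTruth:
    """True frame positions, OCT rotations and event layout of one phantom."""

    ivus_s: np.ndarray
    oct_s: np.ndarray
    oct_rotation_deg: np.ndarray
    oct_frame_spacing_mm: float
    branches: tuple[BranchEvent, ...] = ()
    calcium: tuple[CalciumEvent, ...] = ()


def _place_events(rng: np.random.Generator, cfg: PhantomConfig):
    """Place branch and calcium intervals uniformly at random, no s-overlap."""
    extents = [_BRANCH_EXTENT_MM] * cfg.n_branches + [
        float(rng.uniform(*_CALCIUM_EXTENT_MM)) for _ in range(cfg.n_calcium)
    ]
    lo, hi = _EVENT_MARGIN_MM, cfg.length_mm - _EVENT_MARGIN_MM
    placed: list[tuple[float, float]] = []
    for attempt_budget, ext in zip([500] * len(extents), extents):
        ok = False
        for _ in range(attempt_budget):
            s0 = float(rng.uniform(lo, hi - ext))
            s1 = s0 + ext
            if all(s1 + _EVENT_GAP_MM <= a or s0 - _EVENT_GAP_MM >= b for a, b in placed):
                placed.append((s0, s1))
                ok = True
                break
        if not ok:
            raise PhantomConfigError(
                "could not place branch/calcium events without overlap; "
                "reduce their number or lengthen the vessel"
            )
    branches = tuple(
        BranchEvent(s0, s1, float(rng.uniform(0, 360)), float(rng.uniform(*cfg.branch_width_deg)))
        for (s0, s1) in placed[: cfg.n_branches]
    )
    calcium = tuple(
        CalciumEvent(s0, s1, float(rng.uniform(0, 360)), float(rng.uniform(*cfg.calcium_arc_deg)))
        for (s0, s1) in placed[cfg.n_branches:]
    )
    return branches, calcium


def make_phantom(cfg: PhantomConfig) -> Vessel:
    """Build the deterministic ground-truth vessel for a configuration."""
    rng = np.random.default_rng([cfg.seed, 0])
    phase = float(rng.uniform(0, 2 * np.pi))
    branches, calcium = _place_events(rng, cfg)
    return Vessel(cfg, phase, branches, calcium)


def _frame_annotations(
    vessel: Vessel,
    s: float,
    rotation_deg: float,
    rng: np.random.Generator,
    cfg: PhantomConfig,
):
    """Contour, branch boxes and calcium arc of one frame.

    ``rotation_deg`` is the catheter twist: a feature at true angle theta
    appears at theta - rotation_deg in the frame, so rotating the frame CCW
    by rotation_deg restores the true orientation.
    """
    offset = rng.normal(0.0, _CATHETER_OFFSET_SD_MM, size=2)

    # random dither of the vertex grid: delineated contours do not share a
    # fixed angular grid across frames or modalities
    dither = float(rng.uniform(0.0, 360.0 / _CONTOUR_POINTS))
    obs_angles = 360.0 * np.arange(_CONTOUR_POINTS) / _CONTOUR_POINTS + dither
    r = vessel.radius(s, obs_angles + rotation_deg)
    if cfg.contour_noise_sd_mm > 0:
        r = r + rng.normal(0.0, cfg.contour_noise_sd_mm, size=r.shape)
    th = np.deg2rad(obs_angles)
    contour = Contour(
        np.stack([offset[0] + r * np.cos(th), offset[1] + r * np.sin(th)], axis=1)
    )

    boxes = []
    for ev in vessel.branches:
        if not (ev.s_start <= s <= ev.s_end):
            continue
        if rng.random() < cfg.feature_dropout_prob:
            continue
        beta = wrap_deg(ev.angle_deg - rotation_deg)
        rb = float(vessel.radius(s, ev.angle_deg))
        side = max(0.3, rb * np.deg2rad(ev.width_deg) / 2.0)
        center = (
            offset[0] + rb * np.cos(np.deg2rad(beta)),
            offset[1] + rb * np.sin(np.deg2rad(beta)),
        )
        boxes.append(BranchBox(center, side, side))

    flags = np.zeros(N_ANGLE_BINS, dtype=np.uint8)
    bin_centers = 2.0 * np.arange(N_ANGLE_BINS) + 1.0
    for ev in vessel.calcium:
        if not (ev.s_start <= s <= ev.s_end):
            continue
        if rng.random() < cfg.feature_dropout_prob:
            continue
        start = ev.angle_start_deg - rotation_deg
        flags |= (np.mod(bin_centers - start, 360.0) < ev.arc_deg).astype(np.uint8)

    return contour, tuple(boxes), CalciumArc(flags)


def acquire_ivus(vessel: Vessel, cfg: PhantomConfig | None = None):
    """Sample the IVUS (end-diastolic) pullback.

    Returns (pullback, true_s): true arc-length per frame, which differs from
    the nominal 0.5 mm grid by the residual cardiac jitter (sorted to keep
    the pullback monotone).
    """
    cfg = cfg or vessel.config
    rng = np.random.default_rng([cfg.seed, 1])
    n = int(np.floor(cfg.length_mm / cfg.ivus_frame_spacing_mm)) + 1
    s = np.arange(n) * cfg.ivus_frame_spacing_mm
    if cfg.ivus_cardiac_jitter_mm > 0:
        s = np.sort(np.clip(s + rng.normal(0, cfg.ivus_cardiac_jitter_mm, n), 0, cfg.length_mm))
        s += np.arange(n) * 1e-9  # break exact ties after clipping
    frames = []
    for i, si in enumerate(s):
        contour, boxes, calc = _frame_annotations(vessel, float(si), 0.0, rng, cfg)
        frames.append(
            Frame("IVUS", i, i * cfg.ivus_frame_spacing_mm, True, contour, boxes, calc)
        )
    return Pullback("IVUS", tuple(frames), cfg.ivus_frame_spacing_mm), s


def acquire_oct(vessel: Vessel, cfg: PhantomConfig | None = None):
    """Sample the OCT pullback.

    Returns (pullback, true_s, rotation_deg): the per-frame catheter twist
    phi_j follows a Gaussian random walk from a uniform start; rotating OCT
    frame j counter-clockwise by phi_j aligns it with the IVUS orientation.
    """
    cfg = cfg or vessel.config
    rng = np.random.default_rng([cfg.seed, 2])
    n = int(np.floor(cfg.length_mm / cfg.oct_frame_spacing_mm)) + 1
    s = np.arange(n) * cfg.oct_frame_spacing_mm
    phi0 = float(rng.uniform(0, 360))
    steps = rng.normal(0, cfg.drift_step_sd_deg, n - 1) if cfg.drift_step_sd_deg > 0 else np.zeros(n - 1)
    phi = wrap_deg(phi0 + np.concatenate([[0.0], np.cumsum(steps)]))
    frames = []
    for j, sj in enumerate(s):
        contour, boxes, calc = _frame_annotations(vessel, float(sj), float(phi[j]), rng, cfg)
        frames.append(Frame("OCT", j, float(sj), True, contour, boxes, calc))
    return Pullback("OCT", tuple(frames), cfg.oct_frame_spacing_mm), s, phi


def true_correspondence(gt: GroundTruth):
    """True continuous OCT index and rotation per IVUS frame.

    The OCT index of IVUS frame i is (s_i - s_oct[0]) / spacing, clamped to
    the OCT range; the true rotation is read at the nearest OCT frame.
    """
    idx = (gt.ivus_s - gt.oct_s[0]) / gt.oct_frame_spacing_mm
    idx = np.clip(idx, 0.0, len(gt.oct_s) - 1.0)
    nearest = np.clip(np.round(idx).astype(int), 0, len(gt.oct_s) - 1)
    return idx, gt.oct_rotation_deg[nearest]


def simulate(cfg: PhantomConfig):
    """End-to-end phantom: (ivus_pullback, oct_pullback, ground_truth)."""
    vessel = make_phantom(cfg)
    ivus, ivus_s = acquire_ivus(vessel, cfg)
    oct_pb, oct_s, phi = acquire_oct(vessel, cfg)
    gt = GroundTruth(
        ivus_s, oct_s, phi, cfg.oct_frame_spacing_mm, vessel.branches, vessel.calcium
    )
    return ivus, oct_pb, gt
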