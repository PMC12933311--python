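"""Domain model for annotated intravascular pullbacks.

A *pullback* is the ordered stack of cross-sectional frames acquired as an
imaging catheter (IVUS or OCT) is withdrawn through a coronary vessel. Each
frame carries the annotations the co-registration pipeline consumes: a closed
lumen contour in catheter-centered mm coordinates, rectangular side-branch
bounding boxes, and a 180-bin calcium arc (one binary flag per 2 degrees of
circumference around the lumen centroid).

This module also provides the geometric primitives every later stage builds
on: polygon area and centroid, the centroid-anchored radial profile sampled
in 2-degree increments, lumen eccentricity, calcium fraction and total
side-branch area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidContourError, InvalidPullbackError, ParameterError

N_ANGLE_BINS = 180  #: circumferential bins, 2 degrees each

# Acquisition arithmetic. The OCT catheter is pulled back at a fixed speed
# while frames are acquired at a fixed rate, which fixes the inter-frame
# spacing; analysis then retains every second OCT frame.
OCT_PULLBACK_SPEED_MM_S = 36.0
OCT_FRAME_RATE_HZ = 180.0
IVUS_PULLBACK_SPEED_MM_S = 0.5


def frame_spacing_from_speed(speed_mm_s: float, frame_rate_hz: float) -> float:
    """Inter-frame spacing (mm) of a constant-speed pullback."""
    if speed_mm_s <= 0 or frame_rate_hz <= 0:
        raise ParameterError("speed and frame rate must be positive")
    return speed_mm_s / frame_rate_hz


def analysis_interval_mm(frame_spacing_mm: float, retain_every: int = 2) -> float:
    """Longitudinal interval between retained analysis frames (mm)."""
    if retain_every < 1:
        raise ParameterError("retain_every must be >= 1")
    return frame_spacing_mm * retain_every


def segment_length_mm(n_analysis_frames: int, interval_mm: float) -> float:
    """Length of a segment covered by ``n_analysis_frames`` at a fixed interval."""
    return n_analysis_frames * interval_mm


@dataclass(frozen=True)
class Contour:
    """Closed lumen polygon: ordered (x, y) vertices in mm, last joins first."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidContourError("contour points must be an (N, 2) array")
        if pts.shape[0] < 3:
            raise InvalidContourError(
                f"contour needs >= 3 points, got {pts.shape[0]}"
            )
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class BranchBox:
    """Axis-aligned bounding box of a side-branch ostium (mm)."""

    center: tuple[float, float]
    width: float
    height: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ParameterError("branch box width and height must be > 0")

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class CalciumArc:
    """Binary calcium presence per 2-degree bin around the lumen centroid.

    Bin ``b`` covers [2b, 2b+2) degrees counter-clockwise from the +x axis.
    """

    flags: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.flags)
        if f.shape != (N_ANGLE_BINS,):
            raise ParameterError(
                f"calcium arc needs exactly {N_ANGLE_BINS} flags, got {f.shape}"
            )
        if not np.isin(f, (0, 1)).all():
            raise ParameterError("calcium flags must be 0 or 1")
        object.__setattr__(self, "flags", f.astype(np.uint8))

    @classmethod
    def empty(cls) -> "CalciumArc":
        return cls(np.zeros(N_ANGLE_BINS, dtype=np.uint8))


@dataclass(frozen=True)
class Frame:
    """One cross-section's annotations."""

    modality: str  # "IVUS" | "OCT"
    index: int
    position_mm: float
    is_ed: bool
    lumen: Contour
    branches: tuple[BranchBox, ...] = ()
    calcium: CalciumArc = field(default_factory=CalciumArc.empty)

    def __post_init__(self):
        if self.modality not in ("IVUS", "OCT"):
            raise InvalidPullbackError(f"unknown modality {self.modality!r}")
        if self.index < 0:
            raise InvalidPullbackError("frame index must be >= 0")
        object.__setattr__(self, "branches", tuple(self.branches))


@dataclass(frozen=True)
class Pullback:
    """Ordered stack of frames of a single modality."""

    modality: str
    frames: tuple[Frame, ...]
    frame_spacing_mm: float

    def __post_init__(self):
        frames = tuple(self.frames)
        if len(frames) < 2:
            raise InvalidPullbackError("a pullback needs >= 2 frames")
        if self.frame_spacing_mm <= 0:
            raise InvalidPullbackError("frame spacing must be > 0")
        for f in frames:
            if f.modality != self.modality:
                raise InvalidPullbackError(
                    f"frame {f.index} modality {f.modality} != pullback {self.modality}"
                )
        idx = np.array([f.index for f in frames])
        pos = np.array([f.position_mm for f in frames])
        if len(np.unique(idx)) != len(idx):
            raise InvalidPullbackError("frame indices must be unique")
        if not (np.diff(pos) > 0).all():
            raise InvalidPullbackError("frame positions must be strictly increasing")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions_mm(self) -> np.ndarray:
        return np.array([f.position_mm for f in self.frames])

    @property
    def indices(self) -> np.ndarray:
        return np.array([f.index for f in self.frames])


# ---------------------------------------------------------------------------
# Geometric primitives
# ---------------------------------------------------------------------------

def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def contour_area(c: Contour) -> float:
    """Enclosed area of the lumen polygon (shoelace formula), mm^2."""
    a = _signed_area(c.points)
    if a == 0.0:
        raise InvalidContourError("contour has zero signed area")
    return abs(a)


def contour_centroid(c: Contour) -> tuple[float, float]:
    """Area-weighted centroid of the lumen polygon, mm."""
    pts = c.points
    a = _signed_area(pts)
    if a == 0.0:
        raise InvalidContourError("centroid undefined for zero-area contour")
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    cx = float(np.sum((x + xn) * cross) / (6.0 * a))
    cy = float(np.sum((y + yn) * cross) / (6.0 * a))
    return (cx, cy)


def radial_profile(c: Contour, n_bins: int = N_ANGLE_BINS) -> np.ndarray:
    """Centroid-to-boundary distance along each angular bin-center ray.

    Bin ``b`` covers [b*w, (b+1)*w) degrees (w = 360/n_bins) counter-clockwise
    from +x; the sampling ray points along the bin center (b + 0.5)*w. The
    distance is found by ray/polygon-edge intersection. Lumens are expected to
    be star-shaped about their centroid; if a ray misses the boundary (highly
    non-convex contour) the nearest vertex within that angular bin is used
    instead and a warning is emitted.

    Returns an array of ``n_bins`` positive radii in mm.
    """
    if n_bins < 4:
        raise ParameterError("n_bins must be >= 4")
    cen = contour_centroid(c)
    pts = c.points - np.asarray(cen)

    width = 360.0 / n_bins
    theta = np.deg2rad((np.arange(n_bins) + 0.5) * width)
    d = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # (B, 2)

    p1 = pts
    e = np.roll(pts, -1, axis=0) - pts  # (N, 2) edge vectors

    # Ray origin + t*d = p1 + u*e; solve with 2D cross products, broadcast B x N.
    denom = d[:, None, 0] * e[None, :, 1] - d[:, None, 1] * e[None, :, 0]
    cross_p_e = p1[None, :, 0] * e[None, :, 1] - p1[None, :, 1] * e[None, :, 0]
    cross_p_d = p1[None, :, 0] * d[:, None, 1] - p1[None, :, 1] * d[:, None, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross_p_e / denom
        u = cross_p_d / denom
    # small slack on u so rays passing exactly through a vertex still hit
    valid = (np.abs(denom) > 1e-300) & (t > 1e-12) & (u >= -1e-9) & (u < 1.0 + 1e-9)
    t = np.where(valid, t, np.inf)
    radii = t.min(axis=1)

    missed = ~np.isfinite(radii)
    if missed.any():
        warnings.warn(
            "contour is not star-shaped about its centroid; "
            "falling back to nearest-vertex distance in affected bins",
            RuntimeWarning,
            stacklevel=2,
        )
        vert_ang = np.rad2deg(np.arctan2(pts[:, 1], pts[:, 0])) % 360.0
        vert_r = np.linalg.norm(pts, axis=1)
        vert_bin = np.floor(vert_ang / width).astype(int) % n_bins
        for b in np.flatnonzero(missed):
            in_bin = vert_bin == b
            radii[b] = vert_r[in_bin].min() if in_bin.any() else vert_r.min()
    return radii


def eccentricity(profile: np.ndarray) -> float:
    """Lumen eccentricity from a radial profile: (max - min) / max, in [0, 1)."""
    r = np.asarray(profile, dtype=float)
    if (r <= 0).any():
        raise ParameterError("radial profile must be strictly positive")
    rmax = r.max()
    return float((rmax - r.min()) / rmax)


def calcium_fraction(arc: CalciumArc) -> float:
    """Proportion of the circumference labelled calcified, in [0, 1]."""
    return float(np.mean(arc.flags))


def branch_area_total(frame: Frame) -> float:
    """Summed side-branch bounding-box area of a frame, mm^2 (0 if none)."""
    return float(sum(b.area for b in frame.branches))


def rotate_frame(frame: Frame, delta_deg: float) -> Frame:
    """Rigidly rotate a frame's annotations CCW by ``delta_deg`` about the origin.

    The calcium arc is a binned signal, so ``delta_deg`` must be a multiple
    of the 2-degree bin width for the rotation to be representable exactly.
    """
    bin_width = 360.0 / N_ANGLE_BINS
    shift, rem = divmod(delta_deg, bin_width)
    if abs(rem) > 1e-9 and abs(rem - bin_width) > 1e-9:
        raise ParameterError(
            f"delta_deg must be a multiple of {bin_width} degrees to rotate calcium bins"
        )
    th = np.deg2rad(delta_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    contour = Contour(frame.lumen.points @ rot.T)
    branches = tuple(
        BranchBox(tuple(rot @ np.asarray(b.center)), b.width, b.height)
        for b in frame.branches
    )
    calcium = CalciumArc(np.roll(frame.calcium.flags, int(round(shift)) % N_ANGLE_BINS))
    return Frame(
        frame.modality, frame.index, frame.position_mm, frame.is_ed,
        contour, branches, calcium,
    )


def regular_polygon(radius: float, n: int = 64, center=(0.0, 0.0)) -> Contour:
    """Convenience: a regular n-gon contour approximating a circle."""
    th = 2 * np.pi * np.arange(n) / n
    pts = np.stack([center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)], axis=1)
    return Contour(pts)
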