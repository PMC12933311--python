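"""Shared fixtures: small hand-built pullbacks and star-shaped polygons."""

import numpy as np
import pytest

from ivoctreg.pullback import (
    BranchBox,
    CalciumArc,
    Contour,
    Frame,
    N_ANGLE_BINS,
    Pullback,
)


def star_polygon(radii: np.ndarray, phase_deg: float = 0.0, center=(0.0, 0.0)) -> Contour:
    """Polygon with given radii at evenly spaced angles (star-shaped by construction)."""
    radii = np.asarray(radii, dtype=float)
    th = np.deg2rad(360.0 * np.arange(len(radii)) / len(radii) + phase_deg)
    pts = np.stack(
        [center[0] + radii * np.cos(th), center[1] + radii * np.sin(th)], axis=1
    )
    return Contour(pts)


def make_frame(
    modality="IVUS",
    index=0,
    position=0.0,
    is_ed=True,
    radius=1.5,
    n_pts=48,
    branches=(),
    calc_bins=(),
    center=(0.0, 0.0),
):
    """A circular-lumen frame with optional branch boxes and calcium bins."""
    contour = star_polygon(np.full(n_pts, radius), center=center)
    flags = np.zeros(N_ANGLE_BINS, dtype=int)
    flags[list(calc_bins)] = 1
    return Frame(
        modality, index, position, is_ed, contour,
        tuple(branches), CalciumArc(flags),
    )


@pytest.fixture
def small_ivus():
    """5-frame IVUS pullback with varying lumen size, one branch, some calcium."""
    frames = []
    radii = [1.0, 1.3, 1.6, 1.3, 1.0]
    for i, r in enumerate(radii):
        branches = (BranchBox((r, 0.0), 0.5, 0.5),) if i == 2 else ()
        calc = range(10, 30) if i >= 3 else ()
        frames.append(
            make_frame("IVUS", i, 0.5 * i, True, r, branches=branches, calc_bins=calc)
        )
    return Pullback("IVUS", tuple(frames), 0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
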