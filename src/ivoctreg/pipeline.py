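"""End-to-end co-registration: feature signals -> DTW -> rotational DP.

`coregister` ties the stages together for one IVUS/OCT pullback pair:

1. build the four-channel feature sequences (normalize, smooth, down-sample);
2. DTW over the feature-weighted distance matrix, then expand the path to a
   continuous OCT frame index per IVUS analysis (end-diastolic) frame;
3. select landmark pairs (side branch or calcium visible in both frames),
   build the rotation cost matrix from circular-profile NCC, run the
   shape-regularized DP, and circularly interpolate rotations to all pairs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .circumferential import (
    circular_profile,
    dp_rotation_path,
    interpolate_rotations,
    rotation_cost_row,
    select_landmark_pairs,
)
from .config import RunConfig
from .dtw import AlignmentPath, distance_matrix, dtw, expand_alignment
from .features import build_feature_sequence
from .pullback import Pullback


@dataclass(frozen=True)
class CoregistrationResult:
    """Longitudinal map and rotation per IVUS analysis frame."""

    ivus_frames: np.ndarray  # original IVUS frame indices (the ED frames)
    oct_frame_continuous: np.ndarray  # matched continuous OCT original index
    rotation_deg: np.ndarray  # OCT rotation (deg CCW) aligning each pair
    is_landmark: np.ndarray
    is_path_node: np.ndarray
    path: AlignmentPath
    oct_retained: np.ndarray
    stage_seconds: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ivus_frames)


def coregister(
    ivus: Pullback, oct_pb: Pullback, config: RunConfig | None = None
) -> CoregistrationResult:
    """Register an OCT pullback to an IVUS pullback of the same vessel."""
    cfg = config or RunConfig()
    if ivus.modality != "IVUS" or oct_pb.modality != "OCT":
        raise ValueError("coregister expects (IVUS pullback, OCT pullback)")
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    seq_i = build_feature_sequence(ivus, cfg.sigma_frames)
    seq_o = build_feature_sequence(oct_pb, cfg.sigma_frames)
    timings["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    D = distance_matrix(seq_i, seq_o, cfg.dtw_weights)
    path = dtw(D, band=cfg.dtw_band)
    full_map = expand_alignment(path, seq_i.retained_indices, seq_o.retained_indices)
    timings["longitudinal"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    idx_by_original = {f.index: f for f in ivus.frames}
    ivus_frames = [idx_by_original[i] for i in seq_i.retained_indices]
    oct_frames = list(oct_pb.frames)
    landmarks = select_landmark_pairs(full_map, ivus_frames, oct_frames, cfg.landmark_rule)
    rows = np.stack(
        [
            rotation_cost_row(
                circular_profile(ivus_frames[ipos]),
                circular_profile(oct_frames[oj]),
                cfg.ncc_channel_weights,
            )
            for (_, ipos, oj) in landmarks
        ]
    )
    rotations = dp_rotation_path(rows, cfg.lambda_shape, cfg.max_step_deg)
    series = interpolate_rotations(
        np.array([p for (p, _, _) in landmarks]), rotations, len(full_map)
    )
    timings["circumferential"] = time.perf_counter() - t0

    on_path = np.zeros(len(full_map), dtype=bool)
    on_path[np.unique(path.pairs[:, 0])] = True
    return CoregistrationResult(
        ivus_frames=seq_i.retained_indices,
        oct_frame_continuous=full_map,
        rotation_deg=series.rotation_deg,
        is_landmark=series.landmark,
        is_path_node=on_path,
        path=path,
        oct_retained=seq_o.retained_indices,
        stage_seconds=timings,
    )
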