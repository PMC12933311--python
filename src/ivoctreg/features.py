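"""Longitudinal feature signals feeding the DTW stage.

Four features are extracted per frame of each pullback: lumen area and total
side-branch area (both normalized by the maximum lumen area observed in that
vessel, so they land in [0, 1]), degree of calcification (fraction of the
circumference labelled calcified), and normalized frame position. The three
geometric channels are Gaussian-smoothed along the pullback axis so a
landmark missed on one frame still leaves signal on its neighbours; the
position channel is left untouched because it must stay strictly monotone.
The smoothed sequences are then down-sampled — IVUS to its end-diastolic
frames, OCT to every second frame — and the position channel is recomputed
over the retained frames so both modalities span [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import InvalidPullbackError, ParameterError
from .pullback import Pullback, branch_area_total, calcium_fraction, contour_area

FEATURE_NAMES = ("lumen_area_norm", "branch_area_norm", "calc_fraction", "position_norm")
POSITION_CHANNEL = 3  # never smoothed


@dataclass(frozen=True)
class FeatureSequence:
    """Down-sampled four-channel feature sequence of one pullback."""

    modality: str
    vectors: np.ndarray  # (M, 4)
    retained_indices: np.ndarray  # original frame indices, strictly increasing
    sigma_frames: float

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        r = np.asarray(self.retained_indices, dtype=int)
        if v.ndim != 2 or v.shape[1] != 4:
            raise ParameterError("feature vectors must be (M, 4)")
        if len(v) != len(r):
            raise ParameterError("vectors and retained_indices length mismatch")
        if not (np.diff(r) > 0).all():
            raise ParameterError("retained_indices must be strictly increasing")
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "retained_indices", r)

    def __len__(self) -> int:
        return len(self.vectors)


def raw_features(pullback: Pullback) -> np.ndarray:
    """Per-frame feature matrix (N, 4), before smoothing or down-sampling.

    Lumen and branch areas are both scaled by the maximum lumen area in the
    pullback; position is i/(N-1) over all frames.
    """
    areas = np.array([contour_area(f.lumen) for f in pullback.frames])
    max_area = areas.max()
    if max_area <= 0:
        raise InvalidPullbackError("maximum lumen area is zero")
    branch = np.array([branch_area_total(f) for f in pullback.frames])
    calc = np.array([calcium_fraction(f.calcium) for f in pullback.frames])
    n = len(pullback)
    pos = np.arange(n) / (n - 1)
    return np.stack([areas / max_area, branch / max_area, calc, pos], axis=1)


def gaussian_smooth(signal: np.ndarray, sigma_frames: float) -> np.ndarray:
    """Smooth a 1-D signal with a truncated (±4σ), renormalized Gaussian kernel.

    The signal is reflect-padded at both ends; sigma 0 is the identity. The
    kernel is a convex combination, so output values stay within the input's
    [min, max] range.
    """
    if sigma_frames < 0:
        raise ParameterError("sigma_frames must be >= 0")
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 1:
        raise ParameterError("signal must be a non-empty 1-D array")
    if sigma_frames == 0:
        return x.copy()
    return gaussian_filter1d(x, sigma=sigma_frames, mode="reflect", truncate=4.0)


def smooth_features(features: np.ndarray, sigma_frames: float) -> np.ndarray:
    """Smooth the three geometric channels; leave the position channel alone."""
    out = np.asarray(features, dtype=float).copy()
    for ch in range(out.shape[1]):
        if ch != POSITION_CHANNEL:
            out[:, ch] = gaussian_smooth(out[:, ch], sigma_frames)
    return out


def downsample(pullback: Pullback, features: np.ndarray, sigma_frames: float = 0.0) -> FeatureSequence:
    """Down-sample per-frame features to the analysis grid of the modality.

    IVUS keeps its end-diastolic frames; OCT keeps every second frame starting
    at 0. The position channel is recomputed as i/(M-1) over the retained
    frames so both modalities express relative progress along the segment.
    """
    features = np.asarray(features, dtype=float)
    if len(features) != len(pullback):
        raise ParameterError("features and pullback length mismatch")
    if pullback.modality == "IVUS":
        keep = np.array([i for i, f in enumerate(pullback.frames) if f.is_ed], dtype=int)
    else:
        keep = np.arange(0, len(pullback), 2)
    if len(keep) < 2:
        raise InvalidPullbackError(
            f"{pullback.modality} pullback retains {len(keep)} frames; need >= 2"
        )
    vecs = features[keep].copy()
    vecs[:, POSITION_CHANNEL] = np.arange(len(keep)) / (len(keep) - 1)
    retained = pullback.indices[keep]
    return FeatureSequence(pullback.modality, vecs, retained, sigma_frames)


def build_feature_sequence(pullback: Pullback, sigma_frames: float = 2.0) -> FeatureSequence:
    """Full feature stage: raw features -> smoothing -> down-sampling."""
    feats = smooth_features(raw_features(pullback), sigma_frames)
    return downsample(pullback, feats, sigma_frames)
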