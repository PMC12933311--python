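"""Observer-agreement statistics for co-registration estimates.

Given two (or three) per-frame correspondence estimates — e.g. two expert
analysts and an automated method — this module computes the evaluation suite
used to judge registration quality: median (IQR) frame and angle differences,
Lin's concordance correlation coefficient, Spearman rank correlation, the
Williams Index with a jackknife 95% CI, Bland–Altman bias and limits of
agreement, and a Wilcoxon signed-rank comparison of paired difference
series.

The Williams Index compares an algorithm's mean disagreement with each of
two experts against the experts' disagreement with each other; WI > 1 means
the algorithm is closer to the experts than they are to one another.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .angles import circular_abs_diff_deg
from .errors import ParameterError, UndefinedMetricError

OCT_FRAME_TO_MM = 0.2  # inter-frame spacing in OCT


def _paired(a, b, name="series"):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError(f"{name} must be 1-D and the same length")
    return a, b


def frame_differences(map_a, map_b) -> np.ndarray:
    """Per-frame absolute difference between two OCT-index maps, in frames."""
    a, b = _paired(map_a, map_b, "frame maps")
    return np.abs(a - b)


def angle_differences(rot_a, rot_b) -> np.ndarray:
    """Per-frame circular absolute difference between rotations, in [0, 180] deg."""
    a, b = _paired(rot_a, rot_b, "rotation series")
    return circular_abs_diff_deg(a, b)


def median_iqr(values) -> tuple[float, float, float]:
    """Median and interquartile bounds (25th, 75th percentile)."""
    v = np.asarray(values, dtype=float)
    return (float(np.median(v)), float(np.percentile(v, 25)), float(np.percentile(v, 75)))


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient, population (1/n) moments.

    2*cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2), in [-1, 1].
    """
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ParameterError("lin_ccc needs length >= 3")
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0:
        raise UndefinedMetricError("lin_ccc undefined when both series are constant")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    return float(2 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2))


def spearman_r(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ParameterError("spearman_r needs length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("spearman_r undefined for a constant series")
    return float(stats.spearmanr(x, y).statistic)


def mean_abs_disagreement(a, b, circular: bool = False) -> float:
    """Mean absolute difference between two series (circular degrees optional)."""
    d = angle_differences(a, b) if circular else frame_differences(a, b)
    return float(np.mean(d))


def williams_index(
    model,
    expert1,
    expert2,
    circular: bool = False,
    groups=None,
) -> tuple[float, tuple[float, float]]:
    """Williams Index of a model against two experts, with 95% jackknife CI.

    Disagreement is the mean absolute difference (circular for angles):

        WI = 0.5 * (1/D(M,E1) + 1/D(M,E2)) / (1/D(E1,E2))

    The CI is a delete-one jackknife over ``groups`` (e.g. the vessel each
    frame belongs to, matching the per-vessel structure of a test set); with
    no groups, each observation is its own jackknife unit.
    """
    m = np.asarray(model, dtype=float)
    e1 = np.asarray(expert1, dtype=float)
    e2 = np.asarray(expert2, dtype=float)
    if not (m.shape == e1.shape == e2.shape) or m.ndim != 1:
        raise ParameterError("all three series must be 1-D and the same length")

    def wi(mask):
        d_me1 = mean_abs_disagreement(m[mask], e1[mask], circular)
        d_me2 = mean_abs_disagreement(m[mask], e2[mask], circular)
        d_ee = mean_abs_disagreement(e1[mask], e2[mask], circular)
        if d_me1 == 0 or d_me2 == 0 or d_ee == 0:
            raise UndefinedMetricError(
                "Williams Index undefined under perfect pairwise agreement"
            )
        return 0.5 * (1.0 / d_me1 + 1.0 / d_me2) * d_ee

    full = wi(np.ones(len(m), dtype=bool))
    groups = np.zeros(0) if groups is None else np.asarray(groups)
    units = np.arange(len(m)) if groups.size == 0 else np.unique(groups)
    labels = np.arange(len(m)) if groups.size == 0 else groups
    if len(units) < 2:
        return full, (full, full)
    reps = []
    for u in units:
        mask = labels != u
        if mask.sum() >= 2:
            reps.append(wi(mask))
    reps = np.asarray(reps)
    g = len(reps)
    ps = g * full - (g - 1) * reps  # pseudo-values
    se = float(np.std(ps, ddof=1) / np.sqrt(g))
    return full, (full - 1.96 * se, full + 1.96 * se)


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bland–Altman bias and 95% limits of agreement (bias ± 1.96 sample sd)."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ParameterError("bland_altman needs length >= 3")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def wilcoxon_signed_rank(diff_a, diff_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired difference series.

    Zero differences are dropped; ties get mid-ranks; the exact null
    distribution (2^n sign assignments) is enumerated for n <= 25, the
    normal approximation with continuity correction is used beyond.
    """
    a, b = _paired(diff_a, diff_b, "difference series")
    d = a - b
    d = d[d != 0]
    if len(d) < 6:
        raise UndefinedMetricError(
            "wilcoxon_signed_rank needs >= 6 nonzero paired differences"
        )
    method = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between two correspondence estimates over the same frames."""

    n_frames: int
    median_frame_diff: float
    frame_diff_iqr: tuple[float, float]
    median_frame_diff_mm: float
    median_angle_diff_deg: float | None
    angle_diff_iqr: tuple[float, float] | None
    ccc_frames: float
    spearman_frames: float
    bland_altman_frames: tuple[float, float, float]

    def to_dict(self) -> dict:
        return asdict(self)


def compare_estimates(map_a, map_b, rot_a=None, rot_b=None) -> AgreementReport:
    """Full pairwise agreement report between two co-registration estimates."""
    fd = frame_differences(map_a, map_b)
    fmed, flo, fhi = median_iqr(fd)
    amed = aiqr = None
    if rot_a is not None and rot_b is not None:
        ad = angle_differences(rot_a, rot_b)
        amed, alo, ahi = median_iqr(ad)
        aiqr = (alo, ahi)
    return AgreementReport(
        n_frames=len(fd),
        median_frame_diff=fmed,
        frame_diff_iqr=(flo, fhi),
        median_frame_diff_mm=fmed * OCT_FRAME_TO_MM,
        median_angle_diff_deg=amed,
        angle_diff_iqr=aiqr,
        ccc_frames=lin_ccc(map_a, map_b),
        spearman_frames=spearman_r(map_a, map_b),
        bland_altman_frames=bland_altman(map_a, map_b),
    )
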