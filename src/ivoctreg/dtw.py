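"""Longitudinal frame matching by dynamic time warping.

The two down-sampled feature sequences (IVUS end-diastolic frames vs every
second OCT frame) are compared with a feature-weighted Euclidean distance,
accumulated into the classic DTW cost matrix with symmetric unit-weight
steps (diagonal, down, right) and full boundary constraints, and the optimal
monotone path is recovered by backtracking from the last cell. The raw path
may match one IVUS frame to several OCT frames; `expand_alignment` collapses
it to a functional map — one continuous OCT frame index per IVUS frame — by
averaging, which mirrors how interpolation between manually matched sections
assigns an OCT frame to every IVUS cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .features import FeatureSequence

#: default feature weights (lumen, branch, calcium, position)
DEFAULT_WEIGHTS = (1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class AlignmentPath:
    """Monotone DTW path in retained-sequence coordinates plus its cost."""

    pairs: np.ndarray  # (L, 2) int: (ivus_retained_pos, oct_retained_pos)
    total_cost: float

    def __post_init__(self):
        p = np.asarray(self.pairs, dtype=int)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ParameterError("path pairs must be (L, 2)")
        object.__setattr__(self, "pairs", p)


def weighted_euclidean(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> float:
    """sqrt(sum_k w_k (u_k - v_k)^2) with nonnegative weights, at least one > 0."""
    w = np.asarray(w, dtype=float)
    if (w < 0).any() or not (w > 0).any():
        raise ParameterError("weights must be nonnegative with at least one > 0")
    d = np.asarray(u, dtype=float) - np.asarray(v, dtype=float)
    return float(np.sqrt(np.sum(w * d * d)))


def distance_matrix(
    a: FeatureSequence | np.ndarray,
    b: FeatureSequence | np.ndarray,
    weights=DEFAULT_WEIGHTS,
) -> np.ndarray:
    """Pairwise feature-weighted Euclidean distances, shape (n, m)."""
    ua = a.vectors if isinstance(a, FeatureSequence) else np.asarray(a, dtype=float)
    ub = b.vectors if isinstance(b, FeatureSequence) else np.asarray(b, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or not (w > 0).any():
        raise ParameterError("weights must be nonnegative with at least one > 0")
    diff = ua[:, None, :] - ub[None, :, :]
    return np.sqrt(np.einsum("ijk,k->ij", diff * diff, w))


def dtw(D: np.ndarray, band: float | None = None) -> AlignmentPath:
    """Minimal-cost monotone alignment of the two sequences behind ``D``.

    Accumulates C[i, j] = D[i, j] + min(C[i-1, j-1], C[i-1, j], C[i, j-1])
    with C[0, 0] = D[0, 0], then backtracks from (n-1, m-1). Ties prefer the
    diagonal predecessor, then (i-1, j), making the path deterministic.

    ``band`` optionally restricts cells to a Sakoe–Chiba corridor of that
    half-width around the rescaled diagonal.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] < 2 or D.shape[1] < 2:
        raise ParameterError("distance matrix must be at least 2x2")
    if not np.isfinite(D).all():
        raise ParameterError("distance matrix contains non-finite entries")
    n, m = D.shape

    allowed = np.ones((n, m), dtype=bool)
    if band is not None:
        if band < 0:
            raise ParameterError("band must be >= 0")
        jj = np.arange(m)[None, :]
        diag = np.arange(n)[:, None] * (m - 1) / (n - 1)
        allowed = np.abs(jj - diag) <= band
        allowed[0, 0] = allowed[n - 1, m - 1] = True

    C = np.full((n, m), np.inf)
    # predecessor code: 0 diagonal, 1 up (i-1, j), 2 left (i, j-1), -1 none
    pred = np.full((n, m), -1, dtype=np.int8)
    C[0, 0] = D[0, 0]
    for i in range(n):
        for j in range(m):
            if (i, j) == (0, 0) or not allowed[i, j]:
                continue
            best, code = np.inf, -1
            if i > 0 and j > 0 and C[i - 1, j - 1] < best:
                best, code = C[i - 1, j - 1], 0
            if i > 0 and C[i - 1, j] < best:
                best, code = C[i - 1, j], 1
            if j > 0 and C[i, j - 1] < best:
                best, code = C[i, j - 1], 2
            if code >= 0:
                C[i, j] = D[i, j] + best
                pred[i, j] = code
    if not np.isfinite(C[n - 1, m - 1]):
        raise ParameterError("no feasible path (band too narrow)")

    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        code = pred[i, j]
        if code == 0:
            i, j = i - 1, j - 1
        elif code == 1:
            i = i - 1
        else:
            j = j - 1
        path.append((i, j))
    return AlignmentPath(np.array(path[::-1]), float(C[n - 1, m - 1]))


def expand_alignment(
    path: AlignmentPath | np.ndarray,
    ivus_retained: np.ndarray,
    oct_retained: np.ndarray,
) -> np.ndarray:
    """Continuous OCT frame index (original units) per retained IVUS frame.

    Where an IVUS frame appears in several path pairs, its matched OCT
    original indices are averaged; any retained IVUS position absent from the
    path (possible only under exotic step restrictions) is filled by linear
    interpolation in original frame index. The result is non-decreasing.
    """
    pairs = path.pairs if isinstance(path, AlignmentPath) else np.asarray(path, dtype=int)
    ivus_retained = np.asarray(ivus_retained, dtype=int)
    oct_retained = np.asarray(oct_retained, dtype=int)
    n = len(ivus_retained)
    full = np.full(n, np.nan)
    for i in range(n):
        matched = pairs[pairs[:, 0] == i, 1]
        if len(matched):
            full[i] = float(np.mean(oct_retained[matched]))
    missing = np.isnan(full)
    if missing.any():
        have = np.flatnonzero(~missing)
        full[missing] = np.interp(ivus_retained[missing], ivus_retained[have], full[have])
    return np.maximum.accumulate(full)
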