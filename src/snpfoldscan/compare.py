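"""Locate the interval where two base-pair probability ensembles differ most.

The structural difference between wild-type and mutant is scored per
sequence interval [i, j], counting only base pairs with *both* endpoints
inside the interval (local regions are self-contained structures):

* Euclidean distance  d(i,j) = sqrt( sum_{i<=k<l<=j} (pwt_kl - pmut_kl)^2 ),
  maximized.  d is monotone non-decreasing under interval inclusion.
* Pearson correlation r(i,j) over the cells where max(pwt, pmut) clears a
  probability floor, minimized; intervals with fewer than 3 qualifying
  cells or zero variance are not scorable.

All intervals are scored in O(n^2) total via the inclusion-exclusion
recurrence  T[i,j] = T[i+1,j] + T[i,j-1] - T[i+1,j-1] + A[i,j]  applied to
per-cell summands, instead of recomputing every interval from scratch.
A direct per-interval recomputation is kept as the brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fold import PairProbMatrix

DISTANCE = "distance"
CORRELATION = "correlation"

#: default minimum reported interval length (nt)
DEFAULT_MIN_LEN = 50

#: default probability floor for the correlation measure
DEFAULT_PROB_FLOOR = 0.01

#: default fixed window length for the two-step local scan (nt)
DEFAULT_FIXED_LEN = 120

_BRUTE_GUARD = 80
_VAR_EPS = 1e-24


class NoScorableInterval(ValueError):
    """Every candidate interval was skipped (correlation measure only)."""


@dataclass(frozen=True)
class IntervalScore:
    """A local region [start, end] (1-based inclusive) with its score."""

    start: int
    end: int
    measure: str
    score: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _check_pair(P_wt: PairProbMatrix, P_mut: PairProbMatrix) -> int:
    if P_wt.n != P_mut.n:
        raise ValueError(f"matrix size mismatch: {P_wt.n} vs {P_mut.n}")
    return P_wt.n


def triangle_cumsum(A: np.ndarray) -> np.ndarray:
    """T[i, j] = sum of A[k, l] over all i <= k < l <= j (upper triangle)."""
    n = A.shape[0]
    T = np.zeros((n, n))
    for d in range(1, n):
        i = np.arange(0, n - d)
        j = i + d
        T[i, j] = A[i, j] + T[i + 1, j] + T[i, j - 1] - T[i + 1, j - 1]
    return T


def _pick_best(score: np.ndarray, valid: np.ndarray, maximize: bool) -> tuple[int, int]:
    """Tie-break: best score, then shortest interval, then smallest start."""
    masked = np.where(valid, score, -np.inf if maximize else np.inf)
    best = masked.max() if maximize else masked.min()
    if not np.isfinite(best):
        raise NoScorableInterval("no scorable interval")
    cand = np.argwhere(masked == best)
    lengths = cand[:, 1] - cand[:, 0]
    order = np.lexsort((cand[:, 0], lengths))
    i, j = cand[order[0]]
    return int(i), int(j)


def _interval_mask(n: int, min_len: int) -> np.ndarray:
    if min_len < 1 or min_len > n:
        raise ValueError(f"min_len ({min_len}) must be in [1, {n}]")
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return (jj - ii + 1) >= min_len


def distance_landscape(P_wt: PairProbMatrix, P_mut: PairProbMatrix) -> np.ndarray:
    """d(i, j) for every interval, as an upper-triangular matrix (0-based)."""
    _check_pair(P_wt, P_mut)
    delta2 = np.triu((P_wt.p - P_mut.p) ** 2, k=1)
    return np.sqrt(np.maximum(triangle_cumsum(delta2), 0.0))


def interval_scan_distance(
    P_wt: PairProbMatrix,
    P_mut: PairProbMatrix,
    min_len: int = DEFAULT_MIN_LEN,
    return_landscape: bool = False,
):
    """Interval maximizing the Euclidean distance between the ensembles."""
    n = _check_pair(P_wt, P_mut)
    D = distance_landscape(P_wt, P_mut)
    i, j = _pick_best(D, _interval_mask(n, min_len), maximize=True)
    result = IntervalScore(i + 1, j + 1, DISTANCE, float(D[i, j]))
    return (result, D) if return_landscape else result


def correlation_landscape(
    P_wt: PairProbMatrix,
    P_mut: PairProbMatrix,
    prob_floor: float = DEFAULT_PROB_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """(r matrix, scorable mask) for every interval.

    r(i, j) is the Pearson correlation of the wild-type and mutant
    probability vectors over qualifying cells inside [i, j]; intervals
    with < 3 qualifying cells or zero variance are flagged unscorable.
    """
    _check_pair(P_wt, P_mut)
    n = P_wt.n
    tri = np.triu(np.ones((n, n), dtype=bool), k=1)
    qual = tri & (np.maximum(P_wt.p, P_mut.p) >= prob_floor)
    x = np.where(qual, P_wt.p, 0.0)
    y = np.where(qual, P_mut.p, 0.0)
    cnt = triangle_cumsum(qual.astype(float))
    sx = triangle_cumsum(x)
    sy = triangle_cumsum(y)
    sxx = triangle_cumsum(x * x)
    syy = triangle_cumsum(y * y)
    sxy = triangle_cumsum(x * y)
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = cnt * sxx - sx * sx
        vy = cnt * syy - sy * sy
        cov = cnt * sxy - sx * sy
        r = cov / np.sqrt(vx * vy)
    scorable = (cnt >= 3) & (vx > _VAR_EPS) & (vy > _VAR_EPS)
    r = np.where(scorable, np.clip(r, -1.0, 1.0), np.nan)
    return r, scorable


def interval_scan_correlation(
    P_wt: PairProbMatrix,
    P_mut: PairProbMatrix,
    min_len: int = DEFAULT_MIN_LEN,
    prob_floor: float = DEFAULT_PROB_FLOOR,
) -> IntervalScore:
    """Interval minimizing the Pearson correlation between the ensembles.

    Raises :class:`NoScorableInterval` if no interval qualifies.
    """
    n = _check_pair(P_wt, P_mut)
    r, scorable = correlation_landscape(P_wt, P_mut, prob_floor)
    valid = _interval_mask(n, min_len) & scorable
    i, j = _pick_best(np.where(scorable, r, np.inf), valid, maximize=False)
    return IntervalScore(i + 1, j + 1, CORRELATION, float(r[i, j]))


def two_step_scan(
    P_wt: PairProbMatrix,
    P_mut: PairProbMatrix,
    fixed_len: int = DEFAULT_FIXED_LEN,
    min_len: int = DEFAULT_MIN_LEN,
) -> tuple[IntervalScore, IntervalScore]:
    """Two-step localization on locally folded matrices (distance measure).

    Step 1 scores every interval of length exactly ``fixed_len`` (stride 1)
    and keeps the maximum; step 2 rescans all sub-intervals of that winner
    with length >= ``min_len``.  Returns (step2, step1) scores, both in
    whole-matrix 1-based coordinates.  A matrix shorter than ``fixed_len``
    degrades to the single interval [1, n] in step 1.
    """
    n = _check_pair(P_wt, P_mut)
    D = distance_landscape(P_wt, P_mut)
    if n <= fixed_len:
        s1, e1 = 0, n - 1
    else:
        starts = np.arange(0, n - fixed_len + 1)
        scores = D[starts, starts + fixed_len - 1]
        s1 = int(starts[np.argmax(scores)])  # argmax: first = smallest start
        e1 = s1 + fixed_len - 1
    step1 = IntervalScore(s1 + 1, e1 + 1, DISTANCE, float(D[s1, e1]))

    sub_n = e1 - s1 + 1
    eff_min = min(min_len, sub_n)
    sub = D[s1 : e1 + 1, s1 : e1 + 1]
    i, j = _pick_best(sub, _interval_mask(sub_n, eff_min), maximize=True)
    step2 = IntervalScore(s1 + i + 1, s1 + j + 1, DISTANCE, float(sub[i, j]))
    return step2, step1


def brute_force_scan(
    P_wt: PairProbMatrix,
    P_mut: PairProbMatrix,
    min_len: int = DEFAULT_MIN_LEN,
    measure: str = DISTANCE,
    prob_floor: float = DEFAULT_PROB_FLOOR,
) -> IntervalScore:
    """Direct per-interval recomputation (test oracle; guarded at 80 nt).

    Applies the same qualification rules and tie-breaking as the DP scans.
    """
    n = _check_pair(P_wt, P_mut)
    if n > _BRUTE_GUARD:
        raise ValueError(f"brute-force oracle guarded at {_BRUTE_GUARD} nt, got {n}")
    if min_len < 1 or min_len > n:
        raise ValueError(f"min_len ({min_len}) must be in [1, {n}]")
    best: IntervalScore | None = None
    maximize = measure == DISTANCE
    for i in range(n):
        for j in range(i + min_len - 1, n):
            cells_i, cells_j = np.triu_indices(j - i + 1, k=1)
            x = P_wt.p[i + cells_i, i + cells_j]
            y = P_mut.p[i + cells_i, i + cells_j]
            if measure == DISTANCE:
                score = float(np.sqrt(np.sum((x - y) ** 2)))
            elif measure == CORRELATION:
                keep = np.maximum(x, y) >= prob_floor
                xs, ys = x[keep], y[keep]
                if xs.size < 3:
                    continue
                m = xs.size
                vx = m * np.sum(xs * xs) - np.sum(xs) ** 2
                vy = m * np.sum(ys * ys) - np.sum(ys) ** 2
                if vx <= _VAR_EPS or vy <= _VAR_EPS:
                    continue
                score = float(
                    np.clip((m * np.sum(xs * ys) - np.sum(xs) * np.sum(ys))
                            / np.sqrt(vx * vy), -1.0, 1.0)
                )
            else:
                raise ValueError(f"unknown measure {measure!r}")
            cand = IntervalScore(i + 1, j + 1, measure, score)
            if best is None:
                best = cand
                continue
            key_new = (-cand.score if maximize else cand.score,
                       cand.length, cand.start)
            key_old = (-best.score if maximize else best.score,
                       best.length, best.start)
            if key_new < key_old:
                best = cand
    if best is None:
        raise NoScorableInterval("no scorable interval")
    return best
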