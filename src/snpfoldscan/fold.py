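"""Ensemble folding: global and windowed-local base-pair probabilities.

The global fold is a McCaskill-style partition function over all
pseudoknot-free structures under the package's internal nearest-neighbor
model (:mod:`snpfoldscan.energy`), with pair probabilities from the
outside recursion.  The local fold averages window-restricted global
folds in the sliding-window convention of plfold-type tools: every
length-W window is folded independently and the probability of a pair is
the mean over all windows that contain both partners, with pairs whose
span reaches the max-span cutoff reported as zero.

A pluggable backend interface lets an external folding engine (e.g. the
Vienna RNA package, via :mod:`snpfoldscan.vienna`) stand in for the
internal model where compatibility with its energy parameters matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from . import _kernels
from .energy import DEFAULT_MODEL, EnergyModel, encode
from .sequences import RnaSequence

#: probabilities below this are clamped to zero when *writing* outputs;
#: comparison measures always use unclamped values
OUTPUT_CLAMP = 1e-8


@dataclass
class PairProbMatrix:
    """Upper-triangular ensemble base-pair probabilities for one sequence.

    ``p[i, j]`` (0-based, i < j) is the Boltzmann probability that bases
    i and j pair; the lower triangle and diagonal are zero.
    """

    n: int
    p: np.ndarray

    def __post_init__(self) -> None:
        if self.p.shape != (self.n, self.n):
            raise ValueError(f"matrix shape {self.p.shape} != ({self.n}, {self.n})")

    @classmethod
    def zeros(cls, n: int) -> "PairProbMatrix":
        return cls(n, np.zeros((n, n)))

    def get(self, i: int, j: int) -> float:
        """Probability for 1-based positions i < j."""
        if not (1 <= i < j <= self.n):
            raise IndexError(f"pair ({i}, {j}) outside 1 <= i < j <= {self.n}")
        return float(self.p[i - 1, j - 1])

    def pairing_mass(self) -> np.ndarray:
        """Per-position total pairing probability (length-n vector)."""
        return self.p.sum(axis=0) + self.p.sum(axis=1)

    def clamped(self, floor: float = OUTPUT_CLAMP) -> np.ndarray:
        out = self.p.copy()
        out[out < floor] = 0.0
        return out


@runtime_checkable
class FoldBackend(Protocol):
    """Anything that can produce a base-pair probability matrix."""

    name: str

    def global_probs(self, seq: RnaSequence) -> PairProbMatrix: ...


class InternalBackend:
    """Partition-function folding under the package's internal model."""

    def __init__(self, model: EnergyModel | None = None):
        self.model = model or DEFAULT_MODEL
        self.name = self.model.name

    def global_probs(self, seq: RnaSequence) -> PairProbMatrix:
        return global_pair_probabilities(seq, self.model)


def _kernel_args(model: EnergyModel):
    return (
        model.pair_type, model.stack, model.hairpin, model.internal,
        model.kT, model.min_hairpin, model.maxloop,
        model.ml_close, model.ml_branch, model.ml_unpaired,
    )


def partition_function(seq: RnaSequence, model: EnergyModel | None = None) -> float:
    """Total Boltzmann sum Q over all structures (open chain included)."""
    model = (model or DEFAULT_MODEL).sized_for(len(seq))
    s = encode(seq.bases)
    _, _, _, qf, _ = _kernels.inside(s, *_kernel_args(model))
    return float(qf[len(seq)])


def global_pair_probabilities(
    seq: RnaSequence, model: EnergyModel | None = None
) -> PairProbMatrix:
    """Ensemble pair probabilities from the inside/outside recursions.

    A sequence with no admissible pair (or too short to close a hairpin)
    folds to the open chain only: the matrix is all zero.
    """
    model = (model or DEFAULT_MODEL).sized_for(len(seq))
    n = len(seq)
    if n < model.min_hairpin + 2:
        return PairProbMatrix.zeros(n)
    s = encode(seq.bases)
    pt, stack, hairpin, internal, kT, h, maxloop, a, b, c = _kernel_args(model)
    qb, qm, qm1, qf, qr = _kernels.inside(
        s, pt, stack, hairpin, internal, kT, h, maxloop, a, b, c
    )
    prob = _kernels.outside(
        s, pt, stack, internal, kT, h, maxloop, a, b, c, qb, qm, qf, qr
    )
    return PairProbMatrix(n, prob)


def local_pair_probabilities(
    seq: RnaSequence,
    model: EnergyModel | None = None,
    window: int = 200,
    max_span: int = 120,
    backend: FoldBackend | None = None,
) -> PairProbMatrix:
    """Sliding-window local pair probabilities.

    Every window of ``window`` nt (stride 1; truncated to the sequence if
    it is shorter) is folded globally, and p(i, j) is averaged over the
    windows containing both i and j.  Pairs with span ``j - i >= max_span``
    are reported as zero.  With ``window >= n`` and ``max_span >= n`` this
    reduces exactly to the global fold.
    """
    if max_span < 1:
        raise ValueError("max_span must be >= 1")
    if window < max_span:
        raise ValueError(f"window ({window}) must be >= max_span ({max_span})")
    n = len(seq)
    W = min(window, n)
    if backend is None:
        backend = InternalBackend(model)
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for start in range(0, n - W + 1):
        sub = seq.subsequence(start + 1, start + W)
        pm = backend.global_probs(sub)
        acc[start : start + W, start : start + W] += pm.p
        cnt[start : start + W, start : start + W] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(cnt > 0, acc / np.maximum(cnt, 1.0), 0.0)
    # span cutoff: pairs at distance >= max_span are outside the local model
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    avg[jj - ii >= max_span] = 0.0
    return PairProbMatrix(n, avg)


# ---------------------------------------------------------------------------
# MFE structure (display output)

_TRACE_TOL = 1e-6


def mfe_structure(
    seq: RnaSequence, model: EnergyModel | None = None
) -> tuple[str, float]:
    """Minimum-free-energy structure in dot-bracket notation, with energy.

    Ties are broken toward the first decomposition found (outermost pair
    first, then leftmost inner pair), which makes the output deterministic.
    """
    model = (model or DEFAULT_MODEL).sized_for(len(seq))
    n = len(seq)
    if n < model.min_hairpin + 2:
        return "." * n, 0.0
    s = encode(seq.bases)
    pt, stack, hairpin, internal, kT, h, maxloop, a, b, c = _kernel_args(model)
    vb, vm, vm1, f = _kernels.mfe_tables(
        s, pt, stack, hairpin, internal, kT, h, maxloop, a, b, c
    )
    pairs: list[tuple[int, int]] = []

    def close(x: float, y: float) -> bool:
        return np.isfinite(x) and np.isfinite(y) and abs(x - y) <= _TRACE_TOL

    def trace_vb(i: int, j: int) -> None:
        pairs.append((i, j))
        target = vb[i, j]
        if close(target, hairpin[j - i - 1]):
            return
        kmax = min(i + maxloop + 1, j - h - 2)
        for k in range(i + 1, kmax + 1):
            l1 = k - i - 1
            lmin = max(k + h + 1, j - 1 - (maxloop - l1))
            for l in range(lmin, j):
                if not np.isfinite(vb[k, l]):
                    continue
                l2 = j - l - 1
                if l1 == 0 and l2 == 0:
                    e = stack[pt[s[i], s[j]], pt[s[k], s[l]]]
                else:
                    e = internal[l1, l2]
                if close(target, e + vb[k, l]):
                    trace_vb(k, l)
                    return
        for u in range(i + 2, j):
            if close(target, a + b + vm[i + 1, u - 1] + vm1[u, j - 1]):
                trace_vm(i + 1, u - 1)
                trace_vm1(u, j - 1)
                return
        raise AssertionError(f"MFE traceback failed at pair ({i}, {j})")

    def trace_vm1(i: int, j: int) -> None:
        target = vm1[i, j]
        for l in range(i + h + 1, j + 1):
            if close(target, vb[i, l] + b + c * (j - l)):
                trace_vb(i, l)
                return
        raise AssertionError(f"MFE traceback failed in vm1 ({i}, {j})")

    def trace_vm(i: int, j: int) -> None:
        target = vm[i, j]
        for u in range(i, j + 1):
            if not np.isfinite(vm1[u, j]):
                continue
            if close(target, c * (u - i) + vm1[u, j]):
                trace_vm1(u, j)
                return
            if u > i and close(target, vm[i, u - 1] + vm1[u, j]):
                trace_vm(i, u - 1)
                trace_vm1(u, j)
                return
        raise AssertionError(f"MFE traceback failed in vm ({i}, {j})")

    # exterior walk, right to left
    j = n
    while j > 0:
        if close(f[j], f[j - 1]) or f[j] == f[j - 1]:
            j -= 1
            continue
        done = False
        for k in range(0, j - 1 - h):
            if close(f[j], f[k] + vb[k, j - 1]):
                trace_vb(k, j - 1)
                j = k
                done = True
                break
        if not done:
            raise AssertionError(f"MFE traceback failed in exterior at {j}")

    db = ["."] * n
    for i, jj in pairs:
        db[i] = "("
        db[jj] = ")"
    return "".join(db), float(f[n])
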