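"""Exhaustive structure enumeration — the independent cross-check for the
partition-function recursions.

Enumerates every pseudoknot-free structure of a short sequence (guarded at
14 nt), evaluates each by explicit loop decomposition under the same
energy model the DP kernels use, and derives Boltzmann weights and pair
probabilities by brute-force summation.  The code path shares nothing
with :mod:`snpfoldscan._kernels` beyond the energy tables themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .energy import DEFAULT_MODEL, EnergyModel
from .fold import PairProbMatrix
from .sequences import RnaSequence

MAX_ENUM_LENGTH = 14


@dataclass(frozen=True)
class EnumeratedStructure:
    pairs: frozenset[tuple[int, int]]  # 0-based (i, j), i < j
    energy: float
    weight: float  # exp(-E/kT), unnormalized

    def dot_bracket(self, n: int) -> str:
        db = ["."] * n
        for i, j in self.pairs:
            db[i], db[j] = "(", ")"
        return "".join(db)


def _all_pairings(
    bases: str, i: int, j: int, model: EnergyModel, memo: dict
) -> list[frozenset[tuple[int, int]]]:
    """All pseudoknot-free pair sets on [i, j] (inclusive, 0-based)."""
    if j - i < model.min_hairpin + 1:
        return [frozenset()]
    key = (i, j)
    if key in memo:
        return memo[key]
    # base i unpaired
    result = list(_all_pairings(bases, i + 1, j, model, memo))
    # base i paired with k
    for k in range(i + model.min_hairpin + 1, j + 1):
        if not model.can_pair(bases[i], bases[k]):
            continue
        for inner in _all_pairings(bases, i + 1, k - 1, model, memo):
            for outer in _all_pairings(bases, k + 1, j, model, memo):
                result.append(inner | outer | {(i, k)})
    memo[key] = result
    return result


def structure_energy(
    bases: str, pairs: frozenset[tuple[int, int]], model: EnergyModel
) -> float:
    """Loop-decomposition energy of an explicit structure.

    Returns +inf for structures the model excludes (interior loops larger
    than the model's cap), matching the DP ensemble exactly.
    """
    by_open = sorted(pairs)
    total = 0.0
    for (i, j) in by_open:
        # direct children: pairs immediately enclosed by (i, j)
        children = []
        k = i + 1
        open_at = {p[0]: p for p in by_open}
        while k < j:
            if k in open_at and open_at[k][1] < j:
                children.append(open_at[k])
                k = open_at[k][1] + 1
            else:
                k += 1
        if not children:
            total += model.hairpin_energy(j - i - 1)
        elif len(children) == 1:
            (k, l) = children[0]
            l1, l2 = k - i - 1, j - l - 1
            e = model.interior_energy(
                l1, l2, model.pair_code(bases[i], bases[j]),
                model.pair_code(bases[k], bases[l]),
            )
            if not math.isfinite(e):
                return math.inf
            total += e
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            total += model.multiloop_energy(len(children) + 1, unpaired)
    return total


def enumerate_structures(
    seq: RnaSequence, model: EnergyModel | None = None
) -> list[EnumeratedStructure]:
    """Every admissible structure with its energy and Boltzmann weight.

    Structures the model excludes (infinite energy) are dropped; the open
    chain (no pairs, energy 0, weight 1) is always present.
    """
    model = model or DEFAULT_MODEL
    n = len(seq)
    if n > MAX_ENUM_LENGTH:
        raise ValueError(
            f"enumeration is guarded at {MAX_ENUM_LENGTH} nt, got {n}"
        )
    out = []
    for pairs in _all_pairings(seq.bases, 0, n - 1, model, {}):
        e = structure_energy(seq.bases, pairs, model)
        if math.isfinite(e):
            out.append(EnumeratedStructure(pairs, e, math.exp(-e / model.kT)))
    return out


def enumerated_partition_function(
    seq: RnaSequence, model: EnergyModel | None = None
) -> float:
    return sum(s.weight for s in enumerate_structures(seq, model))


def enumerated_pair_probabilities(
    seq: RnaSequence, model: EnergyModel | None = None
) -> PairProbMatrix:
    """Pair probabilities by direct Boltzmann-weighted summation."""
    structures = enumerate_structures(seq, model)
    n = len(seq)
    Z = sum(s.weight for s in structures)
    p = np.zeros((n, n))
    for s in structures:
        for (i, j) in s.pairs:
            p[i, j] += s.weight
    p /= Z
    return PairProbMatrix(n, p)


def enumerated_mfe(
    seq: RnaSequence, model: EnergyModel | None = None
) -> tuple[str, float]:
    structures = enumerate_structures(seq, model)
    best = min(structures, key=lambda s: (s.energy, s.dot_bracket(len(seq))))
    return best.dot_bracket(len(seq)), best.energy


def count_structures(seq: RnaSequence, model: EnergyModel | None = None) -> int:
    """Number of admissible pair sets (independent combinatorial recount)."""
    model = model or DEFAULT_MODEL

    def count(i: int, j: int) -> int:
        if j - i < model.min_hairpin + 1:
            return 1
        total = count(i + 1, j)
        for k in range(i + model.min_hairpin + 1, j + 1):
            if model.can_pair(seq.bases[i], seq.bases[k]):
                total += count(i + 1, k - 1) * count(k + 1, j)
        return total

    return count(0, len(seq) - 1)
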