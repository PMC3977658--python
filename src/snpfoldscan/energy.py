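"""Internal nearest-neighbor energy model for secondary-structure ensembles.

The model scores a pseudoknot-free structure by its loop decomposition:

* stacked pairs get a sequence-dependent stacking free energy,
* hairpin loops an initiation penalty growing logarithmically in size,
* bulges and internal loops a size-dependent penalty plus an asymmetry
  term, capped at a total loop size of ``MAXLOOP`` unpaired bases (larger
  interior loops are excluded from the ensemble, the convention of all
  practical folding implementations),
* multiloops a linear model ``a + b * branches + c * unpaired`` where the
  closing pair counts as a branch,
* exterior (unpaired ends, helices hanging off the open chain) is free.

Admissible pairs are the Watson-Crick pairs plus the GU wobble.  The
constants are plausible 37 degC nearest-neighbor values in kcal/mol; the
model deliberately omits dangling ends, coaxial stacking and
tetraloop/terminal-mismatch bonuses, so its energies are *not* those of a
full Turner-2004 implementation.  Everything downstream (partition
function, enumeration oracle, MFE) uses this one definition, which is what
makes the exhaustive-enumeration cross-check exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: base encoding used by the folding kernels
BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: pair-type encoding, 0 = not pairable (ViennaRNA-style ordering)
PAIR_TYPES = ["", "CG", "GC", "GU", "UG", "AU", "UA"]
N_PAIR_TYPES = 7

#: maximum number of unpaired bases in a bulge or internal loop
MAXLOOP = 30

#: minimum unpaired bases enclosed by a hairpin pair
MIN_HAIRPIN = 3

#: kT at 37 degC in kcal/mol
KT_37 = 0.6163

# Stacking free energies dG37 (kcal/mol) for 5'-ij-3' paired over 3'-kl-5',
# indexed [outer pair type][inner pair type].  Watson-Crick block follows
# the standard nearest-neighbor hierarchy (GC/CG stacks strongest); wobble
# entries are weaker, with the destabilizing UG/GU tandem kept positive.
_STACK = {
    ("CG", "CG"): -3.3, ("CG", "GC"): -2.4, ("CG", "GU"): -1.4,
    ("CG", "UG"): -2.1, ("CG", "AU"): -2.1, ("CG", "UA"): -2.1,
    ("GC", "CG"): -3.4, ("GC", "GC"): -3.3, ("GC", "GU"): -1.5,
    ("GC", "UG"): -2.5, ("GC", "AU"): -2.4, ("GC", "UA"): -2.2,
    ("GU", "CG"): -2.5, ("GU", "GC"): -2.1, ("GU", "GU"): -0.5,
    ("GU", "UG"): +1.3, ("GU", "AU"): -1.3, ("GU", "UA"): -1.4,
    ("UG", "CG"): -1.5, ("UG", "GC"): -1.4, ("UG", "GU"): +0.3,
    ("UG", "UG"): -0.5, ("UG", "AU"): -1.0, ("UG", "UA"): -0.6,
    ("AU", "CG"): -2.2, ("AU", "GC"): -2.1, ("AU", "GU"): -0.6,
    ("AU", "UG"): -1.4, ("AU", "AU"): -0.9, ("AU", "UA"): -1.1,
    ("UA", "CG"): -2.4, ("UA", "GC"): -2.1, ("UA", "GU"): -1.0,
    ("UA", "UG"): -1.3, ("UA", "AU"): -1.3, ("UA", "UA"): -0.9,
}

# Loop initiation penalties by number of unpaired bases (kcal/mol).
_HAIRPIN_INIT = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_INIT = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_INIT = {2: 4.1, 3: 5.1, 4: 4.9, 5: 5.3, 6: 5.7}

#: Jacobson-Stockmayer extrapolation coefficient (1.75 * kT at 37 degC)
_LXC = 1.75 * KT_37

#: internal-loop asymmetry penalty per unpaired-base difference, capped
_ASYM_PENALTY = 0.5
_ASYM_MAX = 3.0

# multiloop linear model (closing pair counts as one branch)
_ML_CLOSE = 3.4   # a
_ML_BRANCH = 0.4  # b
_ML_UNPAIRED = 0.1  # c


def _extrapolate(table: dict[int, float], size: int, ref: int) -> float:
    if size in table:
        return table[size]
    return table[ref] + _LXC * math.log(size / ref)


@dataclass
class EnergyModel:
    """Tabulated energy model ready for the folding kernels.

    All arrays are indexed so the numba kernels can use them directly:
    ``pair_type[a, b]`` maps encoded bases to a pair-type code (0 =
    unpairable), ``stack[pt_outer, pt_inner]`` to a stacking energy, and
    the loop arrays to size-indexed penalties.  ``max_size`` bounds the
    hairpin table; :meth:`sized_for` grows it on demand.
    """

    kT: float = KT_37
    min_hairpin: int = MIN_HAIRPIN
    maxloop: int = MAXLOOP
    ml_close: float = _ML_CLOSE
    ml_branch: float = _ML_BRANCH
    ml_unpaired: float = _ML_UNPAIRED
    max_size: int = 1024
    name: str = "internal-nn-v1"

    pair_type: np.ndarray = field(init=False, repr=False)
    stack: np.ndarray = field(init=False, repr=False)
    hairpin: np.ndarray = field(init=False, repr=False)
    internal: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        pt = np.zeros((4, 4), dtype=np.int64)
        for code, pair in enumerate(PAIR_TYPES):
            if pair:
                pt[BASE_INDEX[pair[0]], BASE_INDEX[pair[1]]] = code
        self.pair_type = pt

        st = np.full((N_PAIR_TYPES, N_PAIR_TYPES), np.inf)
        for (outer, inner), e in _STACK.items():
            st[PAIR_TYPES.index(outer), PAIR_TYPES.index(inner)] = e
        self.stack = st

        self.hairpin = self._hairpin_table(self.max_size)

        # internal[l1, l2]: l1, l2 >= 0, l1 + l2 <= maxloop, (0, 0) unused
        internal = np.full((self.maxloop + 1, self.maxloop + 1), np.inf)
        for l1 in range(self.maxloop + 1):
            for l2 in range(self.maxloop + 1):
                total = l1 + l2
                if total == 0 or total > self.maxloop:
                    continue
                if l1 == 0 or l2 == 0:
                    internal[l1, l2] = _extrapolate(_BULGE_INIT, total, 6)
                else:
                    e = _extrapolate(_INTERNAL_INIT, total, 6)
                    e += min(_ASYM_MAX, _ASYM_PENALTY * abs(l1 - l2))
                    internal[l1, l2] = e
        self.internal = internal

    def _hairpin_table(self, max_size: int) -> np.ndarray:
        hp = np.full(max_size + 1, np.inf)
        for size in range(self.min_hairpin, max_size + 1):
            hp[size] = _extrapolate(_HAIRPIN_INIT, size, 9)
        return hp

    def sized_for(self, n: int) -> "EnergyModel":
        """Return a model whose hairpin table covers sequences of length n."""
        if n <= self.max_size:
            return self
        grown = EnergyModel(
            kT=self.kT, min_hairpin=self.min_hairpin, maxloop=self.maxloop,
            ml_close=self.ml_close, ml_branch=self.ml_branch,
            ml_unpaired=self.ml_unpaired, max_size=max(n, 2 * self.max_size),
            name=self.name,
        )
        return grown

    # -- loop energies in plain Python (used by the enumeration oracle and
    #    structure evaluation; the kernels read the arrays directly) -------

    def pair_code(self, a: str, b: str) -> int:
        return int(self.pair_type[BASE_INDEX[a], BASE_INDEX[b]])

    def can_pair(self, a: str, b: str) -> bool:
        return self.pair_code(a, b) != 0

    def hairpin_energy(self, size: int) -> float:
        if size < self.min_hairpin:
            return math.inf
        if size >= len(self.hairpin):
            return _extrapolate(_HAIRPIN_INIT, size, 9)
        return float(self.hairpin[size])

    def stack_energy(self, outer: str, inner: str) -> float:
        """outer/inner are two-character pair strings, e.g. 'GC' over 'CG'."""
        return float(self.stack[PAIR_TYPES.index(outer), PAIR_TYPES.index(inner)])

    def interior_energy(self, l1: int, l2: int, outer_code: int, inner_code: int) -> float:
        """Energy of the loop between an outer pair and its single inner pair."""
        if l1 == 0 and l2 == 0:
            return float(self.stack[outer_code, inner_code])
        if l1 + l2 > self.maxloop:
            return math.inf
        return float(self.internal[l1, l2])

    def multiloop_energy(self, branches: int, unpaired: int) -> float:
        """branches counts the closing pair plus every inner helix."""
        return self.ml_close + self.ml_branch * branches + self.ml_unpaired * unpaired


def encode(bases: str) -> np.ndarray:
    """Encode an A/C/G/U string for the folding kernels."""
    return np.fromiter((BASE_INDEX[b] for b in bases), dtype=np.int64, count=len(bases))


DEFAULT_MODEL = EnergyModel()
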