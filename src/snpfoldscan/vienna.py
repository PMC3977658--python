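"""Compatibility folding backend on top of the Vienna RNA package.

The internal model is self-contained and oracle-verified, but its
energies are not those of the full Turner parameterization used by the
established folding engines.  Where agreement with results produced by
those engines matters (e.g. re-running published worked examples), this
backend swaps the partition-function fold for ViennaRNA's, behind the
same :class:`~snpfoldscan.fold.FoldBackend` interface.

Requires the ``RNA`` python bindings; import errors surface only when the
backend is actually constructed.
"""

from __future__ import annotations

import numpy as np

from .fold import PairProbMatrix
from .sequences import RnaSequence


def vienna_available() -> bool:
    try:
        import RNA  # noqa: F401
    except ImportError:
        return False
    return True


class ViennaBackend:
    """Global ensemble pair probabilities from ViennaRNA's partition function."""

    def __init__(self) -> None:
        import RNA

        self._RNA = RNA
        self.name = f"viennarna-{RNA.__version__}"

    def global_probs(self, seq: RnaSequence) -> PairProbMatrix:
        RNA = self._RNA
        fc = RNA.fold_compound(seq.bases)
        fc.pf()
        n = len(seq)
        bpp = fc.bpp()  # 1-based, (n+1) x (n+1)
        p = np.zeros((n, n))
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                v = bpp[i][j]
                if v > 0.0:
                    p[i - 1, j - 1] = v
        return PairProbMatrix(n, p)

    def mfe(self, seq: RnaSequence) -> tuple[str, float]:
        fc = self._RNA.fold_compound(seq.bases)
        db, energy = fc.mfe()
        return db, float(energy)
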