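"""False-positive calibration of the substitution screen.

The screen's advertised property is that on a sequence with no biology —
an i.i.d. random sequence drawn from the same family as the null tables —
about 5% of substitutions come out at P < 0.05.  This module runs that
experiment end to end: build the Mode 1 and Mode 2 background tables,
draw an independent random sequence, screen every substitution, and
report the significant fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .background import BackgroundTable, build_background_table, random_sequence
from .compare import DISTANCE
from .modes import ModeParams, mode1_score_fn, mode2_score_fn, run_mode3


@dataclass
class CalibrationResult:
    fraction_significant: float  # of all substitutions, at p < report_cutoff
    n_substitutions: int
    n_significant: int
    sequence_gc: float

    @property
    def percent_significant(self) -> float:
        return 100.0 * self.fraction_significant


def build_screen_tables(
    params: ModeParams,
    N: int,
    seed_mode1: int,
    seed_mode2: int,
    length: int,
    gc: float,
) -> dict[str, BackgroundTable]:
    """Single-stratum Mode 1 + Mode 2 tables at the given (length, gc)."""
    t1 = build_background_table(
        mode1_score_fn(params), DISTANCE, "mode1", N, seed_mode1, [length], [gc]
    )
    t2 = build_background_table(
        mode2_score_fn(params), DISTANCE, "mode2", N, seed_mode2, [length], [gc]
    )
    return {"mode1": t1, "mode2": t2}


def null_screen_calibration(
    seed: int,
    length: int = 100,
    gc: float = 0.5,
    N: int = 500,
    params: ModeParams | None = None,
    tables: dict[str, BackgroundTable] | None = None,
) -> CalibrationResult:
    """Screen all 3*length substitutions of a fresh null sequence.

    ``seed`` deterministically derives three independent streams (Mode 1
    table, Mode 2 table, foreground sequence).  Precomputed ``tables``
    may be passed to amortize table building across calibration runs.
    """
    params = params or ModeParams()
    root = np.random.SeedSequence(seed)
    ss_t1, ss_t2, ss_seq = root.spawn(3)
    if tables is None:
        seed1 = int(ss_t1.generate_state(1)[0] % (2**31))
        seed2 = int(ss_t2.generate_state(1)[0] % (2**31))
        tables = build_screen_tables(params, N, seed1, seed2, length, gc)
    seq = random_sequence(length, gc, np.random.default_rng(ss_seq), "null-foreground")
    hits = run_mode3(seq, params, tables)
    n_subs = 3 * length
    return CalibrationResult(
        fraction_significant=len(hits) / n_subs,
        n_substitutions=n_subs,
        n_significant=len(hits),
        sequence_gc=seq.gc_fraction,
    )
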