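"""The three operation modes.

Mode 1 (short sequences): global partition-function fold of wild-type and
mutant over a flank-bounded region around the mutation, full interval
scan, empirical P-value.

Mode 2 (long sequences): windowed local fold of the same region, then the
two-step localization — fixed-length scan followed by a rescan of the
winner's sub-intervals.

Mode 3 (screen): every one of the 3n possible substitutions is evaluated
with Mode 2; candidates below a permissive screen cutoff are re-scored
with Mode 1, and those below the report cutoff are returned, most
significant first.

All reported coordinates are 1-based inclusive in the coordinates of the
*original* input sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

from .background import BackgroundTable, empirical_pvalue
from .compare import (
    CORRELATION,
    DEFAULT_FIXED_LEN,
    DEFAULT_MIN_LEN,
    DEFAULT_PROB_FLOOR,
    DISTANCE,
    IntervalScore,
    NoScorableInterval,
    interval_scan_correlation,
    interval_scan_distance,
    two_step_scan,
)
from .energy import BASES, EnergyModel
from .fold import (
    FoldBackend,
    InternalBackend,
    global_pair_probabilities,
    local_pair_probabilities,
)
from .sequences import Mutation, MutationSet, RnaSequence, apply_mutations

#: server-style soft cap on Mode 3 input length (warning, not an error)
MODE3_SOFT_CAP = 1000


@dataclass
class ModeParams:
    """Tunable knobs shared by the mode runners.

    flank: nt added on each side of the mutated position(s) to form the
    folding region (default 200).  window/max_span parameterize the local
    fold; fixed_len the first pass of the two-step scan; min_len the
    shortest reportable local region; screen/report cutoffs drive Mode 3.
    """

    measure: str = DISTANCE
    flank: int = 200
    min_len: int = DEFAULT_MIN_LEN
    window: int = 200
    max_span: int = 120
    fixed_len: int = DEFAULT_FIXED_LEN
    prob_floor: float = DEFAULT_PROB_FLOOR
    screen_cutoff: float = 0.2
    report_cutoff: float = 0.05
    model: EnergyModel | None = None
    backend: FoldBackend | None = None

    def __post_init__(self) -> None:
        if self.measure not in (DISTANCE, CORRELATION):
            raise ValueError(f"unknown measure {self.measure!r}")
        for name in ("screen_cutoff", "report_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.flank < 1:
            raise ValueError("flank must be >= 1")

    def fold_backend(self) -> FoldBackend:
        return self.backend or InternalBackend(self.model)


@dataclass(frozen=True)
class SnpEffectResult:
    """One mutation's predicted structural effect."""

    sequence_id: str
    label: str
    mode: int
    w_start: int  # folding region, 1-based inclusive, original coordinates
    w_end: int
    local_start: int  # predicted local region, original coordinates
    local_end: int
    measure: str
    score: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.w_start <= self.local_start <= self.local_end <= self.w_end):
            raise ValueError(
                f"local region [{self.local_start}, {self.local_end}] outside "
                f"folding region [{self.w_start}, {self.w_end}]"
            )
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")


def extract_folding_region(
    seq: RnaSequence, ms: MutationSet, flank: int
) -> tuple[RnaSequence, int]:
    """Flank-bounded region around the mutated positions.

    Returns the subsequence and the offset mapping local to original
    coordinates (original = local + offset).  The region spans
    [max(1, p_min - flank), min(n, p_max + flank)] where p_min/p_max are
    the extreme mutated positions; a compound mutant wider than the flank
    still covers all its positions.
    """
    n = len(seq)
    p_min, p_max = ms.min_position, ms.max_position
    if p_max > n:
        raise ValueError(f"mutation position {p_max} beyond sequence length {n}")
    start = max(1, p_min - flank)
    end = min(n, p_max + flank)
    return seq.subsequence(start, end), start - 1


def _scan(P_wt, P_mut, params: ModeParams, region_len: int) -> IntervalScore:
    eff_min = min(params.min_len, region_len)
    if params.measure == DISTANCE:
        return interval_scan_distance(P_wt, P_mut, eff_min)
    try:
        return interval_scan_correlation(P_wt, P_mut, eff_min, params.prob_floor)
    except NoScorableInterval:
        # no cell anywhere clears the floor: structurally featureless —
        # report the weakest possible effect rather than failing the run
        return IntervalScore(1, region_len, CORRELATION, 1.0)


def _mode1_interval(
    wt: RnaSequence, mut: RnaSequence, params: ModeParams
) -> IntervalScore:
    backend = params.fold_backend()
    P_wt = backend.global_probs(wt)
    P_mut = backend.global_probs(mut)
    return _scan(P_wt, P_mut, params, len(wt))


def _mode2_interval(
    wt: RnaSequence, mut: RnaSequence, params: ModeParams
) -> IntervalScore:
    n = len(wt)
    kwargs = dict(
        model=params.model,
        window=params.window,
        max_span=min(params.max_span, params.window),
        backend=params.backend,
    )
    P_wt = local_pair_probabilities(wt, **kwargs)
    P_mut = local_pair_probabilities(mut, **kwargs)
    step2, _ = two_step_scan(
        P_wt, P_mut, params.fixed_len, min(params.min_len, n)
    )
    return step2


def mode1_score_fn(params: ModeParams) -> Callable[[RnaSequence, RnaSequence], float]:
    """Mode-1 statistic as a (wt, mut) -> score function for null sampling."""
    return lambda wt, mut: _mode1_interval(wt, mut, params).score


def mode2_score_fn(params: ModeParams) -> Callable[[RnaSequence, RnaSequence], float]:
    """Mode-2 statistic as a (wt, mut) -> score function for null sampling."""
    return lambda wt, mut: _mode2_interval(wt, mut, params).score


def _result(
    seq: RnaSequence, ms: MutationSet, mode: int, params: ModeParams,
    table: BackgroundTable, interval: IntervalScore,
    region: RnaSequence, offset: int,
) -> SnpEffectResult:
    # stratum lookup: wild-type folding region's length and GC content
    p = empirical_pvalue(interval.score, len(region), region.gc_fraction, table)
    return SnpEffectResult(
        sequence_id=seq.id,
        label=ms.label,
        mode=mode,
        w_start=offset + 1,
        w_end=offset + len(region),
        local_start=offset + interval.start,
        local_end=offset + interval.end,
        measure=interval.measure,
        score=interval.score,
        p_value=p,
    )


def run_mode1(
    seq: RnaSequence, ms: MutationSet, params: ModeParams, table: BackgroundTable
) -> SnpEffectResult:
    """Global-fold analysis of one mutant over the flanked region."""
    region, offset = extract_folding_region(seq, ms, params.flank)
    mut_region, _ = extract_folding_region(apply_mutations(seq, ms), ms, params.flank)
    interval = _mode1_interval(region, mut_region, params)
    return _result(seq, ms, 1, params, table, interval, region, offset)


def run_mode2(
    seq: RnaSequence, ms: MutationSet, params: ModeParams, table: BackgroundTable
) -> SnpEffectResult:
    """Local-fold analysis with two-step localization over the flanked region."""
    region, offset = extract_folding_region(seq, ms, params.flank)
    mut_region, _ = extract_folding_region(apply_mutations(seq, ms), ms, params.flank)
    interval = _mode2_interval(region, mut_region, params)
    return _result(seq, ms, 2, params, table, interval, region, offset)


def all_substitutions(seq: RnaSequence):
    """All 3n single substitutions of a sequence, position order then base."""
    for pos in range(1, len(seq) + 1):
        ref = seq.bases[pos - 1]
        for alt in BASES:
            if alt != ref:
                yield MutationSet((Mutation(pos, ref, alt),))


def run_mode3(
    seq: RnaSequence,
    params: ModeParams,
    tables: dict[str, BackgroundTable],
    warn: Callable[[str], None] | None = None,
) -> list[SnpEffectResult]:
    """Brute-force screen of every possible substitution.

    Every substitution is scored with Mode 2 against ``tables['mode2']``;
    those at or below ``screen_cutoff`` are confirmed with Mode 1 against
    ``tables['mode1']``; confirmations below ``report_cutoff`` are
    returned sorted by P-value, then position.  With ``screen_cutoff = 1``
    this is exactly Mode 1 applied to all 3n substitutions.
    """
    if len(seq) > MODE3_SOFT_CAP and warn is not None:
        warn(
            f"sequence length {len(seq)} exceeds the advisory Mode 3 cap of "
            f"{MODE3_SOFT_CAP} nt; expect long runtimes"
        )
    out: list[SnpEffectResult] = []
    for ms in all_substitutions(seq):
        screened = run_mode2(seq, ms, params, tables["mode2"])
        if screened.p_value <= params.screen_cutoff:
            confirmed = run_mode1(seq, ms, params, tables["mode1"])
            if confirmed.p_value < params.report_cutoff:
                out.append(replace(confirmed, mode=3))
    out.sort(key=lambda r: (r.p_value, r.local_start, r.label))
    return out


def screen_all_substitutions(
    seq: RnaSequence,
    params: ModeParams,
    tables: dict[str, BackgroundTable],
) -> list[tuple[SnpEffectResult, SnpEffectResult | None]]:
    """Mode 3 with full bookkeeping: (mode2 result, mode1 result or None)
    for every substitution, in position order.  Useful for calibration
    studies where the unreported substitutions matter too."""
    rows = []
    for ms in all_substitutions(seq):
        screened = run_mode2(seq, ms, params, tables["mode2"])
        confirmed = None
        if screened.p_value <= params.screen_cutoff:
            confirmed = run_mode1(seq, ms, params, tables["mode1"])
            confirmed = replace(confirmed, mode=3)
        rows.append((screened, confirmed))
    return rows
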