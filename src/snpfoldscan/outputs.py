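"""Standard-format result writers: TSV tables, BED6 tracks, dot-plot records."""

from __future__ import annotations

from typing import Sequence, TextIO

import numpy as np

from .fold import OUTPUT_CLAMP, PairProbMatrix
from .modes import SnpEffectResult
from .sequences import GenomicOrigin

RESULT_COLUMNS = (
    "sequence_id", "mutation", "w_start", "w_end",
    "local_start", "local_end", "measure", "score", "p_value",
)


def write_results_tsv(results: Sequence[SnpEffectResult], stream: TextIO) -> None:
    """One header row plus one row per result, 1-based inclusive coordinates.

    Scores are printed with 4 significant digits minimum; P-values with 4
    decimals, matching the resolution of the empirical null.
    """
    stream.write("\t".join(RESULT_COLUMNS) + "\n")
    for r in results:
        stream.write(
            f"{r.sequence_id}\t{r.label}\t{r.w_start}\t{r.w_end}\t"
            f"{r.local_start}\t{r.local_end}\t{r.measure}\t"
            f"{r.score:.6g}\t{r.p_value:.4f}\n"
        )


def _to_genomic(origin: GenomicOrigin, seq_len: int, start: int, end: int) -> tuple[int, int]:
    """Map a 1-based sequence interval to a 0-based half-open genomic one."""
    if origin.strand == "+":
        return origin.start + start - 2, origin.start + end - 1
    # minus strand: sequence position p sits at genomic start + len - p
    return origin.start + seq_len - end - 1, origin.start + seq_len - start


def write_bed(
    results: Sequence[SnpEffectResult],
    origin: GenomicOrigin,
    seq_len: int,
    stream: TextIO,
) -> None:
    """BED6 track: per result, the mutated site(s) and the local region.

    The score column is round(1000 * (1 - p)) clamped to [0, 1000], so
    strong effects show dark in a genome browser.  Minus-strand intervals
    are mirrored onto the forward genomic strand.
    """
    if origin is None:
        raise ValueError("BED output requires a genomic origin")
    for r in results:
        score = int(np.clip(round(1000 * (1.0 - r.p_value)), 0, 1000))
        # the variant position(s): label tokens carry their own coordinates
        for token in r.label.split("-"):
            pos = int("".join(ch for ch in token if ch.isdigit()))
            gs, ge = _to_genomic(origin, seq_len, pos, pos)
            stream.write(
                f"{origin.chrom}\t{gs}\t{ge}\t{token}\t{score}\t{origin.strand}\n"
            )
        gs, ge = _to_genomic(origin, seq_len, r.local_start, r.local_end)
        stream.write(
            f"{origin.chrom}\t{gs}\t{ge}\t{r.label}:local_region\t{score}\t"
            f"{origin.strand}\n"
        )


def write_dotplot_records(
    P_wt: PairProbMatrix,
    P_mut: PairProbMatrix,
    region: tuple[int, int],
    stream: TextIO,
    clamp: float = OUTPUT_CLAMP,
) -> int:
    """TSV of (i, j, p_wt, p_mut) for rendering a two-triangle dot plot.

    Emits every cell inside ``region`` (1-based inclusive) where either
    probability is positive after clamping tiny values to zero; i < j
    throughout, so the wild-type belongs in the upper and the mutant in
    the lower triangle of a square plot.  Returns the record count.
    """
    if P_wt.n != P_mut.n:
        raise ValueError(f"matrix size mismatch: {P_wt.n} vs {P_mut.n}")
    lo, hi = region
    if not (1 <= lo <= hi <= P_wt.n):
        raise ValueError(f"region {region} outside [1, {P_wt.n}]")
    wt = P_wt.clamped(clamp)
    mut = P_mut.clamped(clamp)
    stream.write("i\tj\tp_wt\tp_mut\n")
    count = 0
    for i in range(lo - 1, hi):
        for j in range(i + 1, hi):
            if wt[i, j] > 0.0 or mut[i, j] > 0.0:
                stream.write(f"{i + 1}\t{j + 1}\t{wt[i, j]:.6g}\t{mut[i, j]:.6g}\n")
                count += 1
    return count


def parse_bed(text: str) -> list[tuple[str, int, int, str, int, str]]:
    """Parse BED6 text back into tuples (round-trip checks and tooling)."""
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, end, name, score, strand = line.split("\t")[:6]
        rows.append((chrom, int(start), int(end), name, int(score), strand))
    return rows
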