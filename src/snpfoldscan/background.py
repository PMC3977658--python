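"""Empirical null distributions of substitution effects.

An observed wild-type/mutant interval score means nothing on its own: the
same statistic computed on random sequences with one random substitution
sets the scale.  Null scores depend strongly on sequence length and GC
content, so they are tabulated per (length bin, GC bin) stratum and an
observed score is converted to an empirical P-value against the nearest
stratum (clamping outside the grid).

Tables are plain TSV with a '#'-prefixed metadata header so they are
human-inspectable, diff-able and exactly regenerable from their recorded
seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, TextIO

import numpy as np

from .compare import CORRELATION, DISTANCE
from .energy import BASES
from .sequences import RnaSequence

MAGIC = "SNPFOLDSCAN-TABLE v1"

#: default stratification grid: folding-window lengths and GC fractions
DEFAULT_LENGTH_BINS = tuple(range(100, 801, 50))
DEFAULT_GC_BINS = tuple(round(0.30 + 0.05 * k, 2) for k in range(9))


class TableFormatError(ValueError):
    """Background-table file is missing, truncated or the wrong version."""


def random_sequence(length: int, gc: float, rng: np.random.Generator,
                    seq_id: str = "random") -> RnaSequence:
    """I.i.d. random RNA: P(G) = P(C) = gc/2, P(A) = P(U) = (1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draw = rng.choice(4, size=length, p=p)
    return RnaSequence(seq_id, "".join(BASES[k] for k in draw))


def random_substitution(seq: RnaSequence, rng: np.random.Generator) -> RnaSequence:
    """One substitution: uniform position, uniform over the 3 other bases."""
    pos = int(rng.integers(0, len(seq)))
    ref = seq.bases[pos]
    alt = rng.choice([b for b in BASES if b != ref])
    bases = seq.bases[:pos] + alt + seq.bases[pos + 1 :]
    return RnaSequence(f"{seq.id}|{ref}{pos + 1}{alt}", bases)


def sample_null_scores(
    length: int,
    gc: float,
    N: int,
    score_fn: Callable[[RnaSequence, RnaSequence], float],
    rng: np.random.Generator,
) -> np.ndarray:
    """N draws of the substitution-effect statistic under the null.

    Each draw: a fresh random sequence at (length, gc), one random
    substitution, then ``score_fn(wild_type, mutant)`` — the same measure
    and parameters as the foreground run being calibrated.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    scores = np.empty(N)
    for k in range(N):
        wt = random_sequence(length, gc, rng)
        mut = random_substitution(wt, rng)
        scores[k] = score_fn(wt, mut)
    return scores


@dataclass
class BackgroundTable:
    """Null score distributions stratified by (length bin, GC bin).

    ``strata[(length_bin, gc_bin)]`` is an ascending-sorted array of N
    null scores.  ``metadata`` records everything needed to regenerate
    the table bit-for-bit (measure, mode, folding parameters, N, seed,
    model identifier).
    """

    measure: str
    mode: str
    samples_per_stratum: int
    seed: int
    model: str
    params: dict[str, float | int | str] = field(default_factory=dict)
    strata: dict[tuple[int, float], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.measure not in (DISTANCE, CORRELATION):
            raise ValueError(f"unknown measure {self.measure!r}")
        for key, scores in self.strata.items():
            if scores.size == 0:
                raise ValueError(f"empty stratum {key}")

    @property
    def length_bins(self) -> list[int]:
        return sorted({lb for lb, _ in self.strata})

    @property
    def gc_bins(self) -> list[float]:
        return sorted({gb for _, gb in self.strata})

    def nearest_stratum(self, length: int, gc: float) -> np.ndarray:
        """Nearest length bin, then nearest GC bin; clamps outside the grid."""
        if not self.strata:
            raise TableFormatError("background table has no strata")
        lb = min(self.length_bins, key=lambda b: (abs(b - length), b))
        gbs = sorted({g for (l, g) in self.strata if l == lb})
        gb = min(gbs, key=lambda b: (abs(b - gc), b))
        return self.strata[(lb, gb)]


def empirical_pvalue(score: float, length: int, gc: float,
                     table: BackgroundTable) -> float:
    """Add-one empirical P-value of an observed score against its stratum.

    Distance: fraction of null scores >= observed.  Correlation: fraction
    <= observed (low correlation = strong effect).  The +1 in numerator
    and denominator keeps p in [1/(N+1), 1].
    """
    null = table.nearest_stratum(length, gc)
    N = null.size
    if table.measure == DISTANCE:
        exceed = int(np.searchsorted(null, score, side="left"))
        count = N - exceed  # null >= score
    else:
        count = int(np.searchsorted(null, score, side="right"))  # null <= score
    return (1 + count) / (N + 1)


def build_background_table(
    score_fn: Callable[[RnaSequence, RnaSequence], float],
    measure: str,
    mode: str,
    N: int,
    seed: int,
    length_bins: Sequence[int] = DEFAULT_LENGTH_BINS,
    gc_bins: Sequence[float] = DEFAULT_GC_BINS,
    model: str = "internal-nn-v1",
    params: dict | None = None,
    progress: Callable[[str], None] | None = None,
) -> BackgroundTable:
    """One sorted stratum of N null scores per (length, GC) grid cell.

    Strata are generated from independent child seeds spawned
    deterministically from ``seed``, so the table is reproducible and
    insensitive to grid iteration order.
    """
    if not length_bins or not gc_bins:
        raise ValueError("length_bins and gc_bins must be non-empty")
    table = BackgroundTable(
        measure=measure, mode=mode, samples_per_stratum=N, seed=seed,
        model=model, params=dict(params or {}),
    )
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(length_bins) * len(gc_bins))
    k = 0
    for lb in length_bins:
        for gb in gc_bins:
            if progress:
                progress(f"stratum length={lb} gc={gb}")
            rng = np.random.default_rng(children[k])
            k += 1
            scores = sample_null_scores(lb, gb, N, score_fn, rng)
            table.strata[(int(lb), float(gb))] = np.sort(scores)
    return table


# ---------------------------------------------------------------------------
# persistence

def save_table(table: BackgroundTable, path: str | Path | TextIO) -> None:
    """Write the versioned TSV table format (lossless round-trip)."""
    close = False
    if isinstance(path, (str, Path)):
        stream: TextIO = open(path, "w")
        close = True
    else:
        stream = path
    try:
        stream.write(f"# {MAGIC}\n")
        stream.write(f"# measure={table.measure}\n")
        stream.write(f"# mode={table.mode}\n")
        stream.write(f"# samples_per_stratum={table.samples_per_stratum}\n")
        stream.write(f"# seed={table.seed}\n")
        stream.write(f"# model={table.model}\n")
        for key in sorted(table.params):
            stream.write(f"# param:{key}={table.params[key]}\n")
        stream.write("length_bin\tgc_bin\trank\tscore\n")
        for (lb, gb) in sorted(table.strata):
            for rank, score in enumerate(table.strata[(lb, gb)]):
                stream.write(f"{lb}\t{gb:g}\t{rank}\t{float(score)!r}\n")
    finally:
        if close:
            stream.close()


def _parse_scalar(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def load_table(path: str | Path | TextIO) -> BackgroundTable:
    """Read a table written by :func:`save_table`; checks magic and shape."""
    if isinstance(path, (str, Path)):
        with open(path) as fh:
            text = fh.read()
    else:
        text = path.read()
    lines = text.splitlines()
    if not lines or lines[0].strip() != f"# {MAGIC}":
        raise TableFormatError(
            f"not a background table (expected magic {MAGIC!r})"
        )
    meta: dict[str, str] = {}
    params: dict = {}
    body_start = None
    for k, line in enumerate(lines[1:], start=1):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            key = key.strip()
            if key.startswith("param:"):
                params[key[len("param:"):]] = _parse_scalar(value.strip())
            else:
                meta[key] = value.strip()
        else:
            body_start = k
            break
    required = {"measure", "mode", "samples_per_stratum", "seed", "model"}
    if body_start is None or not required.issubset(meta):
        raise TableFormatError("truncated table: missing metadata or body")
    header = lines[body_start].split("\t")
    if header != ["length_bin", "gc_bin", "rank", "score"]:
        raise TableFormatError(f"unexpected column header {header}")
    raw: dict[tuple[int, float], list[tuple[int, float]]] = {}
    for line in lines[body_start + 1 :]:
        if not line.strip():
            continue
        lb, gb, rank, score = line.split("\t")
        raw.setdefault((int(lb), float(gb)), []).append((int(rank), float(score)))
    N = int(meta["samples_per_stratum"])
    strata = {}
    for key, rows in raw.items():
        rows.sort()
        if [r for r, _ in rows] != list(range(len(rows))) or len(rows) != N:
            raise TableFormatError(f"truncated stratum {key}")
        strata[key] = np.array([s for _, s in rows])
    return BackgroundTable(
        measure=meta["measure"], mode=meta["mode"],
        samples_per_stratum=N, seed=int(meta["seed"]),
        model=meta["model"], params=params, strata=strata,
    )


def table_to_text(table: BackgroundTable) -> str:
    buf = io.StringIO()
    save_table(table, buf)
    return buf.getvalue()
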