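"""Sequence and mutation handling.

RNA (or DNA) sequences are normalized to the alphabet {A, C, G, U}:
uppercased, T replaced by U.  Any other character is a hard error — folding
an ambiguity code is not meaningful.  Point mutations use the compact
``RefPosAlt`` notation (e.g. ``U22G``); several substitutions applied
jointly to one molecule are hyphen-joined into a compound mutant
(``U22G-G14C``).  Positions are 1-based throughout the user-facing API.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterator, TextIO

RNA_ALPHABET = frozenset("ACGU")

_MUTATION_RE = re.compile(r"^([ACGUTacgut])(\d+)([ACGUTacgut])$")


class SequenceError(ValueError):
    """Invalid sequence content or mutation specification."""


@dataclass(frozen=True)
class GenomicOrigin:
    """Genomic locus a sequence was extracted from.

    ``start`` is the 1-based genomic coordinate of the region on the
    forward genomic strand; for ``strand == '-'`` sequence position 1
    corresponds to the *end* of the genomic interval.
    """

    assembly: str
    chrom: str
    start: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1:
            raise ValueError("genomic start must be >= 1")


@dataclass(frozen=True)
class RnaSequence:
    """A normalized RNA sequence with optional genomic origin."""

    id: str
    bases: str
    origin: GenomicOrigin | None = None

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise SequenceError(f"sequence {self.id!r} is empty")
        for pos, b in enumerate(self.bases, start=1):
            if b not in RNA_ALPHABET:
                raise SequenceError(
                    f"sequence {self.id!r}: invalid character {b!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def gc_fraction(self) -> float:
        n = len(self.bases)
        return (self.bases.count("G") + self.bases.count("C")) / n

    def subsequence(self, start: int, end: int, sub_id: str | None = None) -> "RnaSequence":
        """1-based inclusive slice; origin is not propagated (coordinates shift)."""
        if not (1 <= start <= end <= len(self.bases)):
            raise IndexError(f"[{start}, {end}] outside sequence of length {len(self.bases)}")
        return RnaSequence(sub_id or f"{self.id}:{start}-{end}", self.bases[start - 1 : end])


def normalize_bases(raw: str, seq_id: str = "<sequence>") -> str:
    """Uppercase and T->U; reject anything outside the DNA/RNA alphabet.

    The error names the 1-based position of the first offending character.
    """
    cleaned = []
    pos = 0
    for ch in raw:
        if ch.isspace():
            continue
        pos += 1
        up = ch.upper()
        if up == "T":
            up = "U"
        if up not in RNA_ALPHABET:
            raise SequenceError(
                f"sequence {seq_id!r}: invalid character {ch!r} at position {pos}"
            )
        cleaned.append(up)
    return "".join(cleaned)


def read_fasta(stream: TextIO | str, origin: GenomicOrigin | None = None) -> list[RnaSequence]:
    """Parse FASTA text into normalized :class:`RnaSequence` records.

    The record id is the first whitespace-delimited token of the header.
    DNA is accepted (T is silently converted to U); other characters raise
    :class:`SequenceError` naming the first offending position.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[RnaSequence] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq_id = header.split()[0] if header.split() else header
        records.append(RnaSequence(seq_id, normalize_bases("".join(chunks), seq_id), origin))

    for line in stream:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            if header is not None:
                flush()
            header = line[1:].strip()
            chunks = []
        else:
            if header is None:
                raise SequenceError("FASTA input does not start with a '>' header")
            chunks.append(line)
    flush()
    if not records:
        raise SequenceError("empty FASTA input: no records found")
    return records


def first_record(records: list[RnaSequence]) -> RnaSequence:
    """The mode runners fold a single molecule; extra records only warn."""
    if len(records) > 1:
        warnings.warn(
            f"input contains {len(records)} FASTA records; only the first "
            f"({records[0].id!r}) is used",
            stacklevel=2,
        )
    return records[0]


@dataclass(frozen=True)
class Mutation:
    """One point substitution, 1-based."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise SequenceError(f"mutation position must be >= 1, got {self.position}")
        for b in (self.ref, self.alt):
            if b not in RNA_ALPHABET:
                raise SequenceError(f"mutation base {b!r} not one of A/C/G/U")
        if self.ref == self.alt:
            raise SequenceError(
                f"mutation {self.ref}{self.position}{self.alt}: ref equals alt"
            )

    def __str__(self) -> str:
        return f"{self.ref}{self.position}{self.alt}"

    def inverse(self) -> "Mutation":
        return Mutation(self.position, self.alt, self.ref)


@dataclass(frozen=True)
class MutationSet:
    """Substitutions applied jointly to one molecule (a single mutant allele).

    ``U22G`` is a single SNP; ``U22G-G14C`` is one compound mutant carrying
    both changes.  Independent SNPs are separate MutationSets.
    """

    mutations: tuple[Mutation, ...]
    label: str = field(default="")

    def __post_init__(self) -> None:
        if not self.mutations:
            raise SequenceError("empty mutation set")
        positions = [m.position for m in self.mutations]
        if len(set(positions)) != len(positions):
            raise SequenceError(f"duplicate positions in mutation set {self.label!r}")
        if not self.label:
            object.__setattr__(self, "label", format_mutation_set(self))

    def __iter__(self) -> Iterator[Mutation]:
        return iter(self.mutations)

    @property
    def min_position(self) -> int:
        return min(m.position for m in self.mutations)

    @property
    def max_position(self) -> int:
        return max(m.position for m in self.mutations)

    def inverse(self) -> "MutationSet":
        return MutationSet(tuple(m.inverse() for m in self.mutations))


def format_mutation_set(ms: MutationSet) -> str:
    return "-".join(str(m) for m in ms.mutations)


def parse_mutation_token(token: str) -> Mutation:
    m = _MUTATION_RE.match(token.strip())
    if m is None:
        raise SequenceError(
            f"malformed mutation token {token!r}: expected RefPosAlt, e.g. 'U22G'"
        )
    ref = normalize_bases(m.group(1))
    alt = normalize_bases(m.group(3))
    return Mutation(int(m.group(2)), ref, alt)


def parse_mutation_spec(text: str) -> list[MutationSet]:
    """Parse mutation-list text: one mutant per line, ``#`` comments allowed.

    A line holds one or more hyphen-joined ``RefPosAlt`` tokens; hyphen-joined
    tokens form a single compound mutant.
    """
    sets: list[MutationSet] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = [t for t in line.split("-") if t]
        muts = tuple(parse_mutation_token(t) for t in tokens)
        sets.append(MutationSet(muts, "-".join(t.strip() for t in tokens)))
    if not sets:
        raise SequenceError("no mutation specifications found")
    return sets


def apply_mutations(seq: RnaSequence, ms: MutationSet) -> RnaSequence:
    """Apply every substitution in ``ms``; the reference base must match.

    The returned sequence differs from ``seq`` exactly at the mutated
    positions and keeps its length.
    """
    bases = list(seq.bases)
    for m in ms:
        if m.position > len(bases):
            raise SequenceError(
                f"mutation {m}: position {m.position} beyond sequence "
                f"length {len(bases)}"
            )
        found = bases[m.position - 1]
        if found != m.ref:
            raise SequenceError(
                f"mutation {m}: reference mismatch at position {m.position} "
                f"(expected {m.ref}, found {found})"
            )
        bases[m.position - 1] = m.alt
    return RnaSequence(f"{seq.id}|{ms.label}", "".join(bases), seq.origin)
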