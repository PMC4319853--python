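"""Reading, cleaning and summarizing small-RNA sequencing libraries.

Raw reads (FASTQ or FASTA) are cleaned into a :class:`TagLibrary` — a
collapsed set of unique tag sequences with read counts — following the
standard small-RNA screening steps: locate and trim the 3' adaptor,
discard 5'-adaptor contaminants, adaptor-adaptor ligation products
(no insert), poly(A) artifacts, low-quality reads and inserts outside
the 15-30 nt window.  Tags are stored uppercase in the RNA alphabet
(T normalized to U).  Length-distribution and first-nucleotide-bias
tables support the usual library summary plots.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd
from Bio import SeqIO

from .fold import normalize_rna

__all__ = [
    "RawRead",
    "Tag",
    "TagLibrary",
    "CleaningParams",
    "CleaningReport",
    "clean_reads",
    "read_fastq",
    "read_fasta",
    "read_tag_fasta",
    "write_tag_fasta",
    "length_distribution",
    "first_nucleotide_bias",
]


@dataclass(frozen=True)
class RawRead:
    """A raw sequencing read, optionally with per-base Phred scores."""

    id: str
    sequence: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality length != sequence length")


@dataclass(frozen=True)
class Tag:
    """A unique small-RNA sequence with its collapsed read count."""

    sequence: str
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


class TagLibrary:
    """A labeled library of unique tags keyed by sequence.

    ``total_clean_reads`` always equals the sum of tag counts.
    """

    def __init__(self, label: str, tags: Iterable[Tag] = ()):
        self.label = label
        self._tags: dict[str, int] = {}
        for t in tags:
            self.add(t.sequence, t.count)

    def add(self, sequence: str, count: int = 1) -> None:
        seq = normalize_rna(sequence)
        self._tags[seq] = self._tags.get(seq, 0) + count

    def __len__(self) -> int:
        return len(self._tags)

    def __contains__(self, sequence: str) -> bool:
        return normalize_rna(sequence) in self._tags

    def __iter__(self) -> Iterator[Tag]:
        for seq in sorted(self._tags):
            yield Tag(seq, self._tags[seq])

    def __eq__(self, other) -> bool:
        return (isinstance(other, TagLibrary) and self.label == other.label
                and self._tags == other._tags)

    def count(self, sequence: str) -> int:
        return self._tags.get(normalize_rna(sequence), 0)

    @property
    def total_clean_reads(self) -> int:
        return sum(self._tags.values())

    @property
    def sequences(self) -> list[str]:
        return sorted(self._tags)

    def __repr__(self) -> str:
        return (f"TagLibrary({self.label!r}, {len(self)} unique tags, "
                f"{self.total_clean_reads} reads)")


_REASONS = ("adaptor_5prime", "no_insert", "polyA", "too_short", "too_long",
            "low_quality")


@dataclass
class CleaningReport:
    """Per-reason removal counts for one cleaning run."""

    adaptor_5prime: int = 0
    no_insert: int = 0
    polyA: int = 0
    too_short: int = 0
    too_long: int = 0
    low_quality: int = 0
    retained: int = 0

    @property
    def removed(self) -> int:
        return sum(getattr(self, r) for r in _REASONS)

    @property
    def total(self) -> int:
        return self.removed + self.retained

    def to_frame(self) -> pd.DataFrame:
        rows = [(r, getattr(self, r)) for r in _REASONS] + [("retained", self.retained)]
        return pd.DataFrame(rows, columns=["reason", "reads"])


@dataclass(frozen=True)
class CleaningParams:
    min_len: int = 15
    max_len: int = 30
    polya_fraction: float = 0.8  # insert discarded when A fraction >= this
    min_mean_quality: float = 20.0
    adaptor_seed_len: int = 8  # exact prefix of the 3' adaptor to locate


def clean_reads(reads: Iterable[RawRead], adaptor_3p: str, adaptor_5p: str,
                params: CleaningParams = CleaningParams(),
                label: str = "library") -> tuple[TagLibrary, CleaningReport]:
    """Screen raw reads into a collapsed tag library.

    The 3' adaptor is located by exact match of its first
    ``adaptor_seed_len`` nt and everything from there on is trimmed; a
    read with no such match is counted as ``no_insert`` (adaptor-adaptor
    ligation or missing insert).  Reads are discarded, with reason
    codes, when the 5' adaptor occurs inside the read, no insert remains
    after trimming, the insert is poly(A), its length falls outside
    [min_len, max_len] (bounds inclusive), it contains N, or mean Phred
    quality is below threshold (FASTA input skips the quality filter).
    """
    if not adaptor_3p or not adaptor_5p:
        raise ValueError("adaptor sequences must be non-empty")
    a3 = adaptor_3p.upper().replace("U", "T")
    a5 = adaptor_5p.upper().replace("U", "T")
    seed = a3[:params.adaptor_seed_len]
    lib = TagLibrary(label)
    rep = CleaningReport()
    for read in reads:
        seq = read.sequence.upper().replace("U", "T")
        if a5 in seq:
            rep.adaptor_5prime += 1
            continue
        cut = seq.find(seed)
        if cut < 0:
            rep.no_insert += 1
            continue
        insert = seq[:cut]
        if not insert:
            rep.no_insert += 1
            continue
        if read.quality is not None:
            qual = read.quality[:cut]
            if "N" in insert or (qual and sum(qual) / len(qual) < params.min_mean_quality):
                rep.low_quality += 1
                continue
        elif "N" in insert:
            rep.low_quality += 1
            continue
        if insert.count("A") / len(insert) >= params.polya_fraction:
            rep.polyA += 1
            continue
        if len(insert) < params.min_len:
            rep.too_short += 1
            continue
        if len(insert) > params.max_len:
            rep.too_long += 1
            continue
        lib.add(insert)
        rep.retained += 1
    return lib, rep


# ---------------------------------------------------------------------------
# format IO
# ---------------------------------------------------------------------------

def _open(source) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source)
    return source


def read_fastq(source) -> Iterator[RawRead]:
    """Parse Sanger (Phred+33) FASTQ into RawRead records (Bio.SeqIO)."""
    fh = _open(source)
    parser = SeqIO.parse(fh, "fastq")
    idx = 0
    while True:
        try:
            rec = next(parser, None)
        except ValueError as exc:
            raise ValueError(f"FASTQ record {idx}: {exc}") from None
        if rec is None:
            return
        yield RawRead(rec.id, str(rec.seq),
                      tuple(rec.letter_annotations["phred_quality"]))
        idx += 1


def read_fasta(source) -> Iterator[tuple[str, str]]:
    """Yield (id+description, sequence) pairs from FASTA text (Bio.SeqIO)."""
    fh = _open(source)
    for rec in SeqIO.parse(fh, "fasta"):
        if len(rec.seq) == 0:
            raise ValueError(f"FASTA record {rec.description!r}: empty or truncated record")
        yield rec.description, str(rec.seq)


def read_tag_fasta(source, label: str = "library") -> TagLibrary:
    """Read the collapsed-tag FASTA dialect ``>tag<N>_x<count>``."""
    lib = TagLibrary(label)
    for header, seq in read_fasta(source):
        name = header.split()[0]
        if "_x" not in name:
            raise ValueError(f"tag header {name!r} lacks the _x<count> suffix")
        try:
            count = int(name.rsplit("_x", 1)[1])
        except ValueError:
            raise ValueError(f"tag header {name!r} has a non-integer count") from None
        lib.add(seq, count)
    return lib


def write_tag_fasta(lib: TagLibrary, dest) -> None:
    """Write a library in the collapsed-tag dialect (deterministic order)."""
    own = isinstance(dest, (str, Path))
    fh = open(dest, "w") if own else dest
    try:
        for i, tag in enumerate(lib, start=1):
            fh.write(f">tag{i}_x{tag.count}\n{tag.sequence}\n")
    finally:
        if own:
            fh.close()


def write_fasta(records: Iterable[tuple[str, str]], dest) -> None:
    own = isinstance(dest, (str, Path))
    fh = open(dest, "w") if own else dest
    try:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    finally:
        if own:
            fh.close()


def tag_fasta_text(lib: TagLibrary) -> str:
    buf = io.StringIO()
    write_tag_fasta(lib, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# library summaries
# ---------------------------------------------------------------------------

def length_distribution(lib: TagLibrary, by: str = "reads") -> pd.DataFrame:
    """Tag-length histogram, weighted by reads or by unique tags."""
    if by not in ("reads", "unique"):
        raise ValueError("by must be 'reads' or 'unique'")
    counts: Counter[int] = Counter()
    for tag in lib:
        counts[len(tag.sequence)] += tag.count if by == "reads" else 1
    return pd.DataFrame(sorted(counts.items()), columns=["length", "count"])


def first_nucleotide_bias(lib: TagLibrary, by: str = "reads") -> pd.DataFrame:
    """Per-length counts of the 5'-terminal base (read-weighted by default)."""
    if by not in ("reads", "unique"):
        raise ValueError("by must be 'reads' or 'unique'")
    counts: Counter[tuple[int, str]] = Counter()
    for tag in lib:
        counts[(len(tag.sequence), tag.sequence[0])] += (
            tag.count if by == "reads" else 1)
    rows = [(l, b, c) for (l, b), c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["length", "first_base", "count"])
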