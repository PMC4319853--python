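"""Tag annotation: transcriptome mapping, ncRNA classification and
conserved-miRNA identification.

Conserved miRNAs are identified by the three-step temporary-database
procedure used in plant small-RNA studies: (1) align all clean tags to
a cross-species miRNA catalog (mature + precursor records, family
labelled) allowing up to two substitutions; (2) keep, per family, the
highest-expressed aligning tag as that family's temporary
representative; (3) re-align the library to the representatives,
summing the counts of every tag within two substitutions to quantify
each conserved miRNA.  Alignments are ungapped; a tag must cover a
mature reference end-to-end up to a +/-2 nt terminal offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

from .fold import normalize_rna, reverse_complement
from .sra_io import TagLibrary

__all__ = [
    "ReferenceRecord",
    "ReferenceSet",
    "TagHit",
    "AnnotationTable",
    "ConservedMiRNAProfile",
    "map_perfect",
    "classify_ncrna",
    "build_temp_mirna_db",
    "quantify_conserved",
    "annotate_library",
]

NCRNA_CLASSES = ("rRNA", "tRNA", "snoRNA", "snRNA")  # classification priority
REFERENCE_CLASSES = NCRNA_CLASSES + ("transcript", "miRNA_mature", "miRNA_precursor")

CATEGORIES = ("rRNA", "tRNA", "snoRNA", "snRNA", "known_miRNA",
              "unannotated_mapped", "unmapped")


@dataclass(frozen=True)
class ReferenceRecord:
    id: str
    sequence: str
    ref_class: str
    family: str | None = None
    species: str | None = None

    def __post_init__(self):
        if self.ref_class not in REFERENCE_CLASSES:
            raise ValueError(f"unknown reference class {self.ref_class!r}")
        if not self.sequence:
            raise ValueError(f"reference {self.id!r} has an empty sequence")


class ReferenceSet:
    """A collection of classified reference sequences with unique ids."""

    def __init__(self, records: Iterable[ReferenceRecord] = ()):
        self._records: dict[str, ReferenceRecord] = {}
        for rec in records:
            self.add(rec)
        self._cache: dict[str, tuple[str, list[tuple[str, int]]]] = {}

    def add(self, rec: ReferenceRecord) -> None:
        if rec.id in self._records:
            raise ValueError(f"duplicate reference id {rec.id!r}")
        norm = ReferenceRecord(rec.id, normalize_rna(rec.sequence), rec.ref_class,
                               rec.family, rec.species)
        self._records[rec.id] = norm

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(sorted(self._records.values(), key=lambda r: r.id))

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, rid: str) -> ReferenceRecord:
        return self._records[rid]

    def by_class(self, ref_class: str) -> list[ReferenceRecord]:
        return [r for r in self if r.ref_class == ref_class]

    def _concat(self, ref_class: str) -> tuple[str, list[tuple[str, int]]]:
        # concatenated sequence with '#' separators for fast substring scans
        if ref_class not in self._cache:
            recs = self.by_class(ref_class)
            offsets, parts, pos = [], [], 0
            for r in recs:
                offsets.append((r.id, pos))
                parts.append(r.sequence)
                pos += len(r.sequence) + 1
            self._cache[ref_class] = ("#".join(parts), offsets)
        return self._cache[ref_class]

    def _locate(self, seq: str, ref_class: str) -> list[tuple[str, int]]:
        text, offsets = self._concat(ref_class)
        out = []
        start = text.find(seq)
        while start >= 0:
            rid, base = next((rid, base) for rid, base in reversed(offsets)
                             if base <= start)
            out.append((rid, start - base))
            start = text.find(seq, start + 1)
        return out

    def find_substring(self, seq: str, ref_class: str,
                       both_strands: bool = True) -> list[tuple[str, int, str]]:
        """All (record id, offset, strand) exact occurrences of seq."""
        s = normalize_rna(seq)
        hits = [(rid, off, "+") for rid, off in self._locate(s, ref_class)]
        if both_strands:
            rc = reverse_complement(s)
            hits += [(rid, off, "-") for rid, off in self._locate(rc, ref_class)]
        return sorted(hits)


def read_reference_fasta(source) -> ReferenceSet:
    """Read a reference FASTA whose description field carries the class
    (``>id class=rRNA family=... species=...``)."""
    from .sra_io import read_fasta

    refs = ReferenceSet()
    for header, seq in read_fasta(source):
        parts = header.split()
        rid = parts[0]
        attrs = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
        refs.add(ReferenceRecord(rid, seq, attrs.get("class", "transcript"),
                                 family=attrs.get("family"),
                                 species=attrs.get("species")))
    return refs


def write_reference_fasta(refs: ReferenceSet, dest) -> None:
    from .sra_io import write_fasta

    def header(r: ReferenceRecord) -> str:
        h = f"{r.id} class={r.ref_class}"
        if r.family:
            h += f" family={r.family}"
        if r.species:
            h += f" species={r.species}"
        return h

    write_fasta(((header(r), r.sequence) for r in refs), dest)


@dataclass(frozen=True)
class TagHit:
    """An exact occurrence of a tag in a reference sequence."""

    tag: str
    ref_id: str
    start: int  # 0-based
    end: int  # half-open
    strand: str


def map_perfect(lib: TagLibrary, transcriptome: ReferenceSet) -> dict[str, list[TagHit]]:
    """Perfect-match mapping of every tag to the transcript references.

    A tag maps iff the tag itself (strand ``+``) or its reverse
    complement (strand ``-``) occurs as an exact substring of a
    transcript.  Returns only tags with at least one hit.
    """
    out: dict[str, list[TagHit]] = {}
    for tag in lib:
        hits = [TagHit(tag.sequence, rid, off, off + len(tag.sequence), strand)
                for rid, off, strand in
                transcriptome.find_substring(tag.sequence, "transcript")]
        if hits:
            out[tag.sequence] = hits
    return out


def classify_ncrna(lib: TagLibrary, ncrna_refs: ReferenceSet) -> dict[str, str]:
    """Classify tags as degradation fragments of structural ncRNAs.

    A tag is assigned the first class in the priority order
    rRNA > tRNA > snoRNA > snRNA for which it is an exact substring of a
    reference of that class (either strand).  Unmatched tags are absent
    from the result.
    """
    out: dict[str, str] = {}
    for tag in lib:
        for cls in NCRNA_CLASSES:
            if ncrna_refs.find_substring(tag.sequence, cls):
                out[tag.sequence] = cls
                break
    return out


# ---------------------------------------------------------------------------
# conserved miRNA identification
# ---------------------------------------------------------------------------

def _align_terminal(tag: str, ref: str, max_mm: int = 2,
                    max_offset: int = 2) -> int | None:
    """Ungapped end-to-end alignment with terminal-offset tolerance.

    The tag is slid against the reference with a 5' offset of at most
    ``max_offset`` nt; the 3' overhang implied by the length difference
    must also stay within ``max_offset``.  Returns the minimum number of
    substitutions over the overlap, or None if no placement qualifies.
    """
    best: int | None = None
    for off in range(-max_offset, max_offset + 1):
        # off = position of tag[0] on the reference
        end_off = (off + len(tag)) - len(ref)
        if abs(end_off) > max_offset:
            continue
        lo = max(0, off)
        hi = min(len(ref), off + len(tag))
        if hi - lo < min(len(tag), len(ref)) - max_offset:
            continue
        mm = sum(1 for p in range(lo, hi) if ref[p] != tag[p - off])
        if mm <= max_mm and (best is None or mm < best):
            best = mm
    return best


def _align_windowed(tag: str, ref: str, max_mm: int = 2) -> int | None:
    """Best substitution count of the tag against any same-length window
    of a longer reference (used for precursor records)."""
    if len(tag) > len(ref):
        return None
    best: int | None = None
    for start in range(len(ref) - len(tag) + 1):
        mm = 0
        for a, b in zip(tag, ref[start:start + len(tag)]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            if best is None or mm < best:
                best = mm
    return best


class _SeedIndex:
    """Exact 6-mer index used to prefilter candidate alignments.

    An ungapped alignment with <= 2 substitutions over an overlap of
    >= 19 nt always contains an exact run of >= 6 nt (pigeonhole), so a tag
    sharing no 6-mer with any reference cannot align and is skipped
    without the O(offsets x length) scan.
    """

    K = 6

    def __init__(self, sequences: Iterable[str]):
        self._kmers: set[str] = set()
        for seq in sequences:
            for i in range(len(seq) - self.K + 1):
                self._kmers.add(seq[i:i + self.K])

    def may_match(self, tag: str) -> bool:
        return any(tag[i:i + self.K] in self._kmers
                   for i in range(len(tag) - self.K + 1))


@dataclass(frozen=True)
class TempMiRNA:
    """A family's temporary representative: its highest-expressed tag."""

    family: str
    sequence: str
    count: int


def build_temp_mirna_db(lib: TagLibrary, plant_mirnas: ReferenceSet,
                        max_mm: int = 2) -> dict[str, TempMiRNA]:
    """Step 1-2 of conserved-miRNA identification.

    For each family with at least one tag aligning (ungapped, <= max_mm
    substitutions, terminal tolerance +/-2 nt against matures; windowed
    against precursors) to any member, keep the aligning tag with the
    highest count as the family representative.  Ties break to the
    lexicographically smaller sequence.
    """
    matures = plant_mirnas.by_class("miRNA_mature")
    precursors = plant_mirnas.by_class("miRNA_precursor")
    index = _SeedIndex(r.sequence for r in matures + precursors)
    best: dict[str, TempMiRNA] = {}
    for tag in lib:
        if not index.may_match(tag.sequence):
            continue
        families = set()
        for rec in matures:
            if _align_terminal(tag.sequence, rec.sequence, max_mm) is not None:
                families.add(rec.family or rec.id)
        for rec in precursors:
            if (rec.family or rec.id) in families:
                continue
            if _align_windowed(tag.sequence, rec.sequence, max_mm) is not None:
                families.add(rec.family or rec.id)
        for fam in families:
            cur = best.get(fam)
            if (cur is None or tag.count > cur.count
                    or (tag.count == cur.count and tag.sequence < cur.sequence)):
                best[fam] = TempMiRNA(fam, tag.sequence, tag.count)
    return dict(sorted(best.items()))


@dataclass
class ConservedMiRNAProfile:
    """A conserved miRNA: representative sequence plus member tags."""

    mirna_id: str
    family: str
    sequence: str
    count: int
    members: list[tuple[str, int]] = field(default_factory=list)


def quantify_conserved(lib: TagLibrary, temp_db: dict[str, TempMiRNA],
                       max_mm: int = 2) -> list[ConservedMiRNAProfile]:
    """Step 3: sum, per family representative, the counts of all library
    tags within ``max_mm`` substitutions of it (ungapped, terminal
    tolerance +/-2 nt).  Each tag contributes to at most one profile:
    best hit by fewest mismatches, then lexicographic family name.
    """
    index = _SeedIndex(rep.sequence for rep in temp_db.values())
    assignments: dict[str, tuple[int, str]] = {}
    for tag in lib:
        if not index.may_match(tag.sequence):
            continue
        best: tuple[int, str] | None = None
        for fam, rep in temp_db.items():
            mm = _align_terminal(tag.sequence, rep.sequence, max_mm)
            if mm is not None and (best is None or (mm, fam) < best):
                best = (mm, fam)
        if best is not None:
            assignments[tag.sequence] = best
    profiles: dict[str, ConservedMiRNAProfile] = {}
    for fam, rep in temp_db.items():
        profiles[fam] = ConservedMiRNAProfile(
            mirna_id=f"pos-{fam}", family=fam, sequence=rep.sequence, count=0)
    for tag in lib:
        if tag.sequence in assignments:
            _, fam = assignments[tag.sequence]
            profiles[fam].count += tag.count
            profiles[fam].members.append((tag.sequence, tag.count))
    return [p for fam, p in sorted(profiles.items()) if p.members]


# ---------------------------------------------------------------------------
# the full annotation partition
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """Category assignment for every unique tag of one library."""

    label: str
    categories: dict[str, str]  # tag sequence -> category

    def to_frame(self) -> pd.DataFrame:
        rows = [(seq, cat) for seq, cat in sorted(self.categories.items())]
        return pd.DataFrame(rows, columns=["tag", "category"])

    def composition(self, lib: TagLibrary) -> pd.DataFrame:
        """Read-weighted and unique-tag composition by category."""
        reads = {c: 0 for c in CATEGORIES}
        uniq = {c: 0 for c in CATEGORIES}
        for tag in lib:
            cat = self.categories[tag.sequence]
            reads[cat] += tag.count
            uniq[cat] += 1
        return pd.DataFrame(
            [(c, uniq[c], reads[c]) for c in CATEGORIES],
            columns=["category", "unique_tags", "reads"])


def annotate_library(lib: TagLibrary, transcriptome: ReferenceSet,
                     ncrna_refs: ReferenceSet,
                     conserved: list[ConservedMiRNAProfile],
                     hits: dict[str, list[TagHit]] | None = None) -> AnnotationTable:
    """Assign every tag exactly one category by the fixed priority order
    rRNA > tRNA > snoRNA > snRNA > known_miRNA > unannotated_mapped >
    unmapped.  ncRNA classification precedes miRNA identification."""
    ncrna = classify_ncrna(lib, ncrna_refs)
    mirna_tags = {seq for prof in conserved for seq, _ in prof.members}
    if hits is None:
        hits = map_perfect(lib, transcriptome)
    cats: dict[str, str] = {}
    for tag in lib:
        seq = tag.sequence
        if seq in ncrna:
            cats[seq] = ncrna[seq]
        elif seq in mirna_tags:
            cats[seq] = "known_miRNA"
        elif seq in hits:
            cats[seq] = "unannotated_mapped"
        else:
            cats[seq] = "unmapped"
    return AnnotationTable(lib.label, cats)
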