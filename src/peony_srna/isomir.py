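"""IsomiR cataloguing: tag placement on pre-miRNAs and variant classes.

Tags are aligned to identified precursor sequences; a tag places when a
prefix of at least (tag length - 3) nt matches the precursor exactly,
the unmatched 3' remainder (<= 3 nt) becoming a candidate non-template
tail.  Relative to the canonical mature interval, a placement is
classified as canonical, 5' variant, 3' variant, both-end variant, or
non-template-tailed (most specific class wins:
nontemplate > both > 5p/3p variant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .fold import normalize_rna
from .sra_io import TagLibrary

__all__ = [
    "Precursor",
    "Placement",
    "IsomiRVariant",
    "map_to_precursor",
    "classify_isomir",
    "summarize_isomirs",
    "catalog_isomirs",
]

MAX_TAIL = 3  # longest non-template 3' addition considered placeable
MIN_OVERLAP = 10  # minimum overlap with the canonical mature

CLASSES = ("canonical", "5p_variant", "3p_variant", "both", "nontemplate")


@dataclass(frozen=True)
class Precursor:
    """A pre-miRNA with its canonical mature interval (0-based, half-open)."""

    precursor_id: str
    sequence: str
    mature_start: int
    mature_end: int

    def __post_init__(self):
        if not (0 <= self.mature_start < self.mature_end <= len(self.sequence)):
            raise ValueError(f"mature interval outside precursor {self.precursor_id!r}")


@dataclass(frozen=True)
class Placement:
    precursor_id: str
    tag: str
    count: int
    start: int  # templated portion, 0-based on the precursor
    end: int  # half-open
    tail: str  # non-template 3' remainder, possibly empty


@dataclass(frozen=True)
class IsomiRVariant:
    precursor_id: str
    tag: str
    count: int
    offset5: int  # positive = extension upstream of the canonical 5' end
    offset3: int  # positive = extension downstream of the canonical 3' end
    tail: str
    variant_class: str


def map_to_precursor(lib: TagLibrary, precursors: Sequence[Precursor]) -> list[Placement]:
    """Place library tags on precursors by exact prefix match.

    For each tag the longest exactly-matching prefix (tag length down to
    tag length - 3) is searched in every precursor; the best placement
    has the shortest tail, ties broken by precursor id, then by leftmost
    position.  Each tag contributes at most one placement.
    """
    placements: list[Placement] = []
    ordered = sorted(precursors, key=lambda p: p.precursor_id)
    for tag in lib:
        t = tag.sequence
        best: Placement | None = None
        for tail_len in range(0, min(MAX_TAIL, len(t) - 1) + 1):
            core, tail = t[:len(t) - tail_len], t[len(t) - tail_len:]
            for pre in ordered:
                pos = normalize_rna(pre.sequence).find(core)
                if pos >= 0:
                    best = Placement(pre.precursor_id, t, tag.count,
                                     pos, pos + len(core), tail)
                    break
            if best is not None:
                break
        if best is not None:
            placements.append(best)
    return placements


def classify_isomir(placement: Placement,
                    canonical: tuple[int, int]) -> IsomiRVariant | None:
    """Classify a placement against the canonical mature interval.

    Returns None when the templated portion overlaps the canonical
    mature by fewer than 10 nt (the tag is then not an isomiR of that
    mature).  Offsets are signed with positive = extension beyond the
    canonical end (upstream for 5', downstream for 3').
    """
    cs, ce = canonical
    overlap = min(placement.end, ce) - max(placement.start, cs)
    if overlap < MIN_OVERLAP:
        return None
    offset5 = cs - placement.start
    offset3 = placement.end - ce
    if placement.tail:
        cls = "nontemplate"
    elif offset5 != 0 and offset3 != 0:
        cls = "both"
    elif offset5 != 0:
        cls = "5p_variant"
    elif offset3 != 0:
        cls = "3p_variant"
    else:
        cls = "canonical"
    return IsomiRVariant(placement.precursor_id, placement.tag, placement.count,
                         offset5, offset3, placement.tail, cls)


def catalog_isomirs(lib: TagLibrary, precursors: Sequence[Precursor]) -> list[IsomiRVariant]:
    """Full per-library catalog: place tags, then classify against each
    precursor's canonical mature."""
    canon = {p.precursor_id: (p.mature_start, p.mature_end)
             for p in precursors}
    out = []
    for pl in map_to_precursor(lib, precursors):
        var = classify_isomir(pl, canon[pl.precursor_id])
        if var is not None:
            out.append(var)
    return out


def summarize_isomirs(variants: Iterable[IsomiRVariant]) -> pd.DataFrame:
    """Per-precursor isomiR summary.

    Columns: number of variants, read share per class (shares sum to 1
    per precursor), and read-weighted 5' vs 3' heterogeneity counts
    (reads whose 5' end — resp. 3' end, including tails — deviates from
    the canonical).
    """
    rows: dict[str, dict] = {}
    for v in variants:
        r = rows.setdefault(v.precursor_id, {
            "precursor": v.precursor_id, "n_variants": 0, "reads": 0,
            **{f"share_{c}": 0.0 for c in CLASSES},
            "het5_reads": 0, "het3_reads": 0})
        r["n_variants"] += 1
        r["reads"] += v.count
        r[f"share_{v.variant_class}"] += v.count
        if v.offset5 != 0:
            r["het5_reads"] += v.count
        if v.offset3 != 0 or v.tail:
            r["het3_reads"] += v.count
    for r in rows.values():
        for c in CLASSES:
            r[f"share_{c}"] = r[f"share_{c}"] / r["reads"] if r["reads"] else 0.0
    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["precursor"]))
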