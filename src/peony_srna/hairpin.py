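"""Novel-miRNA discovery from unannotated mapped tags.

Candidate precursor windows are excised around transcript loci carrying
unannotated tags and evaluated against the standard plant-miRNA hairpin
criteria:

* c1 — the candidate mature is unannotated (enforced upstream by the
  annotation partition);
* c2 — the mature sits on one arm of a single stem-loop, with at least
  75% of its positions paired and every partner on the opposite arm;
* c3 — precursor MFE at or below the configured threshold
  (default -18, engine units ~ kcal/mol);
* c4 — no internal loop or bulge larger than 3 nt inside the
  mature:star duplex;
* c5 — the mature/star duplex presents 2-nt 3' overhangs on both
  strands (1-nt slack at helix termini);
* c6 — read support: tags matching the mature with terminal divergence
  of at most 3 nt must sum to more than 5 reads.

MFE and the MFE index (MFEI = (MFE / length x 100) / GC%) are reported
for every candidate; MFEI is not used as a filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotate import TagHit
from .fold import FoldResult, fold_hairpin, normalize_rna
from .sra_io import Tag, TagLibrary

__all__ = [
    "HairpinParams",
    "CandidateWindow",
    "PrecursorCandidate",
    "NovelMiRNA",
    "excise_candidates",
    "evaluate_candidate",
    "count_novel_reads",
    "call_novel_mirnas",
]


@dataclass(frozen=True)
class HairpinParams:
    flank: int = 150  # nt excised on the far side of each window
    near: int = 20  # nt excised on the short side
    mfe_max: float = -18.0  # c3 threshold
    max_bulge: int = 3  # c4: largest tolerated loop/bulge in the duplex
    min_paired_fraction: float = 0.75  # c2
    min_reads: int = 6  # c6: "more than 5"
    overhang_slack: int = 1  # c5 tolerance at helix termini
    max_candidates_per_locus: int = 3
    fold_backend: str = "embedded"


@dataclass(frozen=True)
class CandidateWindow:
    transcript_id: str
    start: int  # 0-based
    end: int  # half-open
    sequence: str
    tag: str
    tag_start: int  # mature position within the window
    tag_count: int

    @property
    def mature_interval(self) -> tuple[int, int]:
        return self.tag_start, self.tag_start + len(self.tag)


@dataclass
class PrecursorCandidate:
    """An excised window with its fold, statistics and per-criterion flags."""

    window: CandidateWindow
    fold: FoldResult
    mfe: float
    mfei: float
    gc_fraction: float
    arm: str | None  # 5p / 3p
    star: str | None
    mature_count: int = 0
    c2: bool = False
    c3: bool = False
    c4: bool = False
    c5: bool = False
    c6: bool = False
    reject_reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.c2 and self.c3 and self.c4 and self.c5 and self.c6

    @property
    def structural_pass(self) -> bool:
        """All structure-level criteria (c2-c5), before read support."""
        return self.c2 and self.c3 and self.c4 and self.c5


@dataclass(frozen=True)
class NovelMiRNA:
    mirna_id: str
    mature: str
    arm: str
    precursor: PrecursorCandidate
    counts: dict[str, int] = field(hash=False)


# ---------------------------------------------------------------------------
# window excision
# ---------------------------------------------------------------------------

def _cluster_hits(hits: Sequence[tuple[TagHit, int]], gap: int = 30):
    """Group hits on one transcript into loci: intervals whose gaps are
    at most ``gap`` nt are merged."""
    ordered = sorted(hits, key=lambda h: (h[0].start, h[0].end, h[0].tag))
    clusters: list[list[tuple[TagHit, int]]] = []
    for hit, count in ordered:
        if clusters and hit.start <= clusters[-1][-1][0].end + gap:
            clusters[-1].append((hit, count))
        else:
            clusters.append([(hit, count)])
    return clusters


def excise_candidates(hits: dict[str, list[TagHit]], lib: TagLibrary,
                      transcripts: dict[str, str],
                      params: HairpinParams = HairpinParams()) -> list[CandidateWindow]:
    """Excise precursor candidate windows around unannotated tag loci.

    Hits are clustered into loci (nearby/overlapping hits merge into a
    shared locus); for each of the top tags of a locus (by count) two
    asymmetric windows are excised — far flank upstream and far flank
    downstream — so the mature can sit on either arm.  Windows are
    clipped to transcript bounds and deduplicated.
    """
    per_transcript: dict[str, list[tuple[TagHit, int]]] = {}
    for seq, tag_hits in hits.items():
        for h in tag_hits:
            per_transcript.setdefault(h.ref_id, []).append((h, lib.count(seq)))
    windows: dict[tuple, CandidateWindow] = {}
    for tid in sorted(per_transcript):
        tseq = normalize_rna(transcripts[tid])
        for cluster in _cluster_hits(per_transcript[tid]):
            best_per_tag: dict[str, tuple[TagHit, int]] = {}
            for h, c in cluster:
                if h.tag not in best_per_tag:
                    best_per_tag[h.tag] = (h, c)
            chosen = sorted(best_per_tag.values(),
                            key=lambda hc: (-hc[1], hc[0].tag))
            for h, count in chosen[:params.max_candidates_per_locus]:
                for lo, hi in ((h.start - params.flank, h.end + params.near),
                               (h.start - params.near, h.end + params.flank)):
                    lo, hi = max(0, lo), min(len(tseq), hi)
                    key = (tid, lo, hi, h.tag)
                    if key in windows or hi - lo < len(h.tag) + 15:
                        continue
                    mature = normalize_rna(h.tag)
                    windows[key] = CandidateWindow(
                        tid, lo, hi, tseq[lo:hi], mature, h.start - lo, count)
    return [windows[k] for k in sorted(windows)]


# ---------------------------------------------------------------------------
# criterion evaluation
# ---------------------------------------------------------------------------

def _duplex_geometry(fold: FoldResult, ms: int, me: int):
    """Partners of the mature positions, in mature order."""
    partners = [(i, fold.partner(i)) for i in range(ms, me) if fold.partner(i) >= 0]
    return partners


def evaluate_candidate(window: CandidateWindow,
                       params: HairpinParams = HairpinParams()) -> PrecursorCandidate:
    """Fold a candidate window and evaluate hairpin criteria c2-c5."""
    seq = window.sequence
    ms, me = window.mature_interval
    if len(seq) < len(window.tag) + 15:
        fold = FoldResult(seq, "." * len(seq), 0.0, tuple([-1] * len(seq)))
        cand = PrecursorCandidate(window, fold, 0.0, 0.0, _gc(seq), None, None,
                                  reject_reason="window_too_short")
        return cand
    fold = fold_hairpin(seq, backend=params.fold_backend)
    gc = _gc(seq)
    mfe = fold.energy
    mfei = (mfe / len(seq) * 100.0) / (gc * 100.0) if gc > 0 else 0.0
    cand = PrecursorCandidate(window, fold, mfe, mfei, gc, None, None)
    cand.c3 = mfe <= params.mfe_max

    partners = _duplex_geometry(fold, ms, me)
    mature_len = me - ms
    paired_fraction = len(partners) / mature_len
    if not partners:
        cand.reject_reason = "mature_unpaired"
        return cand

    part_pos = [p for _, p in partners]
    all_down = all(p >= me for p in part_pos)
    all_up = all(p < ms for p in part_pos)
    # partners must descend as the mature index grows (one helix, no loop
    # crossing) and lie entirely on one side of the mature
    monotone = all(part_pos[k] > part_pos[k + 1] for k in range(len(part_pos) - 1))
    cand.c2 = (paired_fraction >= params.min_paired_fraction
               and (all_down or all_up) and monotone)
    cand.arm = "5p" if all_down else ("3p" if all_up else None)

    # c4: loop/bulge sizes between consecutive paired mature positions
    big_loop = False
    for (i1, j1), (i2, j2) in zip(partners, partners[1:]):
        n1 = i2 - i1 - 1
        n2 = abs(j1 - j2) - 1
        if n1 > params.max_bulge or n2 > params.max_bulge:
            big_loop = True
            break
    cand.c4 = not big_loop

    # c5: 2-nt 3' overhangs of the mature:star duplex (with slack).
    # The star is the partner range plus a 2-nt tail at its 3' end; on
    # either arm this requires the mature 5' end paired (its partner is
    # the star's 3'-most paired base, leaving the star tail as the star
    # 3' overhang) and ~2 unpaired nt at the mature 3' end overhanging
    # the star's 5' end.
    first_paired, last_paired = partners[0][0], partners[-1][0]
    d5 = first_paired - ms  # unpaired mature 5' positions
    d3 = (me - 1) - last_paired  # unpaired mature 3' positions
    slack = params.overhang_slack
    star_lo, star_hi = min(part_pos), max(part_pos)
    tail_limit = len(seq) if cand.arm == "5p" else ms
    star_tail_fits = star_hi + 3 <= tail_limit + slack
    cand.c5 = d5 <= slack and abs(d3 - 2) <= slack and star_tail_fits
    if cand.arm is not None:
        cand.star = seq[star_lo:min(star_hi + 3, len(seq))]
    if not cand.c2:
        cand.reject_reason = cand.reject_reason or "no_single_hairpin_arm"
    elif not cand.c3:
        cand.reject_reason = "mfe_above_threshold"
    elif not cand.c4:
        cand.reject_reason = "large_internal_loop_or_bulge"
    elif not cand.c5:
        cand.reject_reason = "no_2nt_3prime_overhang"
    return cand


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


# ---------------------------------------------------------------------------
# read support and final calls
# ---------------------------------------------------------------------------

_K12 = 12


def _library_kmer_index(lib: TagLibrary) -> dict[str, list]:
    """12-mer -> tags index, cached on the library object.

    A tag within 3 nt terminal divergence of an 18-26 nt mature shares
    an exact run of >= 12 nt with it, so the index is a safe prefilter.
    The cache is invalidated by the library's tag-count fingerprint.
    """
    fingerprint = (len(lib), lib.total_clean_reads)
    cached = getattr(lib, "_k12_cache", None)
    if cached is not None and cached[0] == fingerprint:
        return cached[1]
    index: dict[str, list] = {}
    for tag in lib:
        seen = set()
        for i in range(len(tag.sequence) - _K12 + 1):
            km = tag.sequence[i:i + _K12]
            if km not in seen:
                index.setdefault(km, []).append(tag)
                seen.add(km)
    lib._k12_cache = (fingerprint, index)
    return index


def count_novel_reads(mature: str, lib: TagLibrary, max_terminal: int = 3) -> int:
    """Read support of a candidate mature miRNA.

    Sums the counts of tags identical to the mature over their mutual
    overlap, allowing total terminal divergence (5' offset + 3'
    offset/non-template extension) of at most ``max_terminal`` nt.
    Internal mismatches disqualify a tag.
    """
    m = normalize_rna(mature)
    index = _library_kmer_index(lib)
    candidates: dict[str, Tag] = {}
    for i in range(len(m) - _K12 + 1):
        for tag in index.get(m[i:i + _K12], ()):
            candidates[tag.sequence] = tag
    total = 0
    for tag in sorted(candidates.values(), key=lambda t: t.sequence):
        t = tag.sequence
        matched = False
        for off in range(-max_terminal, max_terminal + 1):
            # off = position of t[0] relative to m[0]
            end_off = (off + len(t)) - len(m)
            if abs(off) + abs(end_off) > max_terminal:
                continue
            lo = max(0, off)
            hi = min(len(m), off + len(t))
            if hi <= lo:
                continue
            if all(m[p] == t[p - off] for p in range(lo, hi)):
                matched = True
                break
        if matched:
            total += tag.count
    return total


def call_novel_mirnas(candidates: Iterable[PrecursorCandidate],
                      libs: Sequence[TagLibrary],
                      params: HairpinParams = HairpinParams()) -> list[NovelMiRNA]:
    """Apply read support (c6) and deduplicate loci into final calls.

    Candidates passing the structural criteria are kept when their
    mature's read support exceeds ``min_reads - 1`` in at least one
    library; overlapping candidates on the same transcript locus keep
    only the lowest-MFE precursor.  Ids are assigned in deterministic
    order (transcript id, window start).
    """
    survivors: list[tuple[PrecursorCandidate, dict[str, int]]] = []
    support_cache: dict[tuple[str, str], int] = {}
    for cand in candidates:
        if not cand.structural_pass:
            continue
        counts = {}
        for lib in libs:
            key = (cand.window.tag, lib.label)
            if key not in support_cache:
                support_cache[key] = count_novel_reads(cand.window.tag, lib)
            counts[lib.label] = support_cache[key]
        cand.mature_count = max(counts.values()) if counts else 0
        cand.c6 = cand.mature_count >= params.min_reads
        if cand.c6:
            survivors.append((cand, counts))

    # deduplicate overlapping loci, keeping the lowest-MFE precursor
    survivors.sort(key=lambda cc: (cc[0].window.transcript_id, cc[0].window.start,
                                   cc[0].window.end, cc[0].window.tag))
    kept: list[tuple[PrecursorCandidate, dict[str, int]]] = []
    for cand, counts in survivors:
        merged = False
        for k, (kc, kcounts) in enumerate(kept):
            if (kc.window.transcript_id == cand.window.transcript_id
                    and cand.window.start < kc.window.end
                    and kc.window.start < cand.window.end):
                if cand.mfe < kc.mfe:
                    kept[k] = (cand, counts)
                merged = True
                break
        if merged:
            continue
        kept.append((cand, counts))
    kept.sort(key=lambda cc: (cc[0].window.transcript_id, cc[0].window.start))
    return [NovelMiRNA(f"novel_mir_{i + 1}", c.window.tag, c.arm or "?", c, counts)
            for i, (c, counts) in enumerate(kept)]
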