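"""Rule-based miRNA target prediction on a transcriptome.

A miRNA-length window slides along each transcript (sense strand; mRNA
targeting); each window is aligned, ungapped, against the miRNA and
scored per position as Watson-Crick pair (WC), G:U wobble (GU, priced
0.5 mismatch) or mismatch (MM).  A hit is accepted when all six rules
hold:

r1  total mismatch score (MM=1, GU=0.5) <= 4;
r2  no run of more than two consecutive MM anywhere in the duplex;
r3  no two consecutive MM within miRNA positions 2-12;
r4  no MM at miRNA positions 10 or 11;
r5  mismatch score over positions 1-12 <= 2.5;
r6  duplex MFE >= 75% of the MFE of the miRNA bound to its perfect
    complement (both from the same duplex energy model, so the ratio of
    a perfect site is exactly 1).

Positions are numbered 1-based from the miRNA 5' end.  G:U wobbles are
treated as paired (not MM) for the boolean rules r2-r4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .fold import duplex_energy, normalize_rna, perfect_complement_energy

__all__ = [
    "TargetParams",
    "DuplexAlignment",
    "TargetHit",
    "align_site",
    "score_duplex",
    "apply_criteria",
    "predict_targets",
    "hits_frame",
]

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class TargetParams:
    max_score: float = 4.0  # r1
    max_mm_run: int = 2  # r2: longest tolerated MM run
    seed_region: tuple[int, int] = (2, 12)  # r3 window (1-based, inclusive)
    no_mm_positions: tuple[int, ...] = (10, 11)  # r4
    max_score_1_12: float = 2.5  # r5
    min_mfe_ratio: float = 0.75  # r6


@dataclass(frozen=True)
class DuplexAlignment:
    """Per-position pairing states of an ungapped miRNA:site duplex.

    ``states[i]`` describes miRNA position i+1 (1-based from the miRNA
    5' end).  The site sequence is kept in transcript (5'->3')
    orientation; site position L-1-i faces miRNA position i.
    """

    mirna: str
    site: str
    states: tuple[str, ...]


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int  # 0-based, transcript coordinates
    end: int  # half-open
    alignment: DuplexAlignment
    mismatch_score: float = 0.0
    score_1_12: float = 0.0
    duplex_mfe: float = 0.0
    perfect_mfe: float = 0.0
    mfe_ratio: float = 0.0
    rules: dict[str, bool] | None = None

    @property
    def accepted(self) -> bool:
        return self.rules is not None and all(self.rules.values())


def align_site(mirna: str, site: str) -> DuplexAlignment:
    """Align a miRNA against an equal-length target site (ungapped).

    ``site`` is the transcript subsequence in its natural 5'->3'
    orientation; the duplex is antiparallel, so miRNA position i (0-based)
    faces site position L-1-i.
    """
    m = normalize_rna(mirna)
    s = normalize_rna(site)
    if len(m) != len(s):
        raise ValueError("miRNA and site must have equal length")
    states = []
    for i, b in enumerate(m):
        facing = s[len(s) - 1 - i]
        if (b, facing) in _WC:
            states.append("WC")
        elif (b, facing) in _GU:
            states.append("GU")
        else:
            states.append("MM")
    return DuplexAlignment(m, s, tuple(states))


def score_duplex(aln: DuplexAlignment) -> tuple[float, float, dict]:
    """Mismatch scores and MM-adjacency facts of an alignment.

    Returns (mismatch_score, score over positions 1-12, facts) where
    facts records the longest MM run overall, whether two consecutive
    MM occur within positions 2-12, and the MM positions (1-based).
    """
    score = 0.0
    score_1_12 = 0.0
    mm_positions = []
    for i, st in enumerate(aln.states):
        w = 1.0 if st == "MM" else (0.5 if st == "GU" else 0.0)
        score += w
        if i < 12:
            score_1_12 += w
        if st == "MM":
            mm_positions.append(i + 1)
    longest_run = run = 0
    prev = 0
    for p in mm_positions:
        run = run + 1 if p == prev + 1 else 1
        longest_run = max(longest_run, run)
        prev = p
    adjacent_in_seed = any(p + 1 in mm_positions and 2 <= p and p + 1 <= 12
                           for p in mm_positions)
    facts = {"longest_mm_run": longest_run,
             "adjacent_mm_2_12": adjacent_in_seed,
             "mm_positions": tuple(mm_positions)}
    return score, score_1_12, facts


def apply_criteria(hit: TargetHit, params: TargetParams = TargetParams()) -> TargetHit:
    """Score a hit's duplex, compute its energies and set rule flags."""
    aln = hit.alignment
    score, score_1_12, facts = score_duplex(aln)
    mask = [st in ("WC", "GU") for st in aln.states]
    hit.mismatch_score = score
    hit.score_1_12 = score_1_12
    hit.duplex_mfe = duplex_energy(aln.mirna, aln.site, mask).energy
    hit.perfect_mfe = perfect_complement_energy(aln.mirna)
    hit.mfe_ratio = (hit.duplex_mfe / hit.perfect_mfe
                     if hit.perfect_mfe < 0 else 0.0)
    mm = set(facts["mm_positions"])
    hit.rules = {
        "r1": score <= params.max_score,
        "r2": facts["longest_mm_run"] <= params.max_mm_run,
        "r3": not facts["adjacent_mm_2_12"],
        "r4": not any(p in mm for p in params.no_mm_positions),
        "r5": score_1_12 <= params.max_score_1_12,
        "r6": hit.mfe_ratio >= params.min_mfe_ratio,
    }
    return hit


def _quick_score(mirna: str, window: str, cap: float) -> float | None:
    """Mismatch score with early exit once the cap is exceeded."""
    score = 0.0
    L = len(mirna)
    for i in range(L):
        pair = (mirna[i], window[L - 1 - i])
        if pair in _WC:
            continue
        score += 0.5 if pair in _GU else 1.0
        if score > cap:
            return None
    return score


def predict_targets(mirnas: dict[str, str], transcripts: dict[str, str],
                    params: TargetParams = TargetParams()) -> list[TargetHit]:
    """Scan every transcript window against every miRNA and keep
    accepted hits; overlapping accepted windows of the same pair keep
    the best hit (lowest mismatch score, then lowest duplex energy,
    then leftmost)."""
    hits: list[TargetHit] = []
    for mid in sorted(mirnas):
        m = normalize_rna(mirnas[mid])
        if not (15 <= len(m) <= 30):
            raise ValueError(f"miRNA {mid!r} length {len(m)} outside the scanning range")
        L = len(m)
        accepted: list[TargetHit] = []
        for tid in sorted(transcripts):
            tseq = normalize_rna(transcripts[tid])
            for start in range(0, len(tseq) - L + 1):
                window = tseq[start:start + L]
                if _quick_score(m, window, params.max_score) is None:
                    continue
                hit = TargetHit(mid, tid, start, start + L, align_site(m, window))
                apply_criteria(hit, params)
                if hit.accepted:
                    accepted.append(hit)
        # merge overlapping windows per (miRNA, transcript)
        accepted.sort(key=lambda h: (h.transcript_id, h.start))
        merged: list[TargetHit] = []
        for h in accepted:
            if (merged and merged[-1].transcript_id == h.transcript_id
                    and h.start < merged[-1].end):
                best = min(merged[-1], h,
                           key=lambda x: (x.mismatch_score, x.duplex_mfe, x.start))
                merged[-1] = best
            else:
                merged.append(h)
        hits.extend(merged)
    return hits


def hits_frame(hits: Iterable[TargetHit]) -> pd.DataFrame:
    """Tabular form of target hits (round-trips through TSV)."""
    rows = []
    for h in hits:
        row = {"mirna": h.mirna_id, "transcript": h.transcript_id,
               "start": h.start, "end": h.end,
               "mismatch_score": h.mismatch_score, "score_1_12": h.score_1_12,
               "duplex_mfe": round(h.duplex_mfe, 6),
               "perfect_mfe": round(h.perfect_mfe, 6),
               "mfe_ratio": round(h.mfe_ratio, 6)}
        row.update({r: bool(v) for r, v in (h.rules or {}).items()})
        row["accepted"] = h.accepted
        rows.append(row)
    return pd.DataFrame(rows)
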