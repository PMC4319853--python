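"""Seeded synthetic references and libraries with known ground truth.

Emulates the two-library (control CK / copper-treated TR) small-RNA
sequencing design at desk scale so that every pipeline stage can be
tested without downloads: random transcripts carry designed miRNA
hairpins (built by explicit stem construction and verified against the
hairpin criteria in their transcript context), a family-labelled
cross-species miRNA catalog provides the conserved miRNAs, structural
ncRNAs supply degradation fragments, and raw FASTQ reads mix canonical
matures, isomiR clouds, ncRNA fragments, adaptor/poly(A) artifacts and
low-quality reads.  Per-miRNA counts are Poisson with planted
fold-changes between the libraries; the length profile has modes at 21
and 24 nt with a 5'-U bias.  A TruthManifest records everything a
recovery test needs, and identical (config, seed) produce byte-identical
output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import ReferenceRecord, ReferenceSet
from .fold import normalize_rna, reverse_complement
from .hairpin import CandidateWindow, HairpinParams, evaluate_candidate
from .sra_io import RawRead

__all__ = [
    "TruthManifest",
    "PlantedPrecursor",
    "SimMiRNA",
    "make_references",
    "simulate_libraries",
    "simulate_count_pairs",
    "dinucleotide_shuffle",
    "write_fastq",
    "ADAPTOR_3P",
    "ADAPTOR_5P",
]

ADAPTOR_3P = "TCGTATGCCGTCTTCTGCTTG"
ADAPTOR_5P = "GTTCAGAGTTCTACAGTCCGACGATC"

_RNA = np.array(list("ACGU"))


@dataclass(frozen=True)
class PlantedPrecursor:
    precursor_id: str
    transcript_id: str
    start: int  # precursor interval on the transcript
    end: int
    mature: str
    mature_start: int  # transcript coordinates
    arm: str
    star: str


@dataclass(frozen=True)
class SimMiRNA:
    mirna_id: str
    kind: str  # conserved | novel
    family: str | None
    mature: str
    base_tpm: float
    log2fc: float


@dataclass
class TruthManifest:
    """The simulator's ground truth, sufficient for every recovery test."""

    seed: int
    transcripts: dict[str, int] = field(default_factory=dict)  # id -> length
    decoys: list[str] = field(default_factory=list)
    planted_precursors: list[PlantedPrecursor] = field(default_factory=list)
    mirnas: list[SimMiRNA] = field(default_factory=list)
    ncrna_classes: dict[str, str] = field(default_factory=dict)
    target_sites: list[dict] = field(default_factory=list)
    isomir_profile: dict = field(default_factory=dict)
    junk_fractions: dict = field(default_factory=dict)
    depths: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TruthManifest":
        if isinstance(source, Path) or (isinstance(source, str)
                                        and "\n" not in source
                                        and Path(source).exists()):
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        d["planted_precursors"] = [PlantedPrecursor(**p) for p in d["planted_precursors"]]
        d["mirnas"] = [SimMiRNA(**m) for m in d["mirnas"]]
        return cls(**d)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_RNA[rng.integers(0, 4, size=n)])


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul-Erickson).

    Edges of the doublet graph are permuted and reassembled along an
    Eulerian path from the original start to the original end vertex;
    the attempt is repeated until the sampled last-edge tree is
    consistent (guaranteed to terminate for sequences admitting one,
    which every original sequence does)."""
    s = normalize_rna(seq)
    if len(s) < 3:
        return s
    for _ in range(1000):
        edges: dict[str, list[str]] = {}
        for a, b in zip(s, s[1:]):
            edges.setdefault(a, []).append(b)
        for a in edges:
            perm = rng.permutation(len(edges[a]))
            edges[a] = [edges[a][i] for i in perm]
        out = [s[0]]
        node = s[0]
        total = len(s) - 1
        for _ in range(total):
            nxt_list = edges.get(node)
            if not nxt_list:
                break
            node = nxt_list.pop(0)
            out.append(node)
        if len(out) == len(s):
            return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian path")


# ---------------------------------------------------------------------------
# hairpin construction
# ---------------------------------------------------------------------------

def _build_precursor(mature: str, arm: str, stem: str, spacer: str) -> tuple[str, int, str]:
    """Explicit stem design: mature and its star (reverse complement of
    all but the last two mature nt, leaving 2-nt 3' overhangs on both
    strands) around a homopolymer loop, enclosed by a perfect lower
    stem.  Returns (precursor, mature offset, star)."""
    sp2, loop = spacer * 2, spacer * 8
    core = reverse_complement(mature[:-2])
    if arm == "5p":
        pre = stem + mature + loop + core + sp2 + reverse_complement(stem)
        ms = len(stem)
        star = core + sp2
    else:
        pre = stem + core + sp2 + loop + mature + sp2 + reverse_complement(stem)
        ms = len(stem) + len(core) + 2 + 8
        star = core + sp2
    return pre, ms, star


def _spacer_for(mature: str) -> str:
    return "C" if "G" not in (mature[-2:] + mature[0]) else "A"


def _sample_mature(rng: np.random.Generator, length: int = 21) -> str:
    return "U" + _random_seq(rng, length - 1)


def _verify_in_context(transcript: str, mature: str, mature_start: int,
                       params: HairpinParams) -> bool:
    """Both excision windows around the planted mature must pass the
    structural hairpin criteria when folded in transcript context."""
    he = mature_start + len(mature)
    ok = False
    for lo, hi in ((mature_start - params.flank, he + params.near),
                   (mature_start - params.near, he + params.flank)):
        lo, hi = max(0, lo), min(len(transcript), hi)
        win = CandidateWindow("ctx", lo, hi, transcript[lo:hi], mature,
                              mature_start - lo, 100)
        cand = evaluate_candidate(win, params)
        ok = ok or cand.structural_pass
    return ok


# ---------------------------------------------------------------------------
# references
# ---------------------------------------------------------------------------

def make_references(seed: int, n_transcripts: int = 30,
                    n_planted_precursors: int = 30,
                    n_conserved_families: int = 12, n_ncrna: int = 12,
                    n_target_sites: int = 8,
                    de_fraction: float = 0.25, planted_lfc: float = 2.0,
                    hairpin_params: HairpinParams = HairpinParams(),
                    ) -> tuple[ReferenceSet, ReferenceSet, ReferenceSet, TruthManifest]:
    """Generate transcriptome, miRNA catalog and ncRNA references plus
    the ground-truth manifest.

    Every planted hairpin is verified to pass the structural criteria in
    its final transcript context (bounded retries per plant); decoy
    transcripts are dinucleotide shuffles of the planted precursors.
    """
    rng = np.random.default_rng(seed)
    truth = TruthManifest(seed=int(seed))
    transcripts: dict[str, str] = {}
    for i in range(n_transcripts):
        tid = f"tx{i + 1:03d}"
        transcripts[tid] = _random_seq(rng, int(rng.integers(500, 3001)))

    # plant novel-miRNA hairpins
    tx_ids = sorted(transcripts)
    planted = 0
    attempts = 0
    while planted < n_planted_precursors:
        attempts += 1
        if attempts > 50 * max(1, n_planted_precursors):
            raise RuntimeError(
                f"hairpin construction failed after {attempts} attempts (seed {seed})")
        tid = tx_ids[planted % len(tx_ids)] if tx_ids else None
        if tid is None:
            break
        mature = _sample_mature(rng)
        arm = "5p" if rng.random() < 0.5 else "3p"
        stem = _random_seq(rng, 12)
        pre, ms, star = _build_precursor(mature, arm, stem, _spacer_for(mature))
        tseq = transcripts[tid]
        if len(tseq) < len(pre) + 100:
            continue
        pos = int(rng.integers(50, len(tseq) - len(pre) - 50))
        new_seq = tseq[:pos] + pre + tseq[pos + len(pre):]  # splice in place
        m_start = pos + ms
        if new_seq.count(mature) != 1:
            continue
        if not _verify_in_context(new_seq, mature, m_start, hairpin_params):
            continue
        transcripts[tid] = new_seq
        pid = f"planted_{planted + 1:03d}"
        truth.planted_precursors.append(PlantedPrecursor(
            pid, tid, pos, pos + len(pre), mature, m_start, arm, star))
        truth.mirnas.append(SimMiRNA(
            pid, "novel", None, mature,
            float(np.round(10 ** rng.uniform(2.0, 3.3), 2)), 0.0))
        planted += 1

    # conserved catalog: family-labelled matures + standalone precursors
    catalog = ReferenceSet()
    fam_numbers = rng.choice(np.arange(150, 400), size=n_conserved_families,
                             replace=False)
    for k in range(n_conserved_families):
        fam = f"miR{int(fam_numbers[k])}"
        mature = _sample_mature(rng, int(rng.choice([21, 21, 22])))
        stem = _random_seq(rng, 12)
        pre, ms, _ = _build_precursor(mature, "5p", stem, _spacer_for(mature))
        catalog.add(ReferenceRecord(f"ath-{fam}", mature, "miRNA_mature",
                                    family=fam, species="ath"))
        catalog.add(ReferenceRecord(f"ath-{fam}-pre", pre, "miRNA_precursor",
                                    family=fam, species="ath"))
        truth.mirnas.append(SimMiRNA(
            f"cons_{fam}", "conserved", fam, mature,
            float(np.round(10 ** rng.uniform(2.0, 3.5), 2)), 0.0))

    # plant fold-changes on a subset of all miRNAs
    n_de = int(round(de_fraction * len(truth.mirnas)))
    de_idx = rng.choice(len(truth.mirnas), size=n_de, replace=False)
    for i in sorted(int(j) for j in de_idx):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        m = truth.mirnas[i]
        truth.mirnas[i] = dataclasses.replace(m, log2fc=sign * planted_lfc)

    # ncRNA references
    ncrna = ReferenceSet()
    classes = ["rRNA", "tRNA", "snoRNA", "snRNA"]
    lengths = {"rRNA": 1500, "tRNA": 75, "snoRNA": 100, "snRNA": 150}
    for i in range(n_ncrna):
        cls = classes[i % 4]
        rid = f"{cls.lower()}_{i + 1:02d}"
        ncrna.add(ReferenceRecord(rid, _random_seq(rng, lengths[cls]), cls))
        truth.ncrna_classes[rid] = cls

    # planted target sites: exact complements of conserved matures
    conserved = [m for m in truth.mirnas if m.kind == "conserved"]
    for k in range(min(n_target_sites, len(conserved))):
        m = conserved[k]
        site = reverse_complement(m.mature)
        tid = tx_ids[int(rng.integers(0, len(tx_ids)))]
        tseq = transcripts[tid]
        pos = int(rng.integers(30, len(tseq) - len(site) - 30))
        # avoid stamping into a planted precursor
        if any(p.transcript_id == tid and pos < p.end and p.start < pos + len(site)
               for p in truth.planted_precursors):
            continue
        transcripts[tid] = tseq[:pos] + site + tseq[pos + len(site):]
        truth.target_sites.append({"mirna_id": m.mirna_id, "mature": m.mature,
                                   "transcript_id": tid, "start": pos,
                                   "end": pos + len(site)})

    # decoys: dinucleotide shuffles of the planted precursors
    transcriptome = ReferenceSet()
    for tid in tx_ids:
        transcriptome.add(ReferenceRecord(tid, transcripts[tid], "transcript"))
        truth.transcripts[tid] = len(transcripts[tid])
    for i, p in enumerate(truth.planted_precursors):
        did = f"decoy{i + 1:03d}"
        pre_seq = transcripts[p.transcript_id][p.start:p.end]
        transcriptome.add(ReferenceRecord(did, dinucleotide_shuffle(pre_seq, rng),
                                          "transcript"))
        truth.decoys.append(did)
        truth.transcripts[did] = p.end - p.start

    truth.isomir_profile = {"p_var5": 0.10, "p_var3": 0.20, "p_tail": 0.05}
    truth.junk_fractions = {"ncrna": 0.25, "adaptor5": 0.05, "polya": 0.03,
                            "no_insert": 0.04, "low_quality": 0.02,
                            "random": 0.20}
    return transcriptome, catalog, ncrna, truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _length_from_profile(rng: np.random.Generator) -> int:
    lengths = np.arange(15, 31)
    weights = np.ones(len(lengths))
    weights[lengths == 21] = 8.0
    weights[lengths == 24] = 5.0
    weights[(lengths >= 20) & (lengths <= 23)] += 1.5
    return int(rng.choice(lengths, p=weights / weights.sum()))


def _isomir_insert(mature: str, context: str | None, rng: np.random.Generator,
                   profile: dict) -> str:
    """Draw one read sequence from the isomiR cloud of a mature.

    5'/3' end shifts are templated from the precursor context when one
    is available; non-template tails deliberately differ from the next
    templated base."""
    seq = mature
    start, end = 0, len(mature)
    pos = context.find(mature) if context else -1
    if pos >= 0 and rng.random() < profile["p_var5"]:
        d = int(rng.choice([-1, 1]))
        if 0 <= pos + d and pos + d < pos + end:
            start = d
    if pos >= 0 and rng.random() < profile["p_var3"]:
        d = int(rng.choice([-2, -1, 1], p=[0.25, 0.4, 0.35]))
        if pos + len(mature) + d <= len(context) and len(mature) + d - start > 12:
            end = len(mature) + d
    if pos >= 0:
        seq = context[pos + start:pos + end]
    if rng.random() < profile["p_tail"]:
        nxt = (context[pos + end] if (pos >= 0 and pos + end < len(context))
               else "A")
        choices = [b for b in "ACGU" if b != nxt]
        seq = seq + "".join(rng.choice(choices)
                            for _ in range(int(rng.choice([1, 1, 2]))))
    return seq


def simulate_libraries(truth: TruthManifest, transcriptome: ReferenceSet,
                       catalog: ReferenceSet, ncrna: ReferenceSet,
                       depth_ck: int = 100_000, depth_tr: int = 100_000,
                       seed: int | None = None,
                       ) -> tuple[list[RawRead], list[RawRead]]:
    """Emit raw reads for the CK and TR libraries.

    Per-miRNA read counts are Poisson with mean = base TPM x depth/1e6
    (TR scaled by 2^log2fc); each miRNA read is drawn from its isomiR
    cloud.  The remaining depth is filled with ncRNA degradation
    fragments, 5'-adaptor contaminants, poly(A) artifacts,
    adaptor-adaptor ligation products, low-quality reads and random
    tags following the 21/24-nt, 5'-U-biased length profile.  Reads
    carry the 3' adaptor so that cleaning has real work to do.
    """
    seed = truth.seed if seed is None else seed
    contexts: dict[str, str | None] = {}
    tx = {r.id: r.sequence for r in transcriptome}
    pre_by_id = {p.precursor_id: p for p in truth.planted_precursors}
    cat_pre = {r.family: r.sequence for r in catalog.by_class("miRNA_precursor")}
    for m in truth.mirnas:
        if m.kind == "novel":
            p = pre_by_id[m.mirna_id]
            contexts[m.mirna_id] = tx[p.transcript_id][p.start:p.end]
        else:
            contexts[m.mirna_id] = cat_pre.get(m.family)
    ncrna_seqs = [r.sequence for r in ncrna]
    depths = {"CK": depth_ck, "TR": depth_tr}
    truth.depths = dict(depths)
    out = []
    for li, (label, depth) in enumerate(depths.items()):
        rng = np.random.default_rng((seed + 1) * 1000 + li)
        inserts: list[str] = []
        if depth > 0:
            for m in truth.mirnas:
                mean = m.base_tpm * depth / 1e6
                if label == "TR":
                    mean *= 2.0 ** m.log2fc
                count = int(rng.poisson(mean))
                for _ in range(count):
                    inserts.append(_isomir_insert(m.mature, contexts[m.mirna_id],
                                                  rng, truth.isomir_profile))
        n_mirna = len(inserts)
        reads: list[RawRead] = []
        jf = truth.junk_fractions
        n_rest = max(0, depth - n_mirna)
        shares = np.array([jf["ncrna"], jf["adaptor5"], jf["polya"],
                           jf["no_insert"], jf["low_quality"], jf["random"]])
        shares = shares / shares.sum()
        counts = np.floor(shares * n_rest).astype(int)
        counts[0] += n_rest - counts.sum()
        n_nc, n_a5, n_pa, n_ni, n_lq, n_rand = (int(c) for c in counts)
        for _ in range(n_nc):
            src = ncrna_seqs[int(rng.integers(0, len(ncrna_seqs)))]
            ln = min(_length_from_profile(rng), len(src))
            start = int(rng.integers(0, len(src) - ln + 1))
            inserts.append(src[start:start + ln])
        for _ in range(n_rand):
            ln = _length_from_profile(rng)
            first = "U" if rng.random() < 0.5 else str(_RNA[rng.integers(0, 4)])
            inserts.append(first + _random_seq(rng, ln - 1))
        # assemble plain reads: insert + 3' adaptor (DNA alphabet)
        for k, ins in enumerate(inserts):
            dna = ins.replace("U", "T")
            reads.append(RawRead(f"{label}_r{k + 1}", dna + ADAPTOR_3P,
                                 tuple([40] * (len(dna) + len(ADAPTOR_3P)))))
        k0 = len(reads)
        for j in range(n_a5):
            ins = _random_seq(rng, 21).replace("U", "T")
            seq = ADAPTOR_5P + ins + ADAPTOR_3P
            reads.append(RawRead(f"{label}_a5_{j + 1}", seq, tuple([40] * len(seq))))
        for j in range(n_pa):
            seq = "A" * int(rng.integers(18, 28)) + ADAPTOR_3P
            reads.append(RawRead(f"{label}_pa_{j + 1}", seq, tuple([40] * len(seq))))
        for j in range(n_ni):
            seq = ADAPTOR_3P + ADAPTOR_3P[:10]
            reads.append(RawRead(f"{label}_ni_{j + 1}", seq, tuple([40] * len(seq))))
        for j in range(n_lq):
            ins = _random_seq(rng, 22).replace("U", "T")
            seq = ins + ADAPTOR_3P
            reads.append(RawRead(f"{label}_lq_{j + 1}", seq, tuple([2] * len(seq))))
        out.append(reads)
    return out[0], out[1]


def write_fastq(reads: list[RawRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in (r.quality or [40] * len(r.sequence)))
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def _terminal_divergence(a: str, b: str, max_d: int = 3) -> bool:
    """True when a and b are identical over their overlap with total
    terminal offset at most max_d (the novel-read counting tolerance)."""
    for off in range(-max_d, max_d + 1):
        end_off = (off + len(a)) - len(b)
        if abs(off) + abs(end_off) > max_d:
            continue
        lo, hi = max(0, off), min(len(b), off + len(a))
        if hi > lo and all(b[p] == a[p - off] for p in range(lo, hi)):
            return True
    return False


def recovered_precursors(truth: TruthManifest,
                         calls: list[tuple[str, int, int, str]]) -> set[str]:
    """Which planted precursors a set of novel-miRNA calls recovers.

    ``calls`` are (transcript id, window start, window end, mature).  A
    planted precursor counts as recovered when a call's window overlaps
    its interval on the same transcript and the called mature matches
    the planted mature up to 3 nt of terminal divergence (Dicer end
    ambiguity reproduced by the isomiR cloud makes exact end identity
    too strict a criterion)."""
    hit = set()
    for p in truth.planted_precursors:
        for tid, start, end, mature in calls:
            if (tid == p.transcript_id and start < p.end and p.start < end
                    and _terminal_divergence(mature, p.mature)):
                hit.add(p.precursor_id)
                break
    return hit


# ---------------------------------------------------------------------------
# count-level simulation for DE calibration / recovery
# ---------------------------------------------------------------------------

def simulate_count_pairs(n_mirnas: int, n_de: int, lfc: float, seed: int,
                         depth: int = 1_000_000,
                         tpm_range: tuple[float, float] = (100.0, 2000.0),
                         ) -> tuple[list, set[str]]:
    """Poisson count pairs for DE testing: ``n_de`` of ``n_mirnas`` get a
    true |log2fc| of ``lfc`` (alternating sign), the rest are null.
    Returns (CountPair list, ids of the truly changed miRNAs)."""
    from .diffexpr import CountPair

    rng = np.random.default_rng(seed)
    log_lo, log_hi = np.log10(tpm_range[0]), np.log10(tpm_range[1])
    pairs, de_ids = [], set()
    for i in range(n_mirnas):
        mid = f"sim_mir_{i + 1:04d}"
        base = 10 ** rng.uniform(log_lo, log_hi)
        true_lfc = 0.0
        if i < n_de:
            true_lfc = lfc if i % 2 == 0 else -lfc
            de_ids.add(mid)
        mean_ck = base * depth / 1e6
        mean_tr = mean_ck * 2.0 ** true_lfc
        pairs.append(CountPair(mid, int(rng.poisson(mean_ck)),
                               int(rng.poisson(mean_tr)), depth, depth))
    return pairs, de_ids
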