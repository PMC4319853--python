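"""Pipeline orchestration: simulate -> clean -> annotate -> discover ->
isomir -> targets -> de -> report, each stage writing its own TSV/FASTA
outputs into a run directory.  Stages never mutate another stage's
outputs; re-running a stage with unchanged inputs is idempotent, and a
full run with the same config and seed is byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import annotate as ann
from . import diffexpr as de
from . import hairpin as hp
from . import isomir as iso
from . import sra_io
from . import synthetic_data as sim
from . import targets as tg
from .config import PipelineConfig

__all__ = ["run_all", "report", "simulate_stage", "clean_stage"]

log = logging.getLogger("peony")

LIBS = ("CK", "TR")


def _outdir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


def simulate_stage(config: PipelineConfig, outdir) -> None:
    out = _outdir(outdir)
    transcriptome, catalog, ncrna, truth = sim.make_references(
        seed=config.seed, n_transcripts=config.n_transcripts,
        n_planted_precursors=config.n_planted_precursors,
        n_conserved_families=config.n_conserved_families,
        n_ncrna=config.n_ncrna, hairpin_params=config.hairpin_params())
    reads_ck, reads_tr = sim.simulate_libraries(
        truth, transcriptome, catalog, ncrna,
        depth_ck=config.depth_ck, depth_tr=config.depth_tr)
    ann.write_reference_fasta(transcriptome, out / "transcriptome.fa")
    ann.write_reference_fasta(catalog, out / "mirna_catalog.fa")
    ann.write_reference_fasta(ncrna, out / "ncrna.fa")
    sim.write_fastq(reads_ck, out / "CK.fastq")
    sim.write_fastq(reads_tr, out / "TR.fastq")
    truth.to_json(out / "truth.json")
    log.info("simulate: %d transcripts, %d reads CK, %d reads TR",
             len(truth.transcripts), len(reads_ck), len(reads_tr))


def clean_stage(config: PipelineConfig, outdir) -> dict[str, sra_io.TagLibrary]:
    out = _outdir(outdir)
    libs = {}
    for label in LIBS:
        fq = out / f"{label}.fastq"
        if not fq.exists():
            raise FileNotFoundError(f"missing input {fq}")
        lib, rep = sra_io.clean_reads(sra_io.read_fastq(fq), config.adaptor_3p,
                                      config.adaptor_5p,
                                      config.cleaning_params(), label=label)
        sra_io.write_tag_fasta(lib, out / f"tags_{label}.fa")
        rep.to_frame().to_csv(out / f"clean_{label}.tsv", sep="\t", index=False)
        libs[label] = lib
        log.info("clean %s: %d reads retained, %d unique tags",
                 label, lib.total_clean_reads, len(lib))
    return libs


def _load_libs(out: Path) -> dict[str, sra_io.TagLibrary]:
    libs = {}
    for label in LIBS:
        fa = out / f"tags_{label}.fa"
        if not fa.exists():
            raise FileNotFoundError(f"missing stage output {fa}; run clean first")
        libs[label] = sra_io.read_tag_fasta(fa, label=label)
    return libs


def _union_library(libs: dict[str, sra_io.TagLibrary]) -> sra_io.TagLibrary:
    union = sra_io.TagLibrary("ALL")
    for lib in libs.values():
        for tag in lib:
            union.add(tag.sequence, tag.count)
    return union


def annotate_stage(config: PipelineConfig, outdir) -> None:
    out = _outdir(outdir)
    libs = _load_libs(out)
    transcriptome = ann.read_reference_fasta(out / "transcriptome.fa")
    catalog = ann.read_reference_fasta(out / "mirna_catalog.fa")
    ncrna = ann.read_reference_fasta(out / "ncrna.fa")
    union = _union_library(libs)
    temp_db = ann.build_temp_mirna_db(union, catalog, config.max_mismatches)
    profiles = {label: ann.quantify_conserved(libs[label], temp_db,
                                              config.max_mismatches)
                for label in LIBS}
    rows = []
    for fam, rep in temp_db.items():
        counts = {label: next((p.count for p in profiles[label] if p.family == fam), 0)
                  for label in LIBS}
        rows.append({"mirna": f"pos-{fam}", "family": fam, "sequence": rep.sequence,
                     "count_CK": counts["CK"], "count_TR": counts["TR"]})
    pd.DataFrame(rows).to_csv(out / "conserved_mirna.tsv", sep="\t", index=False)
    for label in LIBS:
        hits = ann.map_perfect(libs[label], transcriptome)
        table = ann.annotate_library(libs[label], transcriptome, ncrna,
                                     profiles[label], hits=hits)
        table.to_frame().to_csv(out / f"annotation_{label}.tsv", sep="\t",
                                index=False)
        table.composition(libs[label]).to_csv(out / f"composition_{label}.tsv",
                                              sep="\t", index=False)
    log.info("annotate: %d conserved families", len(temp_db))


def discover_stage(config: PipelineConfig, outdir) -> None:
    out = _outdir(outdir)
    libs = _load_libs(out)
    transcriptome = ann.read_reference_fasta(out / "transcriptome.fa")
    params = config.hairpin_params()
    union = _union_library(libs)
    unannotated: dict[str, list] = {}
    annot = {label: pd.read_csv(out / f"annotation_{label}.tsv", sep="\t")
             for label in LIBS}
    status: dict[str, set] = {}
    for label in LIBS:
        for _, row in annot[label].iterrows():
            status.setdefault(row["tag"], set()).add(row["category"])
    hits = ann.map_perfect(union, transcriptome)
    for seq, tag_hits in hits.items():
        if status.get(seq) == {"unannotated_mapped"}:
            unannotated[seq] = tag_hits
    transcripts = {r.id: r.sequence for r in transcriptome}
    windows = hp.excise_candidates(unannotated, union, transcripts, params)
    candidates = [hp.evaluate_candidate(w, params) for w in windows]
    novel = hp.call_novel_mirnas(candidates, [libs[l] for l in LIBS], params)
    rows = []
    for n in novel:
        rows.append({"mirna": n.mirna_id, "mature": n.mature, "arm": n.arm,
                     "transcript": n.precursor.window.transcript_id,
                     "precursor_start": n.precursor.window.start,
                     "precursor_end": n.precursor.window.end,
                     "mfe": round(n.precursor.mfe, 3),
                     "mfei": round(n.precursor.mfei, 4),
                     "gc": round(n.precursor.gc_fraction, 4),
                     "count_CK": n.counts.get("CK", 0),
                     "count_TR": n.counts.get("TR", 0)})
    pd.DataFrame(rows, columns=["mirna", "mature", "arm", "transcript",
                                "precursor_start", "precursor_end", "mfe",
                                "mfei", "gc", "count_CK", "count_TR"]
                 ).to_csv(out / "novel_mirna.tsv", sep="\t", index=False)
    with open(out / "precursors.fa", "w") as fa, open(out / "precursors.dot", "w") as dot:
        for n in novel:
            w = n.precursor.window
            fa.write(f">{n.mirna_id} {w.transcript_id}:{w.start}-{w.end}\n{w.sequence}\n")
            dot.write(f">{n.mirna_id}\n{w.sequence}\n{n.precursor.fold.structure}\n")
    rej = [{"transcript": c.window.transcript_id, "start": c.window.start,
            "end": c.window.end, "tag": c.window.tag, "mfe": round(c.mfe, 3),
            "reason": c.reject_reason or ("accepted" if c.structural_pass else "")}
           for c in candidates if not c.structural_pass]
    pd.DataFrame(rej, columns=["transcript", "start", "end", "tag", "mfe",
                               "reason"]).to_csv(out / "rejected_candidates.tsv",
                                                 sep="\t", index=False)
    log.info("discover: %d windows, %d novel miRNAs", len(windows), len(novel))


def _collect_precursors(out: Path) -> list[iso.Precursor]:
    """Precursor set for isomiR analysis: conserved catalog precursors
    (canonical = the family representative, located on the precursor)
    plus called novel precursors (canonical = the called mature)."""
    precursors = []
    catalog = ann.read_reference_fasta(out / "mirna_catalog.fa")
    cons = pd.read_csv(out / "conserved_mirna.tsv", sep="\t")
    rep_by_family = dict(zip(cons["family"], cons["sequence"]))
    for rec in catalog.by_class("miRNA_precursor"):
        rep = rep_by_family.get(rec.family)
        if rep is None:
            continue
        pos = rec.sequence.find(rep)
        if pos < 0:
            # representative differs from the catalog mature; anchor on
            # the catalog mature of the same family instead
            mature = next((r.sequence for r in catalog.by_class("miRNA_mature")
                           if r.family == rec.family), None)
            pos = rec.sequence.find(mature) if mature else -1
            rep = mature
        if pos >= 0 and rep:
            precursors.append(iso.Precursor(rec.id, rec.sequence, pos,
                                            pos + len(rep)))
    novel = pd.read_csv(out / "novel_mirna.tsv", sep="\t")
    pre_seqs = dict((h.split()[0], s) for h, s in
                    sra_io.read_fasta(out / "precursors.fa")) if (
        out / "precursors.fa").exists() else {}
    for _, row in novel.iterrows():
        seq = pre_seqs.get(row["mirna"])
        if seq is None:
            continue
        pos = seq.find(row["mature"])
        if pos >= 0:
            precursors.append(iso.Precursor(row["mirna"], seq, pos,
                                            pos + len(row["mature"])))
    return precursors


def isomir_stage(config: PipelineConfig, outdir) -> None:
    out = _outdir(outdir)
    libs = _load_libs(out)
    precursors = _collect_precursors(out)
    catalogs = {label: iso.catalog_isomirs(libs[label], precursors)
                for label in LIBS}
    keyed: dict[tuple, dict] = {}
    for label in LIBS:
        for v in catalogs[label]:
            key = (v.precursor_id, v.tag)
            row = keyed.setdefault(key, {
                "precursor": v.precursor_id, "tag": v.tag,
                "offset5": v.offset5, "offset3": v.offset3, "tail": v.tail,
                "class": v.variant_class, "count_CK": 0, "count_TR": 0})
            row[f"count_{label}"] = v.count
    pd.DataFrame(sorted(keyed.values(), key=lambda r: (r["precursor"], r["tag"])),
                 columns=["precursor", "tag", "offset5", "offset3", "tail",
                          "class", "count_CK", "count_TR"]
                 ).to_csv(out / "isomir_catalog.tsv", sep="\t", index=False)
    both = [v for label in LIBS for v in catalogs[label]]
    iso.summarize_isomirs(both).to_csv(out / "isomir_summary.tsv", sep="\t",
                                       index=False)
    log.info("isomir: %d catalog rows", len(keyed))


def targets_stage(config: PipelineConfig, outdir) -> None:
    out = _outdir(outdir)
    transcriptome = ann.read_reference_fasta(out / "transcriptome.fa")
    cons = pd.read_csv(out / "conserved_mirna.tsv", sep="\t")
    novel = pd.read_csv(out / "novel_mirna.tsv", sep="\t")
    mirnas = dict(zip(cons["mirna"], cons["sequence"]))
    mirnas.update(zip(novel["mirna"], novel["mature"]))
    transcripts = {r.id: r.sequence for r in transcriptome}
    hits = tg.predict_targets(mirnas, transcripts, config.target_params())
    tg.hits_frame(hits).to_csv(out / "targets.tsv", sep="\t", index=False)
    log.info("targets: %d accepted hits", len(hits))


def de_stage(config: PipelineConfig, outdir) -> None:
    out = _outdir(outdir)
    libs = _load_libs(out)
    n1 = libs["CK"].total_clean_reads
    n2 = libs["TR"].total_clean_reads
    cons = pd.read_csv(out / "conserved_mirna.tsv", sep="\t")
    novel = pd.read_csv(out / "novel_mirna.tsv", sep="\t")
    pairs = []
    for _, row in pd.concat([cons, novel.rename(columns={"mature": "sequence"})],
                            ignore_index=True).iterrows():
        pairs.append(de.CountPair(row["mirna"], int(row["count_CK"]),
                                  int(row["count_TR"]), n1, n2))
    results = de.call_de(pairs, p_thresh=config.p_thresh,
                         lfc_thresh=config.lfc_thresh,
                         pseudo=config.pseudo_tpm, adjust=config.adjust)
    de.de_table(results).to_csv(out / "de_results.tsv", sep="\t", index=False)
    log.info("de: %d significant of %d", sum(r.significant for r in results),
             len(results))


def report(outdir) -> pd.DataFrame:
    """Consolidated summary: library sizes, composition, conserved/novel
    counts, CK/TR common-vs-specific tags and significant DE counts."""
    out = Path(outdir)
    required = ["tags_CK.fa", "tags_TR.fa", "conserved_mirna.tsv",
                "novel_mirna.tsv", "de_results.tsv"]
    for name in required:
        if not (out / name).exists():
            raise FileNotFoundError(f"incomplete run: missing stage output {name}")
    libs = _load_libs(out)
    for label in LIBS:
        sra_io.length_distribution(libs[label]).to_csv(
            out / f"length_dist_{label}.tsv", sep="\t", index=False)
        sra_io.first_nucleotide_bias(libs[label]).to_csv(
            out / f"first_base_{label}.tsv", sep="\t", index=False)
    ck, tr = set(libs["CK"].sequences), set(libs["TR"].sequences)
    common = ck & tr
    common_reads = sum(libs["CK"].count(s) + libs["TR"].count(s) for s in common)
    total_reads = libs["CK"].total_clean_reads + libs["TR"].total_clean_reads
    cons = pd.read_csv(out / "conserved_mirna.tsv", sep="\t")
    novel = pd.read_csv(out / "novel_mirna.tsv", sep="\t")
    der = pd.read_csv(out / "de_results.tsv", sep="\t")
    rows = [
        ("clean_reads_CK", libs["CK"].total_clean_reads),
        ("clean_reads_TR", libs["TR"].total_clean_reads),
        ("unique_tags_CK", len(libs["CK"])),
        ("unique_tags_TR", len(libs["TR"])),
        ("common_unique_tags", len(common)),
        ("common_unique_fraction", round(len(common) / max(1, len(ck | tr)), 4)),
        ("common_read_fraction", round(common_reads / max(1, total_reads), 4)),
        ("conserved_mirnas", len(cons)),
        ("conserved_families", cons["family"].nunique() if len(cons) else 0),
        ("novel_mirnas", len(novel)),
        ("novel_3p_arm", int((novel["arm"] == "3p").sum()) if len(novel) else 0),
        ("novel_5p_arm", int((novel["arm"] == "5p").sum()) if len(novel) else 0),
        ("de_significant", int(der["significant"].sum()) if len(der) else 0),
        ("de_up", int((der["direction"] == "up").sum()) if len(der) else 0),
        ("de_down", int((der["direction"] == "down").sum()) if len(der) else 0),
    ]
    summary = pd.DataFrame(rows, columns=["metric", "value"])
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    return summary


STAGES = {
    "simulate": simulate_stage,
    "clean": clean_stage,
    "annotate": annotate_stage,
    "discover": discover_stage,
    "isomir": isomir_stage,
    "targets": targets_stage,
    "de": de_stage,
}


def run_all(config: PipelineConfig, outdir, simulate: bool = True) -> pd.DataFrame:
    """Execute every stage in order and return the summary table.

    With ``simulate=False`` the run directory must already contain
    CK.fastq/TR.fastq and the three reference FASTAs.
    """
    out = _outdir(outdir)
    (out / "resolved_config.yaml").write_text(config.to_yaml())
    order = (["simulate"] if simulate else []) + [
        "clean", "annotate", "discover", "isomir", "targets", "de"]
    if not simulate:
        for name in ("CK.fastq", "TR.fastq", "transcriptome.fa",
                     "mirna_catalog.fa", "ncrna.fa"):
            if not (out / name).exists():
                raise FileNotFoundError(f"missing input {out / name}")
    for name in order:
        log.info("stage %s", name)
        STAGES[name](config, out)
    return report(out)
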