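"""Mapping, ncRNA classification and conserved-miRNA identification."""

import pytest

from peony_srna.annotate import (ReferenceRecord, ReferenceSet, annotate_library,
                                 build_temp_mirna_db, classify_ncrna,
                                 map_perfect, quantify_conserved,
                                 read_reference_fasta, write_reference_fasta)
from peony_srna.fold import reverse_complement
from peony_srna.sra_io import Tag, TagLibrary

MAT = "UGACAGAAGAGAGUGAGCACA"  # a 21-nt mature used across fixtures


def _mm(seq, *positions):
    """Substitute at the given positions (A<->C, G<->U)."""
    swap = {"A": "C", "C": "A", "G": "U", "U": "G"}
    out = list(seq)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


@pytest.fixture
def transcriptome():
    t1 = "ACGU" * 10 + MAT + "GCGC" * 10
    t2 = "UUUU" * 5 + MAT + "AAAA" * 5
    return ReferenceSet([ReferenceRecord("t1", t1, "transcript"),
                         ReferenceRecord("t2", t2, "transcript")])


class TestMapPerfect:
    def test_exact_substring_hit_interval(self, transcriptome):
        lib = TagLibrary("x", [Tag(MAT, 5)])
        hits = map_perfect(lib, transcriptome)
        h = [h for h in hits[MAT] if h.ref_id == "t1"][0]
        assert (h.start, h.end, h.strand) == (40, 61, "+")

    def test_tag_in_two_transcripts_two_hits(self, transcriptome):
        hits = map_perfect(TagLibrary("x", [Tag(MAT, 1)]), transcriptome)
        assert {h.ref_id for h in hits[MAT]} == {"t1", "t2"}

    def test_one_mismatch_everywhere_is_unmapped(self, transcriptome):
        lib = TagLibrary("x", [Tag(_mm(MAT, 10), 1)])
        assert map_perfect(lib, transcriptome) == {}

    def test_reverse_complement_maps_on_minus_strand(self, transcriptome):
        lib = TagLibrary("x", [Tag(reverse_complement(MAT), 1)])
        hits = map_perfect(lib, transcriptome)
        assert all(h.strand == "-" for h in hits[reverse_complement(MAT)])


class TestClassifyNcrna:
    def test_priority_rrna_over_trna(self):
        frag = "GGAUCCGGAUCCGGAUCCGG"
        refs = ReferenceSet([
            ReferenceRecord("r1", "AAAA" + frag + "CCCC", "rRNA"),
            ReferenceRecord("t1", "UUUU" + frag + "GGGG", "tRNA")])
        out = classify_ncrna(TagLibrary("x", [Tag(frag, 1)]), refs)
        assert out[frag] == "rRNA"

    def test_unmatched_tag_left_unclassified(self):
        refs = ReferenceSet([ReferenceRecord("r1", "G" * 50, "rRNA")])
        assert classify_ncrna(TagLibrary("x", [Tag("ACGU" * 5, 1)]), refs) == {}

    def test_simulated_trna_fragment(self, small_sim, small_libs):
        """A fragment cut from a simulated tRNA classifies as tRNA."""
        trna = small_sim["ncrna"].by_class("tRNA")[0]
        frag = trna.sequence[10:30]
        out = classify_ncrna(TagLibrary("x", [Tag(frag, 1)]), small_sim["ncrna"])
        assert out[frag] == "tRNA"


@pytest.fixture
def catalog():
    return ReferenceSet([
        ReferenceRecord("ath-miR156", MAT, "miRNA_mature", family="miR156",
                        species="ath"),
        ReferenceRecord("osa-miR157", _mm(MAT, 0, 5, 9, 13, 17), "miRNA_mature",
                        family="miR157", species="osa")])


class TestTempDatabase:
    def test_highest_expression_tag_is_representative(self, catalog):
        lib = TagLibrary("x", [Tag(MAT, 100), Tag(_mm(MAT, 3), 7)])
        db = build_temp_mirna_db(lib, catalog)
        assert db["miR156"].sequence == MAT
        assert db["miR156"].count == 100

    def test_three_mismatches_excluded(self, catalog):
        lib = TagLibrary("x", [Tag(_mm(MAT, 2, 8, 14), 50)])
        assert "miR156" not in build_temp_mirna_db(lib, catalog)

    def test_count_tie_breaks_lexicographically(self, catalog):
        a, b = sorted([_mm(MAT, 2), _mm(MAT, 4)])
        lib = TagLibrary("x", [Tag(a, 10), Tag(b, 10)])
        assert build_temp_mirna_db(lib, catalog)["miR156"].sequence == a

    def test_empty_catalog_empty_db(self):
        lib = TagLibrary("x", [Tag(MAT, 5)])
        assert build_temp_mirna_db(lib, ReferenceSet()) == {}


class TestQuantifyConserved:
    def test_member_sum_stops_at_two_mismatches(self, catalog):
        """Members at 0/1/2 mismatches sum; a 3-mismatch tag does not."""
        lib = TagLibrary("x", [Tag(MAT, 50), Tag(_mm(MAT, 2), 10),
                               Tag(_mm(MAT, 2, 8), 3), Tag(_mm(MAT, 2, 8, 14), 99)])
        db = build_temp_mirna_db(lib, catalog)
        profiles = quantify_conserved(lib, db)
        p156 = [p for p in profiles if p.family == "miR156"][0]
        assert p156.count == 63

    def test_no_nearby_tags_empty_profiles(self, catalog):
        lib = TagLibrary("x", [Tag("GGCC" * 5 + "G", 4)])
        assert quantify_conserved(lib, build_temp_mirna_db(lib, catalog)) == []

    def test_each_tag_assigned_once(self, small_sim, small_libs):
        lib = small_libs["CK"]
        db = build_temp_mirna_db(lib, small_sim["catalog"])
        profiles = quantify_conserved(lib, db)
        seen = [seq for p in profiles for seq, _ in p.members]
        assert len(seen) == len(set(seen))
        assert sum(p.count for p in profiles) <= lib.total_clean_reads

    def test_all_planted_families_recovered(self, small_sim, small_libs):
        lib = small_libs["CK"]
        db = build_temp_mirna_db(lib, small_sim["catalog"])
        profiles = quantify_conserved(lib, db)
        planted = {m.family for m in small_sim["truth"].mirnas
                   if m.kind == "conserved"}
        assert planted <= {p.family for p in profiles}


class TestAnnotationTable:
    def test_partition_covers_every_tag(self, small_sim, small_libs):
        lib = small_libs["TR"]
        db = build_temp_mirna_db(lib, small_sim["catalog"])
        profiles = quantify_conserved(lib, db)
        table = annotate_library(lib, small_sim["transcriptome"],
                                 small_sim["ncrna"], profiles)
        assert set(table.categories) == set(lib.sequences)
        comp = table.composition(lib)
        assert comp["unique_tags"].sum() == len(lib)
        assert comp["reads"].sum() == lib.total_clean_reads

    def test_determinism_of_table(self, small_sim, small_libs):
        lib = small_libs["CK"]
        db = build_temp_mirna_db(lib, small_sim["catalog"])
        profiles = quantify_conserved(lib, db)
        args = (lib, small_sim["transcriptome"], small_sim["ncrna"], profiles)
        assert annotate_library(*args).to_frame().equals(
            annotate_library(*args).to_frame())


def test_reference_fasta_round_trip(tmp_path, small_sim):
    path = tmp_path / "refs.fa"
    write_reference_fasta(small_sim["catalog"], path)
    again = read_reference_fasta(path)
    assert [(r.id, r.sequence, r.ref_class, r.family) for r in again] == \
        [(r.id, r.sequence, r.ref_class, r.family) for r in small_sim["catalog"]]
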