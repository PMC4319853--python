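"""Hairpin criteria, candidate excision, read support and novel calls."""

import random

import pytest

from peony_srna.annotate import TagHit
from peony_srna.fold import reverse_complement
from peony_srna.hairpin import (CandidateWindow, HairpinParams,
                                call_novel_mirnas, count_novel_reads,
                                evaluate_candidate, excise_candidates)
from peony_srna.sra_io import Tag, TagLibrary

# substitution that cannot pair with the given base
NOPAIR = {"A": "C", "C": "A", "G": "A", "U": "C"}

STEM = "GCAUCGGAUCGC"
LOOP, SP2 = "C" * 8, "CC"


def _mature():
    random.seed(2)
    return "U" + "".join(random.choice("ACGU") for _ in range(20))


def _build_5p(mature, star_core=None):
    core = star_core if star_core is not None else reverse_complement(mature[:-2])
    pre = STEM + mature + LOOP + core + SP2 + reverse_complement(STEM)
    return pre, len(STEM)


def _evaluate(pre, mature, ms, **kw):
    w = CandidateWindow("t", 0, len(pre), pre, mature, ms, 50)
    return evaluate_candidate(w, HairpinParams(**kw))


class TestCriteria:
    def test_designed_hairpin_passes_all_structural_criteria(self):
        m = _mature()
        pre, ms = _build_5p(m)
        c = _evaluate(pre, m, ms)
        assert (c.c2, c.c3, c.c4, c.c5) == (True, True, True, True)
        assert c.arm == "5p"
        assert c.mfe < -18 - 5  # construction leaves a wide margin

    def test_3p_arm_construction_passes(self):
        m = _mature()
        core = reverse_complement(m[:-2])
        pre = STEM + core + SP2 + LOOP + m + SP2 + reverse_complement(STEM)
        ms = len(STEM) + len(core) + 2 + 8
        c = _evaluate(pre, m, ms)
        assert c.structural_pass
        assert c.arm == "3p"

    def test_low_pairing_fraction_fails_c2(self):
        """Two 3-nt holes in the star drop mature pairing to ~62%: c2
        fails while the loop sizes stay within the c4 tolerance."""
        m = _mature()
        core = list(reverse_complement(m[:-2]))
        for start in (6, 13):
            for k in range(start, start + 3):
                core[k] = NOPAIR[m[len(m) - 3 - k]]
        pre, ms = _build_5p(m, "".join(core))
        c = _evaluate(pre, m, ms)
        assert not c.c2
        assert c.c3 and c.c4
        assert not c.structural_pass

    def test_weak_hairpin_fails_mfe_threshold(self):
        """An AU-rich duplex folds correctly but lands above -18."""
        m = "UAAUAAUAAAAAUUUUUUUAC"
        pre = m + LOOP + reverse_complement(m[:-2]) + SP2
        c = _evaluate(pre, m, 0)
        assert not c.c3
        assert -18 < c.mfe < 0
        assert c.c2 and c.c4 and c.c5
        assert not c.structural_pass

    def test_six_nt_bulge_fails_c4(self):
        m = _mature()
        core = reverse_complement(m[:-2])
        bulged = core[:9] + "".join(NOPAIR[x] for x in "AAAGGG") + core[9:]
        pre, ms = _build_5p(m, bulged)
        c = _evaluate(pre, m, ms)
        assert not c.c4
        assert c.c2 and c.c3 and c.c5
        assert not c.structural_pass

    def test_blunt_duplex_fails_c5(self):
        """A star complementary to the full mature leaves no 2-nt 3'
        overhang."""
        m = _mature()
        pre, ms = _build_5p(m, reverse_complement(m))
        c = _evaluate(pre, m, ms)
        assert not c.c5
        assert c.c2 and c.c3 and c.c4
        assert not c.structural_pass

    def test_relaxing_mfe_threshold_is_monotone(self):
        m = "UAAUAAUAAAAAUUUUUUUAC"
        pre = m + LOOP + reverse_complement(m[:-2]) + SP2
        strict = _evaluate(pre, m, 0, mfe_max=-18.0)
        relaxed = _evaluate(pre, m, 0, mfe_max=-5.0)
        assert not strict.c3 and relaxed.c3
        assert relaxed.structural_pass

    def test_too_short_window_rejected_with_reason(self):
        m = _mature()
        c = _evaluate(m + "CCCC", m, 0)
        assert c.reject_reason == "window_too_short"
        assert not c.structural_pass

    def test_accepted_candidate_reevaluates_identically(self):
        m = _mature()
        pre, ms = _build_5p(m)
        first = _evaluate(pre, m, ms)
        again = _evaluate(first.window.sequence, first.window.tag,
                          first.window.mature_interval[0])
        assert again.structural_pass
        assert again.mfe == first.mfe


class TestExcision:
    def _hits(self, tag, tid, start):
        return {tag: [TagHit(tag, tid, start, start + len(tag), "+")]}

    def test_flank_window_arithmetic(self):
        tag = "U" * 21
        tx = {"t1": "A" * 1000}
        lib = TagLibrary("x", [Tag(tag, 10)])
        wins = excise_candidates(self._hits(tag, "t1", 500), lib, tx)
        lengths = sorted(w.end - w.start for w in wins)
        assert lengths == [191, 191]  # flank 150 + tag 21 + near 20

    def test_window_clipped_at_transcript_start(self):
        tag = "U" * 21
        tx = {"t1": "A" * 300}
        lib = TagLibrary("x", [Tag(tag, 10)])
        wins = excise_candidates(self._hits(tag, "t1", 0), lib, tx)
        assert all(w.start == 0 for w in wins)

    def test_nearby_tags_share_a_locus(self):
        t1, t2 = "U" * 21, "A" + "U" * 20
        tx = {"t1": "G" * 1000}
        lib = TagLibrary("x", [Tag(t1, 10), Tag(t2, 3)])
        hits = {t1: [TagHit(t1, "t1", 500, 521, "+")],
                t2: [TagHit(t2, "t1", 505, 526, "+")]}
        wins = excise_candidates(hits, lib, tx)
        # both tags evaluated within one clustered locus, windows deduplicated
        assert len({(w.start, w.end, w.tag) for w in wins}) == len(wins)
        assert {w.tag for w in wins} == {t1, t2}


class TestReadSupport:
    def test_terminal_variants_counted_internal_mismatch_not(self):
        m = _mature()
        internal = m[:10] + NOPAIR[m[10]] + m[11:]
        lib = TagLibrary("x", [Tag(m, 10), Tag(m[:-1], 4), Tag(m + "CA", 3),
                               Tag(internal, 8)])
        assert count_novel_reads(m, lib) == 17

    def test_four_nt_shift_excluded(self):
        m = _mature()
        lib = TagLibrary("x", [Tag(m[4:] + "GGCA", 9)])
        assert count_novel_reads(m, lib) == 0

    def test_empty_library_zero(self):
        assert count_novel_reads(_mature(), TagLibrary("x")) == 0


class TestCalls:
    def _accepted_candidate(self, count_lib):
        m = _mature()
        pre, ms = _build_5p(m)
        cand = _evaluate(pre, m, ms)
        assert cand.structural_pass
        return cand, m

    @pytest.mark.parametrize("support,called", [(5, False), (6, True)])
    def test_read_support_strictly_more_than_five(self, support, called):
        cand, m = self._accepted_candidate(None)
        lib = TagLibrary("CK", [Tag(m, support)])
        novel = call_novel_mirnas([cand], [lib])
        assert bool(novel) is called

    def test_overlapping_candidates_keep_lowest_mfe(self):
        m = _mature()
        pre, ms = _build_5p(m)
        w1 = CandidateWindow("t1", 100, 100 + len(pre), pre, m, ms, 50)
        w2 = CandidateWindow("t1", 90, 90 + len(pre) + 10, "G" * 10 + pre, m,
                             10 + ms, 50)
        c1 = evaluate_candidate(w1)
        c2 = evaluate_candidate(w2)
        lib = TagLibrary("CK", [Tag(m, 40)])
        novel = call_novel_mirnas([c1, c2], [lib])
        assert len(novel) == 1
        assert novel[0].precursor.mfe == min(c1.mfe, c2.mfe)

    def test_ids_deterministic(self):
        cand, m = self._accepted_candidate(None)
        lib = TagLibrary("CK", [Tag(m, 40)])
        a = call_novel_mirnas([cand], [lib])
        b = call_novel_mirnas([cand], [lib])
        assert [n.mirna_id for n in a] == [n.mirna_id for n in b] == ["novel_mir_1"]


class TestPlantedRecovery:
    def test_planted_precursors_pass_in_context(self, small_sim, hairpin_params):
        """Every planted precursor, evaluated from its transcript context
        exactly as the discovery stage would, passes the structural
        criteria in at least one excision window."""
        truth = small_sim["truth"]
        tx = {r.id: r.sequence for r in small_sim["transcriptome"]}
        for p in truth.planted_precursors:
            seq = tx[p.transcript_id]
            he = p.mature_start + len(p.mature)
            passed = False
            for lo, hi in ((p.mature_start - hairpin_params.flank, he + 20),
                           (p.mature_start - 20, he + hairpin_params.flank)):
                lo, hi = max(0, lo), min(len(seq), hi)
                w = CandidateWindow(p.transcript_id, lo, hi, seq[lo:hi],
                                    p.mature, p.mature_start - lo, 100)
                passed = passed or evaluate_candidate(w, hairpin_params).structural_pass
            assert passed, p.precursor_id

    def test_shuffled_decoys_produce_no_calls(self, small_sim, small_libs):
        """Dinucleotide-shuffled decoy transcripts carry no perfect-match
        mature, so discovery yields zero candidate loci on them."""
        from peony_srna.annotate import map_perfect

        truth = small_sim["truth"]
        union = TagLibrary("ALL")
        for lib in small_libs.values():
            for tag in lib:
                union.add(tag.sequence, tag.count)
        hits = map_perfect(union, small_sim["transcriptome"])
        decoy_hits = {seq: hs for seq, hs in hits.items()
                      if any(h.ref_id in truth.decoys for h in hs)}
        planted_matures = {p.mature for p in truth.planted_precursors}
        assert not (set(decoy_hits) & planted_matures)
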