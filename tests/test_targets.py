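"""Duplex alignment, the six target rules and transcriptome scanning."""

import random

import pytest

from peony_srna.fold import reverse_complement
from peony_srna.targets import (TargetHit, TargetParams, align_site,
                                apply_criteria, hits_frame, predict_targets,
                                score_duplex)

MIRNA = "UGACAGAAGAGAGUGAGCACA"  # 21 nt
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def perfect_site(m=MIRNA):
    return reverse_complement(m)


def site_with(m, changes):
    """Site whose duplex shows the given state at 1-based miRNA positions.

    changes: {position: "MM"|"GU"}; all other positions Watson-Crick.
    """
    site = list(reverse_complement(m))
    L = len(m)
    for pos, state in changes.items():
        i = pos - 1  # miRNA index
        j = L - 1 - i  # site index facing it
        b = m[i]
        if state == "GU":
            # G:U wobble from the miRNA side needs miRNA G or U
            assert b in "GU", "wobble requires G or U on the miRNA"
            site[j] = "U" if b == "G" else "G"
        else:
            mm = {"A": "C", "C": "A", "G": "A", "U": "C"}[b]
            site[j] = mm
    return "".join(site)


def evaluated(m, site, params=TargetParams()):
    hit = TargetHit("m", "t", 0, len(m), align_site(m, site))
    return apply_criteria(hit, params)


class TestAlignment:
    def test_perfect_complement_all_wc(self):
        aln = align_site(MIRNA, perfect_site())
        assert set(aln.states) == {"WC"}

    def test_g_opposite_u_is_wobble(self):
        pos = MIRNA.index("G") + 1
        aln = align_site(MIRNA, site_with(MIRNA, {pos: "GU"}))
        assert aln.states[pos - 1] == "GU"

    def test_a_opposite_c_is_mismatch(self):
        pos = MIRNA.index("A") + 1
        aln = align_site(MIRNA, site_with(MIRNA, {pos: "MM"}))
        assert aln.states[pos - 1] == "MM"

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            align_site(MIRNA, "ACGU")


class TestScoring:
    def test_gu_counts_half(self):
        """3 MM + 2 GU = 4.0 (G-U priced at 0.5 mismatches)."""
        gu_pos = [i + 1 for i, b in enumerate(MIRNA) if b in "GU"][:2]
        mm_pos = [p for p in range(1, 22) if p not in gu_pos][:3]
        changes = {p: "GU" for p in gu_pos}
        changes.update({p: "MM" for p in mm_pos})
        score, _, _ = score_duplex(align_site(MIRNA, site_with(MIRNA, changes)))
        assert score == pytest.approx(4.0)

    def test_all_wc_scores_zero(self):
        score, s12, facts = score_duplex(align_site(MIRNA, perfect_site()))
        assert score == 0.0 and s12 == 0.0
        assert facts["longest_mm_run"] == 0

    def test_adjacent_mismatches_in_seed_detected(self):
        aln = align_site(MIRNA, site_with(MIRNA, {3: "MM", 4: "MM"}))
        _, _, facts = score_duplex(aln)
        assert facts["adjacent_mm_2_12"]


class TestRules:
    def test_perfect_complement_accepted_with_ratio_one(self):
        hit = evaluated(MIRNA, perfect_site())
        assert hit.accepted
        assert hit.mfe_ratio == 1.0  # exactly, by construction

    def test_r1_five_mismatches_rejected(self):
        hit = evaluated(MIRNA, site_with(MIRNA, {13: "MM", 15: "MM", 17: "MM",
                                                 19: "MM", 21: "MM"}))
        assert not hit.rules["r1"]
        assert not hit.accepted

    def test_r2_three_consecutive_mismatches_rejected(self):
        hit = evaluated(MIRNA, site_with(MIRNA, {15: "MM", 16: "MM", 17: "MM"}))
        assert not hit.rules["r2"]
        assert hit.rules["r1"]
        assert not hit.accepted

    def test_r3_adjacent_seed_mismatches_rejected(self):
        hit = evaluated(MIRNA, site_with(MIRNA, {3: "MM", 4: "MM"}))
        assert not hit.rules["r3"]
        assert hit.rules["r1"] and hit.rules["r2"]
        assert not hit.accepted

    def test_r4_mismatch_at_position_10_rejected(self):
        hit = evaluated(MIRNA, site_with(MIRNA, {10: "MM"}))
        assert not hit.rules["r4"]
        assert hit.rules["r1"] and hit.rules["r2"] and hit.rules["r3"]
        assert not hit.accepted

    def test_r5_three_seed_mismatches_rejected(self):
        hit = evaluated(MIRNA, site_with(MIRNA, {2: "MM", 5: "MM", 8: "MM"}))
        assert not hit.rules["r5"]
        assert hit.rules["r4"]
        assert not hit.accepted

    def test_r6_many_terminal_mismatches_lower_the_ratio(self):
        hit = evaluated(MIRNA, site_with(MIRNA, {18: "MM", 19: "MM", 21: "MM",
                                                 16: "MM"}))
        assert hit.mfe_ratio < 1.0
        if not hit.accepted:
            assert not hit.rules["r6"] or hit.mismatch_score <= 4

    def test_r6_threshold_configurable(self):
        site = site_with(MIRNA, {16: "MM", 18: "MM", 19: "MM", 21: "MM"})
        strict = evaluated(MIRNA, site, TargetParams(min_mfe_ratio=0.999))
        assert not strict.rules["r6"]
        assert not strict.accepted

    def test_gu_at_position_10_is_not_a_mismatch_for_r4(self):
        """A wobble at 10 keeps r4 (G-U is a pair for the boolean rules);
        two seed wobbles cost 1.0 <= 2.5 so r5 holds and the duplex is
        accepted."""
        m = "UGACAGAAGGGAGUGAGCACA"  # G at position 10 supports a wobble
        gu_in_seed = [p for p in range(2, 13) if m[p - 1] in "GU"
                      and p not in (10, 11)][0]
        hit = evaluated(m, site_with(m, {10: "GU", gu_in_seed: "GU"}))
        assert hit.rules["r4"]
        assert hit.score_1_12 == pytest.approx(1.0)
        assert hit.accepted


class TestScanning:
    def test_planted_complement_found_once(self):
        rng = random.Random(8)
        flank = lambda n: "".join(rng.choice("ACGU") for _ in range(n))
        tx = flank(300) + perfect_site() + flank(300)
        hits = predict_targets({"m1": MIRNA}, {"t1": tx})
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (300, 321)

    def test_random_transcript_yields_no_hits(self):
        rng = random.Random(12)
        tx = "".join(rng.choice("ACGU") for _ in range(1000))
        assert predict_targets({"m1": MIRNA}, {"t1": tx}) == []

    def test_empty_mirna_list_empty_output(self):
        assert predict_targets({}, {"t1": "ACGU" * 100}) == []

    def test_scan_order_independent(self):
        rng = random.Random(8)
        flank = lambda n: "".join(rng.choice("ACGU") for _ in range(n))
        t1 = flank(200) + perfect_site() + flank(100)
        t2 = flank(150)
        a = predict_targets({"m1": MIRNA}, {"t1": t1, "t2": t2})
        b = predict_targets({"m1": MIRNA}, {"t2": t2, "t1": t1})
        fa, fb = hits_frame(a), hits_frame(b)
        assert fa.equals(fb)

    def test_hits_round_trip_through_tsv(self, tmp_path):
        rng = random.Random(8)
        flank = lambda n: "".join(rng.choice("ACGU") for _ in range(n))
        tx = flank(100) + perfect_site() + flank(100)
        df = hits_frame(predict_targets({"m1": MIRNA}, {"t1": tx}))
        p = tmp_path / "targets.tsv"
        df.to_csv(p, sep="\t", index=False)
        import pandas as pd

        again = pd.read_csv(p, sep="\t")
        assert again["start"].tolist() == df["start"].tolist()
        assert again["mfe_ratio"].tolist() == pytest.approx(df["mfe_ratio"].tolist())

    def test_planted_sites_from_simulator_recovered(self, small_sim):
        truth = small_sim["truth"]
        tx = {r.id: r.sequence for r in small_sim["transcriptome"]}
        mirnas = {s["mirna_id"]: s["mature"] for s in truth.target_sites}
        relevant = {s["transcript_id"]: tx[s["transcript_id"]]
                    for s in truth.target_sites}
        hits = predict_targets(mirnas, relevant)
        found = {(h.mirna_id, h.transcript_id, h.start) for h in hits}
        for s in truth.target_sites:
            assert (s["mirna_id"], s["transcript_id"], s["start"]) in found
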