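"""Shared fixture builders for the hairpin and target rule matrices."""

import random

from peony_srna.fold import reverse_complement

# substitution that cannot pair with the given base (no WC, no wobble)
NOPAIR = {"A": "C", "C": "A", "G": "A", "U": "C"}

STEM = "GCAUCGGAUCGC"
LOOP, SP2 = "C" * 8, "CC"

WEAK_MATURE = "UAAUAAUAAAAAUUUUUUUAC"  # AU-rich: folds correctly, MFE > -18


def standard_mature():
    random.seed(2)
    return "U" + "".join(random.choice("ACGU") for _ in range(20))


def build_hairpin_5p(mature, star_core=None):
    """Designed 5p-arm precursor; returns (sequence, mature offset)."""
    core = star_core if star_core is not None else reverse_complement(mature[:-2])
    pre = STEM + mature + LOOP + core + SP2 + reverse_complement(STEM)
    return pre, len(STEM)


def hairpin_rule_fixtures():
    """One-factor-at-a-time hairpin fixtures.

    Returns {name: (precursor, mature, mature_offset)} for the base
    (all-pass) case and violations of the arm/pairing criterion, the
    MFE threshold, the loop/bulge size limit and the 3' overhang rule.
    """
    m = standard_mature()
    core = reverse_complement(m[:-2])
    # c2: two 3-nt holes drop mature pairing below 75%
    holey = list(core)
    for start in (6, 13):
        for k in range(start, start + 3):
            holey[k] = NOPAIR[m[len(m) - 3 - k]]
    # c4: 6-nt bulge inside the mature:star duplex
    bulged = core[:9] + "".join(NOPAIR[x] for x in "AAAGGG") + core[9:]
    fixtures = {
        "base": build_hairpin_5p(m) + (m,),
        "c2_low_pairing": build_hairpin_5p(m, "".join(holey)) + (m,),
        "c4_large_bulge": build_hairpin_5p(m, bulged) + (m,),
        "c5_blunt_duplex": build_hairpin_5p(m, reverse_complement(m)) + (m,),
    }
    weak = WEAK_MATURE + LOOP + reverse_complement(WEAK_MATURE[:-2]) + SP2
    fixtures["c3_weak_mfe"] = (weak, 0, WEAK_MATURE)
    return {name: (pre, ms, mat) for name, (pre, ms, mat) in fixtures.items()}


def target_site_with(mirna, changes):
    """Site whose duplex shows the given states at 1-based positions.

    changes: {position: "MM" | "GU"}; all other positions Watson-Crick.
    """
    site = list(reverse_complement(mirna))
    L = len(mirna)
    for pos, state in changes.items():
        i = pos - 1
        j = L - 1 - i
        b = mirna[i]
        if state == "GU":
            assert b in "GU", "wobble requires G or U on the miRNA"
            site[j] = "U" if b == "G" else "G"
        else:
            site[j] = {"A": "C", "C": "A", "G": "A", "U": "C"}[b]
    return "".join(site)
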