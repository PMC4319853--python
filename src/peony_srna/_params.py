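"""Embedded nearest-neighbor energy parameters for the folding engine.

A deliberately small, self-contained Turner-style parameter set
("engine units", approximately kcal/mol at 37 degrees C):

* stacking energies for every combination of the six canonical pairs
  (AU, UA, GC, CG, GU, UG), derived from per-pair strengths so that the
  table is exactly symmetric under helix reversal;
* hairpin-loop, bulge and internal-loop penalties by size, with
  logarithmic (Jacobson-Stockmayer) extrapolation beyond the tabulated
  sizes;
* an affine multibranch-loop model and a bimolecular duplex
  initiation term.

No dangling ends, no coaxial stacking, no pseudoknots; lonely pairs
are allowed.  The table is versioned so that folded output can always
be attributed to the parameter set that produced it.
"""

from __future__ import annotations

import math

import numpy as np

PARAM_VERSION = "PEONY-NN-1"

# base encoding used throughout the engine
BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# per-pair helix strength (kcal/mol contributed to each adjacent stack)
_PAIR_STRENGTH = {
    ("G", "C"): 3.3,
    ("C", "G"): 3.3,
    ("A", "U"): 1.1,
    ("U", "A"): 1.1,
    ("G", "U"): 0.6,
    ("U", "G"): 0.6,
}

#: PAIR_OK[a, b] — True when (a, b) can form a canonical or wobble pair
PAIR_OK = np.zeros((4, 4), dtype=np.bool_)
#: PAIR_W[a, b] — strength of the (a, b) pair, 0 where unpairable
PAIR_W = np.zeros((4, 4), dtype=np.float64)
for (x, y), w in _PAIR_STRENGTH.items():
    PAIR_OK[BASE_INDEX[x], BASE_INDEX[y]] = True
    PAIR_W[BASE_INDEX[x], BASE_INDEX[y]] = w

MIN_HAIRPIN_LOOP = 3  # unpaired nt enclosed by a hairpin-closing pair
MAX_INTERIOR_LOOP = 30  # n1 + n2 cap for interior/bulge loops in the DP

# multibranch affine model: a + b * branches (closing pair included)
MULTI_CLOSE = 3.4
MULTI_BRANCH = 0.4
MULTI_UNPAIRED = 0.0

DUPLEX_INIT = 4.1  # bimolecular initiation for two-strand hybridization

_HAIRPIN_TAB = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_TAB = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_TAB = {2: 1.7, 3: 1.8, 4: 2.0, 5: 2.2, 6: 2.5}
_LOG_EXTRAP = 1.08  # 1.75 * R * T at 310 K


def _extrapolate(table: dict[int, float], n: int) -> float:
    nmax = max(table)
    if n <= nmax:
        return table[n]
    return table[nmax] + _LOG_EXTRAP * math.log(n / nmax)


def hairpin_penalty(n: int) -> float:
    """Destabilizing energy of a hairpin loop of n unpaired nt (n >= 3)."""
    if n < MIN_HAIRPIN_LOOP:
        raise ValueError(f"hairpin loop of {n} nt is below the {MIN_HAIRPIN_LOOP} nt minimum")
    return _extrapolate(_HAIRPIN_TAB, n)


def bulge_penalty(n: int) -> float:
    if n < 1:
        raise ValueError("bulge size must be >= 1")
    return _extrapolate(_BULGE_TAB, n)


def internal_penalty(n: int) -> float:
    """Internal-loop penalty; n is the total unpaired count on both sides."""
    if n < 2:
        raise ValueError("internal loop size must be >= 2")
    return _extrapolate(_INTERNAL_TAB, n)


def stack_energy(pair1: tuple[int, int], pair2: tuple[int, int]) -> float:
    """Stacking energy of pair2 stacked directly on pair1 (encoded bases)."""
    w1 = PAIR_W[pair1[0], pair1[1]]
    w2 = PAIR_W[pair2[0], pair2[1]]
    if w1 == 0.0 or w2 == 0.0:
        raise ValueError("stack_energy called with a non-pairable base combination")
    return -(w1 + w2) / 2.0


def loop_energy(n1: int, n2: int, pair_out: tuple[int, int], pair_in: tuple[int, int]) -> float:
    """Energy of the loop between an outer and inner pair with n1/n2
    unpaired nt on the 5'/3' sides (0/0 = stack, k/0 = bulge, else internal)."""
    if n1 == 0 and n2 == 0:
        return stack_energy(pair_out, pair_in)
    if n1 == 0 or n2 == 0:
        return bulge_penalty(n1 + n2)
    return internal_penalty(n1 + n2)


def _size_table(fn, nmax: int, nmin: int) -> np.ndarray:
    out = np.full(nmax + 1, np.inf)
    for n in range(nmin, nmax + 1):
        out[n] = fn(n)
    return out


def loop_tables(nmax: int = 512) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precomputed (hairpin, bulge, internal) penalty arrays up to nmax."""
    return (
        _size_table(hairpin_penalty, nmax, MIN_HAIRPIN_LOOP),
        _size_table(bulge_penalty, nmax, 1),
        _size_table(internal_penalty, nmax, 2),
    )


def dump_params() -> str:
    """Human-readable dump of the full embedded table (CLI --dump-params)."""
    lines = [f"# embedded nearest-neighbor parameters, version {PARAM_VERSION}",
             "# engine units ~ kcal/mol"]
    lines.append("[stacks]")
    pairs = sorted(_PAIR_STRENGTH)
    for p1 in pairs:
        for p2 in pairs:
            e = -(_PAIR_STRENGTH[p1] + _PAIR_STRENGTH[p2]) / 2.0
            lines.append(f"{p1[0]}{p1[1]}/{p2[0]}{p2[1]}\t{e:.2f}")
    for name, tab in (("hairpin", _HAIRPIN_TAB), ("bulge", _BULGE_TAB),
                      ("internal", _INTERNAL_TAB)):
        lines.append(f"[{name}]")
        for n in sorted(tab):
            lines.append(f"{n}\t{tab[n]:.2f}")
        lines.append(f">max\t+{_LOG_EXTRAP:.2f}*ln(n/nmax)")
    lines.append("[multiloop]")
    lines.append(f"close\t{MULTI_CLOSE:.2f}")
    lines.append(f"branch\t{MULTI_BRANCH:.2f}")
    lines.append(f"unpaired\t{MULTI_UNPAIRED:.2f}")
    lines.append("[duplex]")
    lines.append(f"init\t{DUPLEX_INIT:.2f}")
    return "\n".join(lines)
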