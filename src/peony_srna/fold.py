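"""RNA secondary-structure folding and duplex hybridization energies.

The embedded engine is a Zuker-style minimum-free-energy dynamic
program over the nearest-neighbor model defined in :mod:`._params`:
stacking energies for all canonical + wobble pair combinations,
size-dependent hairpin/bulge/internal-loop penalties, and an affine
multibranch model.  No pseudoknots, no dangling ends, no coaxial
stacking; lonely pairs are allowed.  The matrix fill is JIT-compiled
with numba; the traceback reads the filled matrices in Python.

Two independent routes through the same parameter table exist:

* :func:`fold_hairpin` — the O(n^3) dynamic program (production path);
* :func:`enumerate_structures` + :func:`energy_of_structure` — explicit
  enumeration of every valid structure with loop-decomposition scoring,
  feasible up to ~18 nt and used as the brute-force oracle in tests.

Duplex energies (:func:`duplex_energy`, :func:`perfect_complement_energy`)
score an ungapped two-strand hybrid as duplex initiation plus stacking
over runs of consecutively paired positions.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from numba import njit

from ._params import (
    BASE_INDEX,
    DUPLEX_INIT,
    MAX_INTERIOR_LOOP,
    MIN_HAIRPIN_LOOP,
    MULTI_BRANCH,
    MULTI_CLOSE,
    MULTI_UNPAIRED,
    PAIR_OK,
    PAIR_W,
    hairpin_penalty,
    loop_energy,
    loop_tables,
)

__all__ = [
    "FoldResult",
    "DuplexEnergy",
    "fold_hairpin",
    "energy_of_structure",
    "enumerate_structures",
    "duplex_energy",
    "perfect_complement_energy",
    "reverse_complement",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

_EPS = 1e-6


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([BASE_INDEX[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-RNA character {exc.args[0]!r} in sequence") from None


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    """Reverse complement in RNA alphabet (input normalized first)."""
    s = normalize_rna(seq)
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(s))
    except KeyError as exc:
        raise ValueError(f"non-RNA character {exc.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class FoldResult:
    """Minimum-energy secondary structure of a single strand."""

    sequence: str
    structure: str  # dot-bracket
    energy: float  # engine units ~ kcal/mol, <= 0
    pair_table: tuple[int, ...] = field(repr=False)  # partner index or -1

    @property
    def paired_fraction(self) -> float:
        if not self.pair_table:
            return 0.0
        return sum(p >= 0 for p in self.pair_table) / len(self.pair_table)

    def partner(self, i: int) -> int:
        return self.pair_table[i]


@dataclass(frozen=True)
class DuplexEnergy:
    """Hybridization energy of an ungapped two-strand duplex."""

    energy: float
    paired_mask: tuple[bool, ...]


# ---------------------------------------------------------------------------
# matrix fill (numba)
# ---------------------------------------------------------------------------

_INF = 1e9


@njit(cache=True)
def _fill(seq, pair_w, hairpinE, bulgeE, internalE,
          max_interior, multi_close, multi_branch):  # pragma: no cover - jit
    n = seq.shape[0]
    V = np.full((n, n), _INF)
    M = np.full((n, n), _INF)
    M2 = np.full((n, n), _INF)
    W = np.zeros(n)
    for span in range(5, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            wij = pair_w[seq[i], seq[j]]
            if wij > 0.0:
                best = hairpinE[j - i - 1]
                # stack / bulge / internal loop closing an inner pair
                i2max = min(i + max_interior + 2, j - 4)
                for i2 in range(i + 1, i2max + 1):
                    n1 = i2 - i - 1
                    j2min = i2 + 4
                    if j - 1 - (max_interior - n1) > j2min:
                        j2min = j - 1 - (max_interior - n1)
                    for j2 in range(j2min, j):
                        v_in = V[i2, j2]
                        if v_in >= _INF:
                            continue
                        n2 = j - j2 - 1
                        if n1 == 0 and n2 == 0:
                            e = -(wij + pair_w[seq[i2], seq[j2]]) / 2.0
                        elif n1 == 0 or n2 == 0:
                            e = bulgeE[n1 + n2]
                        else:
                            e = internalE[n1 + n2]
                        if e + v_in < best:
                            best = e + v_in
                # multibranch loop
                if j - i >= 6:
                    m2 = M2[i + 1, j - 1]
                    if m2 < _INF:
                        cand = multi_close + multi_branch + m2
                        if cand < best:
                            best = cand
                V[i, j] = best
            # M: >=1 branch inside i..j;  M2: >=2 branches
            m = M[i + 1, j] if i + 1 <= j else _INF
            if M[i, j - 1] < m:
                m = M[i, j - 1]
            if V[i, j] + multi_branch < m:
                m = V[i, j] + multi_branch
            m2 = M2[i, j - 1]
            for k in range(i + 1, j):
                mk = M[i, k - 1]
                vk = V[k, j]
                if mk < _INF and vk < _INF and mk + vk + multi_branch < m2:
                    m2 = mk + vk + multi_branch
            if m2 < m:
                m = m2
            M[i, j] = m
            M2[i, j] = m2
    for j in range(n):
        w = W[j - 1] if j > 0 else 0.0
        for i in range(0, j):
            wprev = W[i - 1] if i > 0 else 0.0
            if V[i, j] < _INF and wprev + V[i, j] < w:
                w = wprev + V[i, j]
        if j >= 4 and V[0, j] < w:
            w = V[0, j]
        W[j] = w
    return V, M, M2, W


# ---------------------------------------------------------------------------
# traceback
# ---------------------------------------------------------------------------

def _traceback(seq, V, M, M2, W, hairpinE, bulgeE, internalE):
    n = len(seq)
    pairs: list[tuple[int, int]] = []

    def close(a: float, b: float) -> bool:
        return abs(a - b) < _EPS

    def trace_V(i: int, j: int) -> None:
        pairs.append((i, j))
        v = V[i, j]
        if close(v, hairpinE[j - i - 1]):
            return
        wij = PAIR_W[seq[i], seq[j]]
        i2max = min(i + MAX_INTERIOR_LOOP + 2, j - 4)
        for i2 in range(i + 1, i2max + 1):
            n1 = i2 - i - 1
            for j2 in range(max(i2 + 4, j - 1 - (MAX_INTERIOR_LOOP - n1)), j):
                if V[i2, j2] >= _INF:
                    continue
                n2 = j - j2 - 1
                if n1 == 0 and n2 == 0:
                    e = -(wij + PAIR_W[seq[i2], seq[j2]]) / 2.0
                elif n1 == 0 or n2 == 0:
                    e = bulgeE[n1 + n2]
                else:
                    e = internalE[n1 + n2]
                if close(v, e + V[i2, j2]):
                    trace_V(i2, j2)
                    return
        trace_M2(i + 1, j - 1)

    def trace_M2(i: int, j: int) -> None:
        while M2[i, j - 1] < _INF and close(M2[i, j], M2[i, j - 1]):
            j -= 1
        for k in range(i + 1, j):
            if M[i, k - 1] < _INF and V[k, j] < _INF and close(
                    M2[i, j], M[i, k - 1] + V[k, j] + MULTI_BRANCH):
                trace_V(k, j)
                trace_M(i, k - 1)
                return
        raise AssertionError("traceback failed in multibranch decomposition")

    def trace_M(i: int, j: int) -> None:
        while True:
            if i + 1 <= j and close(M[i, j], M[i + 1, j]):
                i += 1
                continue
            if close(M[i, j], M[i, j - 1]):
                j -= 1
                continue
            if V[i, j] < _INF and close(M[i, j], V[i, j] + MULTI_BRANCH):
                trace_V(i, j)
                return
            if close(M[i, j], M2[i, j]):
                trace_M2(i, j)
                return
            raise AssertionError("traceback failed in multibranch segment")

    j = n - 1
    while j > 0:
        prev = W[j - 1] if j > 0 else 0.0
        if close(W[j], prev):
            j -= 1
            continue
        found = False
        for i in range(0, j + 1):
            wprev = W[i - 1] if i > 0 else 0.0
            if V[i, j] < _INF and close(W[j], wprev + V[i, j]):
                trace_V(i, j)
                j = i - 1
                found = True
                break
        if not found:
            raise AssertionError("traceback failed in exterior loop")
    return pairs


_TABLES: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None


def _tables(nmax: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    global _TABLES
    if _TABLES is None or len(_TABLES[0]) <= nmax:
        _TABLES = loop_tables(max(nmax, 512))
    return _TABLES


def _fold_embedded(seq: str) -> FoldResult:
    codes = _encode(seq)
    n = len(codes)
    hp, bl, it = _tables(n + 2)
    V, M, M2, W = _fill(codes, PAIR_W, hp, bl, it,
                        MAX_INTERIOR_LOOP, MULTI_CLOSE, MULTI_BRANCH)
    energy = float(W[n - 1]) if n else 0.0
    if energy >= 0.0:
        return FoldResult(seq, "." * n, 0.0, tuple([-1] * n))
    pairs = _traceback(codes, V, M, M2, W, hp, bl, it)
    table = [-1] * n
    struct = ["."] * n
    for i, j in pairs:
        table[i], table[j] = j, i
        struct[i], struct[j] = "(", ")"
    return FoldResult(seq, "".join(struct), energy, tuple(table))


def _fold_rnafold(seq: str) -> FoldResult:
    """External backend: shell out to ViennaRNA's RNAfold if installed."""
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold not found on PATH; external backend unavailable")
    out = subprocess.run([exe, "--noPS", "-d0"], input=seq + "\n",
                         capture_output=True, text=True, check=True).stdout
    line = out.strip().splitlines()[-1]
    struct, _, rest = line.partition(" ")
    energy = float(rest.strip().lstrip("(").rstrip(")"))
    return FoldResult(seq, struct, min(energy, 0.0), tuple(_pairs_from_db(struct)))


def _pairs_from_db(structure: str) -> list[int]:
    stack: list[int] = []
    table = [-1] * len(structure)
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            table[i], table[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return table


_BACKENDS = {"embedded": _fold_embedded, "external": _fold_rnafold}


def fold_hairpin(seq: str, backend: str = "embedded") -> FoldResult:
    """Minimum-free-energy structure of a single RNA strand.

    Parameters
    ----------
    seq
        RNA sequence, >= 10 nt; DNA T and lowercase are normalized.
    backend
        ``embedded`` (default) uses the built-in nearest-neighbor DP;
        ``external`` delegates to RNAfold under the same output contract
        (balanced dot-bracket, energy <= 0, full pair table).
    """
    s = normalize_rna(seq)
    if len(s) < 10:
        raise ValueError(f"sequence of {len(s)} nt is too short to fold (minimum 10)")
    if backend not in _BACKENDS:
        raise ValueError(f"unknown fold backend {backend!r}")
    return _BACKENDS[backend](s)


# ---------------------------------------------------------------------------
# loop-decomposition scoring + exhaustive enumeration (oracle route)
# ---------------------------------------------------------------------------

def energy_of_structure(seq: str, structure: str | Sequence[tuple[int, int]]) -> float:
    """Score an explicit secondary structure by loop decomposition.

    Accepts dot-bracket text or a list of (i, j) pairs.  Raises on
    non-canonical pairs or hairpin loops below the 3-nt minimum.  This
    scorer is independent of the dynamic program and shares only the
    parameter table with it.
    """
    s = normalize_rna(seq)
    codes = _encode(s)
    n = len(codes)
    if isinstance(structure, str):
        if len(structure) != n:
            raise ValueError("structure length does not match sequence length")
        table = _pairs_from_db(structure)
    else:
        table = [-1] * n
        for i, j in structure:
            table[i], table[j] = j, i
    for i, j in enumerate(table):
        if j > i:
            if not PAIR_OK[codes[i], codes[j]]:
                raise ValueError(f"non-canonical pair at ({i}, {j})")
            if j - i - 1 < MIN_HAIRPIN_LOOP:
                raise ValueError(f"hairpin loop below {MIN_HAIRPIN_LOOP} nt at ({i}, {j})")

    def children_of(i: int, j: int) -> tuple[list[tuple[int, int]], int]:
        kids, unpaired, pos = [], 0, i + 1
        while pos < j:
            p = table[pos]
            if p > pos:
                kids.append((pos, p))
                pos = p + 1
            else:
                unpaired += 1
                pos += 1
        return kids, unpaired

    total = 0.0
    stack: list[tuple[int, int]] = []
    pos = 0
    while pos < n:  # exterior level contributes 0
        p = table[pos]
        if p > pos:
            stack.append((pos, p))
            pos = p + 1
        else:
            pos += 1
    while stack:
        i, j = stack.pop()
        kids, unpaired = children_of(i, j)
        if not kids:
            total += hairpin_penalty(j - i - 1)
        elif len(kids) == 1:
            (k, l) = kids[0]
            total += loop_energy(k - i - 1, j - l - 1,
                                 (codes[i], codes[j]), (codes[k], codes[l]))
        else:
            total += (MULTI_CLOSE + MULTI_BRANCH * (len(kids) + 1)
                      + MULTI_UNPAIRED * unpaired)
        stack.extend(kids)
    return total


def enumerate_structures(seq: str) -> Iterator[list[tuple[int, int]]]:
    """Yield every valid secondary structure (as pair lists) of seq.

    Nested structures only, canonical/wobble pairs, hairpin loops >= 3 nt.
    Exponential — intended for sequences up to ~18 nt as a brute-force
    oracle against the dynamic program.
    """
    codes = _encode(normalize_rna(seq))
    n = len(codes)

    def gen(i: int, j: int) -> Iterator[list[tuple[int, int]]]:
        # structures of the closed-open interval [i, j)
        if j - i < 2:
            yield []
            return
        # position i unpaired
        yield from gen(i + 1, j)
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j):
            if PAIR_OK[codes[i], codes[k]]:
                for inner in gen(i + 1, k):
                    for outer in gen(k + 1, j):
                        yield [(i, k)] + inner + outer

    yield from gen(0, n)


# ---------------------------------------------------------------------------
# duplex energies
# ---------------------------------------------------------------------------

def duplex_energy(strand_a: str, strand_b: str,
                  paired: Sequence[bool] | None = None) -> DuplexEnergy:
    """Hybridization energy of an ungapped duplex.

    ``strand_a`` and ``strand_b`` are both written 5'->3'; position i of
    strand_a faces position L-1-i of strand_b.  ``paired`` marks which
    positions (indexed on strand_a) are engaged; by default every
    position whose facing bases can pair is engaged.  The energy is the
    duplex initiation constant plus stacking terms over runs of
    consecutive paired positions; unpaired positions break stacks.  An
    empty (zero-length) duplex has energy 0.
    """
    a = _encode(normalize_rna(strand_a))
    b = _encode(normalize_rna(strand_b))
    if len(a) != len(b):
        raise ValueError("duplex strands must have equal length")
    n = len(a)
    if n == 0:
        return DuplexEnergy(0.0, ())
    facing = b[::-1]
    if paired is None:
        mask = [bool(PAIR_OK[a[i], facing[i]]) for i in range(n)]
    else:
        if len(paired) != n:
            raise ValueError("paired mask length must match strand length")
        mask = list(bool(m) for m in paired)
        for i, m in enumerate(mask):
            if m and not PAIR_OK[a[i], facing[i]]:
                raise ValueError(f"mask marks non-pairable bases at position {i}")
    energy = DUPLEX_INIT
    for i in range(n - 1):
        if mask[i] and mask[i + 1]:
            energy += -(PAIR_W[a[i], facing[i]] + PAIR_W[a[i + 1], facing[i + 1]]) / 2.0
    return DuplexEnergy(energy, tuple(mask))


def perfect_complement_energy(mirna: str) -> float:
    """Duplex energy of a miRNA bound to its exact reverse complement."""
    s = normalize_rna(mirna)
    return duplex_energy(s, reverse_complement(s)).energy
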