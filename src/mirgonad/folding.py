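"""Minimum-free-energy folding of short RNAs into stem-loop structures.

The model is a self-contained nearest-neighbor model over canonical
Watson-Crick pairs plus G:U wobble:

* stacked pair free energies from a 6 x 6 table (kcal/mol at 37 C),
* hairpin-loop, bulge and internal-loop penalties as a function of loop
  size (with a mild asymmetry term for internal loops),
* interior loops capped at ``MAXLOOP`` (30) unpaired nucleotides, the
  standard convention for secondary-structure DP,
* hairpin loops of at least ``MIN_HAIRPIN`` (3) nucleotides,
* no multiloops: a structure is a set of independent stem-loops hanging
  off the exterior loop, which is exactly the structure class miRNA
  precursor candidates live in.

Because the model is finite and explicit, the dynamic program can be
validated against exhaustive enumeration of every admissible structure
for short sequences; the test suite does so.

The DP fills an O(n^2) matrix with an O(MAXLOOP^2) inner loop.  If
:mod:`numba` is importable the kernel is JIT-compiled; otherwise a pure
Python implementation of the identical recurrence is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

MIN_HAIRPIN = 3
MAXLOOP = 30
INF = 1e9

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

# pair codes: AU=0 UA=1 CG=2 GC=3 GU=4 UG=5, -1 = not pairable
_PAIR_CODE = -np.ones((4, 4), dtype=np.int8)
_PAIR_CODE[0, 3] = 0
_PAIR_CODE[3, 0] = 1
_PAIR_CODE[1, 2] = 2
_PAIR_CODE[2, 1] = 3
_PAIR_CODE[2, 3] = 4
_PAIR_CODE[3, 2] = 5

# stack[p][q]: pair p = (i, j) closing, pair q = (i+1, j-1) stacked inside
STACK = np.array(
    [
        # AU     UA     CG     GC     GU     UG
        [-0.9, -1.1, -2.2, -2.1, -0.6, -1.4],  # AU
        [-1.3, -0.9, -2.4, -2.1, -1.0, -1.3],  # UA
        [-2.1, -2.1, -3.3, -2.4, -1.4, -2.1],  # CG
        [-2.4, -2.2, -3.4, -3.3, -1.5, -2.5],  # GC
        [-1.3, -1.4, -2.5, -2.1, -0.5, -1.3],  # GU
        [-1.0, -0.8, -1.5, -1.4, -0.3, -0.5],  # UG
    ],
    dtype=np.float64,
)

_HAIRPIN_TAB = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_TAB = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_TAB = {2: 1.5, 3: 1.8, 4: 2.5, 5: 3.0, 6: 3.5}
_LOOP_EXTRAPOLATION = 1.07  # ~1.75 * R * T at 37 C, kcal/mol


def hairpin_energy(loop_size: int) -> float:
    """Free-energy penalty of a hairpin loop of ``loop_size`` unpaired nt."""
    if loop_size < MIN_HAIRPIN:
        return INF
    if loop_size in _HAIRPIN_TAB:
        return _HAIRPIN_TAB[loop_size]
    return 6.4 + _LOOP_EXTRAPOLATION * math.log(loop_size / 9.0)


def internal_loop_energy(a: int, b: int) -> float:
    """Penalty of a bulge (one of a, b zero) or internal loop between stems.

    ``a`` and ``b`` are the unpaired counts on the 5' and 3' side.  Loops
    with a + b > MAXLOOP are outside the model.
    """
    t = a + b
    if t < 1 or t > MAXLOOP:
        return INF
    if a == 0 or b == 0:
        if t in _BULGE_TAB:
            return _BULGE_TAB[t]
        return 4.4 + _LOOP_EXTRAPOLATION * math.log(t / 6.0)
    base = _INTERNAL_TAB.get(t, 3.5 + _LOOP_EXTRAPOLATION * math.log(t / 6.0) if t > 6 else 3.5)
    return base + min(0.5 * abs(a - b), 3.0)


def stack_energy(pair_out: int, pair_in: int) -> float:
    """Stacking energy for pair codes (see ``pair_code``)."""
    return float(STACK[pair_out, pair_in])


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as an int8 array (T treated as U)."""
    try:
        return np.array([_BASE_INDEX[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from None


def pair_code(x: int, y: int) -> int:
    return int(_PAIR_CODE[x, y])


def _loop_energy_table() -> np.ndarray:
    tab = np.full((MAXLOOP + 1, MAXLOOP + 1), INF)
    for a in range(MAXLOOP + 1):
        for b in range(MAXLOOP + 1):
            if 1 <= a + b <= MAXLOOP:
                tab[a, b] = internal_loop_energy(a, b)
    return tab


_LOOP_TAB = _loop_energy_table()
_HAIRPIN_ARR_MAX = 1024
_HAIRPIN_ARR = np.array([hairpin_energy(t) if t >= MIN_HAIRPIN else INF
                         for t in range(_HAIRPIN_ARR_MAX)])


def _fill_v_python(pidx, V, stack, hairpin_arr, loop_tab):  # pragma: no cover - numba twin
    n = pidx.shape[0]
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            p = pidx[i, j]
            if p < 0:
                continue
            best = hairpin_arr[span - 1]
            amax = MAXLOOP if MAXLOOP < span else span
            for a in range(amax + 1):
                k = i + 1 + a
                if k + MIN_HAIRPIN + 1 >= j:
                    break
                for b in range(MAXLOOP - a + 1):
                    l = j - 1 - b
                    if l - k <= MIN_HAIRPIN:
                        break
                    v = V[k, l]
                    if v >= INF / 2:
                        continue
                    q = pidx[k, l]
                    if a == 0 and b == 0:
                        e = stack[p, q]
                    else:
                        e = loop_tab[a, b]
                    tot = v + e
                    if tot < best:
                        best = tot
            V[i, j] = best


try:  # optional JIT of the identical kernel
    from numba import njit

    _fill_v_fast = njit(cache=False)(_fill_v_python)
except Exception:  # pragma: no cover
    _fill_v_fast = _fill_v_python


@dataclass
class FoldResult:
    """Minimum-free-energy structure of a sequence.

    ``structure`` is a balanced dot-bracket string of the same length as
    ``sequence``; ``delta_g`` is the model free energy in kcal/mol
    (0.0 and an empty structure for sequences with no stabilizing fold).
    """

    sequence: str
    structure: str
    delta_g: float
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def pair_table(self) -> np.ndarray:
        """Partner index per position, -1 for unpaired."""
        pt = np.full(len(self.sequence), -1, dtype=np.int64)
        for i, j in self.pairs:
            pt[i] = j
            pt[j] = i
        return pt


def pairs_to_dotbracket(pairs, n: int) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i] = "("
        s[j] = ")"
    return "".join(s)


def dotbracket_to_pairs(structure: str) -> list[tuple[int, int]]:
    stack, pairs = [], []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def fold(sequence: str) -> FoldResult:
    """Fold ``sequence`` into its minimum-energy multiloop-free structure.

    Accepts ACGU (T read as U, case-insensitive).  Returns the optimal
    structure under the package energy model; ties are broken towards
    hairpin closure and then the smallest enclosing loop, determinately.
    """
    if not sequence:
        raise ValueError("empty sequence")
    enc = encode(sequence)
    n = len(enc)
    rna = "".join("ACGU"[b] for b in enc)
    pidx = _PAIR_CODE[enc[:, None], enc[None, :]]
    V = np.full((n, n), INF)
    if n > MIN_HAIRPIN + 1:
        _fill_v_fast(pidx, V, STACK, _HAIRPIN_ARR, _LOOP_TAB)

    # exterior loop: W[j] = best energy of prefix [0, j)
    W = np.zeros(n + 1)
    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(j):
            if V[i, j - 1] < INF / 2:
                cand = W[i] + V[i, j - 1]
                if cand < best:
                    best = cand
        W[j] = best

    dg = float(W[n])
    if dg > -1e-9:
        return FoldResult(rna, "." * n, 0.0, [])

    pairs: list[tuple[int, int]] = []
    _traceback_w(n, V, W, pidx, pairs)
    pairs.sort()
    return FoldResult(rna, pairs_to_dotbracket(pairs, n), round(dg, 6), pairs)


_EPS = 1e-6


def _traceback_w(n, V, W, pidx, pairs):
    j = n
    while j > 0:
        if abs(W[j] - W[j - 1]) < _EPS:  # j-1 unpaired is optimal; take it
            j -= 1
            continue
        found = False
        for i in range(j):
            if V[i, j - 1] < INF / 2 and abs(W[i] + V[i, j - 1] - W[j]) < _EPS:
                _traceback_v(i, j - 1, V, pidx, pairs)
                j = i
                found = True
                break
        if not found:  # numerical guard: treat as unpaired
            j -= 1


def _traceback_v(i, j, V, pidx, pairs):
    while True:
        pairs.append((i, j))
        p = pidx[i, j]
        target = V[i, j]
        if abs(_HAIRPIN_ARR[j - i - 1] - target) < _EPS:
            return
        nxt = None
        for a in range(min(MAXLOOP, j - i) + 1):
            k = i + 1 + a
            if k + MIN_HAIRPIN + 1 >= j:
                break
            for b in range(MAXLOOP - a + 1):
                l = j - 1 - b
                if l - k <= MIN_HAIRPIN:
                    break
                if V[k, l] >= INF / 2:
                    continue
                q = pidx[k, l]
                e = STACK[p, q] if (a == 0 and b == 0) else _LOOP_TAB[a, b]
                if abs(V[k, l] + e - target) < _EPS:
                    nxt = (k, l)
                    break
            if nxt:
                break
        if nxt is None:  # hairpin fallback (should not happen)
            return
        i, j = nxt
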