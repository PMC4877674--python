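"""Minimum-free-energy RNA secondary structure prediction.

A self-contained, simplified nearest-neighbour energy model with a
Zuker-style dynamic program. The model is deliberately small and exactly
specified so that the dynamic program can be verified bit-for-bit against
exhaustive enumeration of all nested structures on short sequences:

* all energies are integers in tenths of kcal/mol (no floating point in the
  optimisation, hence exact oracle comparisons);
* stabilising energy comes from stacked base pairs only: a stack of two
  pairs contributes minus the mean of tabulated pair strengths
  (G:C = 3.2, A:U = 2.2, G:U = 1.2 kcal/mol for a same-type stack);
* hairpin, bulge and internal loops pay logarithmic length penalties;
  two-sided loops (bulge + internal) are capped at ``MAXLOOP`` = 10 unpaired
  nucleotides in total — larger interruptions are disallowed by the model;
* multiloops pay an affine penalty (closing + per-branch + per-unpaired);
* minimum hairpin loop of 3 nt; no pseudoknots; G:U wobbles are valid pairs.

Bit-compatibility with any published folding engine is explicitly not a
goal: downstream hairpin criteria act on criterion bounds, not exact MFE
values. An external folder (e.g. ViennaRNA) can be plugged in through
:func:`from_dotbracket` or the ``engine`` argument of :func:`fold`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from .io import to_rna

INF = 10**9

HAIRPIN_MIN = 3  # minimum unpaired nt in a hairpin loop
MAXLOOP = 10  # maximum total unpaired nt in a bulge/internal loop

# pair strengths in tenths of kcal/mol; a stack of pairs p, q scores -(S[p]+S[q])/2*...
_PAIR_STRENGTH = {
    ("G", "C"): 16, ("C", "G"): 16,
    ("A", "U"): 11, ("U", "A"): 11,
    ("G", "U"): 6, ("U", "G"): 6,
}

# multiloop affine penalty (tenths of kcal/mol)
ML_CLOSE = 34
ML_BRANCH = 4
ML_UNPAIRED = 1

_MAXLEN_TABLE = 512


@lru_cache(maxsize=None)
def _hairpin_penalty(length: int) -> int:
    return 45 + int(round(17.5 * math.log(length / 3.0)))


@lru_cache(maxsize=None)
def _bulge_penalty(length: int) -> int:
    return 38 + int(round(17.5 * math.log(length)))


@lru_cache(maxsize=None)
def _internal_penalty(length: int) -> int:
    return 17 + int(round(17.5 * math.log(length / 2.0)))


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIR_STRENGTH


def _stack_energy(outer: tuple[str, str], inner: tuple[str, str]) -> int:
    return -(_PAIR_STRENGTH[outer] + _PAIR_STRENGTH[inner])


def _two_sided_loop_energy(l1: int, l2: int, outer: tuple[str, str], inner: tuple[str, str]) -> int | None:
    """Energy of the loop between two pairs with l1/l2 unpaired nt per side."""
    if l1 == 0 and l2 == 0:
        return _stack_energy(outer, inner)
    if l1 + l2 > MAXLOOP:
        return None
    if l1 == 0 or l2 == 0:
        return _bulge_penalty(l1 + l2)
    return _internal_penalty(l1 + l2)


@dataclass
class FoldResult:
    """A predicted secondary structure for one sequence.

    ``mfe`` is in kcal/mol (≤ 0); ``ptable[i]`` is the 0-based partner of
    position *i* or −1 when unpaired.
    """

    sequence: str  # RNA alphabet
    structure: str  # dot-bracket
    mfe: float
    ptable: list[int] = field(repr=False)

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.ptable) if j > i)

    def pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in enumerate(self.ptable) if j > i]


def parse_dotbracket(structure: str) -> list[int]:
    """Dot-bracket string to partner table; raises on unbalanced brackets."""
    ptable = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            ptable[j], ptable[i] = i, j
        elif c != ".":
            raise ValueError(f"unexpected character {c!r} in dot-bracket")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return ptable


def _dotbracket(ptable: list[int]) -> str:
    out = []
    for i, j in enumerate(ptable):
        out.append("." if j < 0 else ("(" if j > i else ")"))
    return "".join(out)


def _check_alphabet(rna: str) -> None:
    bad = set(rna) - set("ACGU")
    if bad:
        raise ValueError(f"sequence contains non-ACGU(T) characters: {sorted(bad)}")


def structure_energy_int(seq_rna: str, ptable: list[int]) -> int | None:
    """Score a structure under the model, in tenths of kcal/mol.

    Returns ``None`` when the structure is invalid under the model (a
    non-complementary pair, a hairpin loop < 3 nt, or a two-sided loop
    exceeding ``MAXLOOP``). This is the standalone scorer used both for
    re-scoring predicted structures and by the enumeration oracle.
    """
    n = len(seq_rna)
    pairs = [(i, j) for i, j in enumerate(ptable) if j > i]
    for i, j in pairs:
        if not can_pair(seq_rna[i], seq_rna[j]):
            return None
        if j - i - 1 < HAIRPIN_MIN:
            return None
    total = 0
    for i, j in pairs:
        # direct children of the loop closed by (i, j)
        children = []
        k = i + 1
        while k < j:
            if ptable[k] > k:
                children.append((k, ptable[k]))
                k = ptable[k] + 1
            else:
                k += 1
        if not children:
            total += _hairpin_penalty(j - i - 1)
        elif len(children) == 1:
            k, l = children[0]
            e = _two_sided_loop_energy(k - i - 1, j - l - 1,
                                       (seq_rna[i], seq_rna[j]),
                                       (seq_rna[k], seq_rna[l]))
            if e is None:
                return None
            total += e
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            total += ML_CLOSE + ML_BRANCH * (len(children) + 1) + ML_UNPAIRED * unpaired
    return total


def structure_energy(sequence: str, structure: str) -> float | None:
    """Energy (kcal/mol) of a dot-bracket structure under the model."""
    rna = to_rna(sequence)
    _check_alphabet(rna)
    e = structure_energy_int(rna, parse_dotbracket(structure))
    return None if e is None else e / 10.0


def fold(sequence: str, engine=None) -> FoldResult:
    """Predict the MFE structure of ``sequence`` (DNA or RNA alphabet).

    ``engine``, when given, is a callable ``rna -> (dot_bracket, mfe_kcal)``
    delegating to an external folder; the result is wrapped unchanged.
    """
    rna = to_rna(sequence)
    _check_alphabet(rna)
    if engine is not None:
        structure, mfe = engine(rna)
        return FoldResult(rna, structure, float(mfe), parse_dotbracket(structure))

    n = len(rna)
    if n == 0:
        return FoldResult(rna, "", 0.0, [])
    canp = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + HAIRPIN_MIN + 1, n):
            canp[i][j] = can_pair(rna[i], rna[j])

    V = [[INF] * n for _ in range(n)]
    M = [[INF] * n for _ in range(n)]

    for span in range(HAIRPIN_MIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            if canp[i][j]:
                best = _hairpin_penalty(j - i - 1)
                outer = (rna[i], rna[j])
                # interior pair (k, l): stack, bulge or internal loop
                for k in range(i + 1, min(i + MAXLOOP + 2, j)):
                    l1 = k - i - 1
                    Vk = V[k]
                    for l in range(j - 1, max(k + HAIRPIN_MIN, j - (MAXLOOP - l1) - 2), -1):
                        if Vk[l] >= INF:
                            continue
                        e = _two_sided_loop_energy(l1, j - l - 1, outer, (rna[k], rna[l]))
                        if e is None:
                            continue
                        cand = Vk[l] + e
                        if cand < best:
                            best = cand
                # multiloop: interior [i+1, j-1] split into two ≥1-branch parts
                base = ML_CLOSE + ML_BRANCH
                Mi = M[i + 1]
                for k in range(i + 2, j - 1):
                    if Mi[k - 1] < INF and M[k][j - 1] < INF:
                        cand = base + Mi[k - 1] + M[k][j - 1]
                        if cand < best:
                            best = cand
                V[i][j] = best
            # multiloop segment with ≥1 branch on [i, j]
            best = V[i][j] + ML_BRANCH if V[i][j] < INF else INF
            if M[i + 1][j] < INF:
                best = min(best, M[i + 1][j] + ML_UNPAIRED)
            if M[i][j - 1] < INF:
                best = min(best, M[i][j - 1] + ML_UNPAIRED)
            Mi = M[i]
            for k in range(i + 1, j + 1):
                if Mi[k - 1] < INF and M[k][j] < INF:
                    cand = Mi[k - 1] + M[k][j]
                    if cand < best:
                        best = cand
            M[i][j] = best

    # external loop
    w = [0] * (n + 1)
    for j in range(n):
        best = w[j]
        for k in range(0, j - HAIRPIN_MIN):
            if V[k][j] < INF:
                cand = w[k] + V[k][j]
                if cand < best:
                    best = cand
        w[j + 1] = best

    ptable = [-1] * n
    _traceback(rna, V, M, w, ptable)
    return FoldResult(rna, _dotbracket(ptable), w[n] / 10.0, ptable)


def _traceback(rna: str, V, M, w, ptable) -> None:
    n = len(rna)
    # external level: scan 3'->5', preferring the 5'-most paired partner
    stack: list[tuple[int, int, str]] = []
    j = n - 1
    while j >= 0:
        if w[j + 1] == w[j]:
            j -= 1
            continue
        for k in range(0, j - HAIRPIN_MIN):
            if V[k][j] < INF and w[k] + V[k][j] == w[j + 1]:
                stack.append((k, j, "V"))
                j = k - 1
                break
        else:  # pragma: no cover - DP/traceback mismatch would be a bug
            raise AssertionError("traceback failed in external loop")

    while stack:
        i, j, which = stack.pop()
        if which == "V":
            ptable[i], ptable[j] = j, i
            target = V[i][j]
            outer = (rna[i], rna[j])
            found = False
            for k in range(i + 1, min(i + MAXLOOP + 2, j)):
                l1 = k - i - 1
                for l in range(j - 1, max(k + HAIRPIN_MIN, j - (MAXLOOP - l1) - 2), -1):
                    if V[k][l] >= INF:
                        continue
                    e = _two_sided_loop_energy(l1, j - l - 1, outer, (rna[k], rna[l]))
                    if e is not None and V[k][l] + e == target:
                        stack.append((k, l, "V"))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            base = ML_CLOSE + ML_BRANCH
            for k in range(i + 2, j - 1):
                if M[i + 1][k - 1] < INF and M[k][j - 1] < INF and \
                        base + M[i + 1][k - 1] + M[k][j - 1] == target:
                    stack.append((i + 1, k - 1, "M"))
                    stack.append((k, j - 1, "M"))
                    found = True
                    break
            if not found and target != _hairpin_penalty(j - i - 1):  # pragma: no cover
                raise AssertionError("traceback failed in V")
        else:  # M
            target = M[i][j]
            if V[i][j] < INF and V[i][j] + ML_BRANCH == target:
                stack.append((i, j, "V"))
                continue
            found = False
            for k in range(i + 1, j + 1):
                if M[i][k - 1] < INF and M[k][j] < INF and M[i][k - 1] + M[k][j] == target:
                    stack.append((i, k - 1, "M"))
                    stack.append((k, j, "M"))
                    found = True
                    break
            if found:
                continue
            if M[i + 1][j] < INF and M[i + 1][j] + ML_UNPAIRED == target:
                stack.append((i + 1, j, "M"))
            elif M[i][j - 1] < INF and M[i][j - 1] + ML_UNPAIRED == target:
                stack.append((i, j - 1, "M"))
            else:  # pragma: no cover
                raise AssertionError("traceback failed in M")


def from_dotbracket(sequence: str, structure: str, mfe: float | None = None) -> FoldResult:
    """Wrap an externally computed structure; score it internally if no MFE given."""
    rna = to_rna(sequence)
    _check_alphabet(rna)
    ptable = parse_dotbracket(structure)
    if mfe is None:
        e = structure_energy_int(rna, ptable)
        mfe = 0.0 if e is None else e / 10.0
    return FoldResult(rna, structure, float(mfe), ptable)


def viennarna_engine(rna: str) -> tuple[str, float]:
    """Adapter delegating folding to the ViennaRNA python bindings."""
    import RNA  # noqa: deferred optional dependency

    structure, mfe = RNA.fold(rna)
    return structure, float(mfe)


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle (short sequences only)
# ---------------------------------------------------------------------------

def enumerate_structures(sequence: str) -> list[list[int]]:
    """All nested structures (as partner tables) with valid pairs, min loop 3.

    Intended for sequences of ~20 nt or less; the count grows quickly.
    """
    rna = to_rna(sequence)
    _check_alphabet(rna)
    n = len(rna)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if i > j:
            return ((),)
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + HAIRPIN_MIN + 1, j + 1):
            if can_pair(rna[i], rna[k]):
                for inner in rec(i + 1, k - 1):
                    for rest in rec(k + 1, j):
                        out.append(((i, k),) + inner + rest)
        return tuple(out)

    results = []
    for pairs in rec(0, n - 1):
        ptable = [-1] * n
        for a, b in pairs:
            ptable[a], ptable[b] = b, a
        results.append(ptable)
    rec.cache_clear()
    return results


def mfe_by_enumeration(sequence: str) -> tuple[float, str]:
    """Brute-force MFE: score every nested structure, return (mfe, dot-bracket).

    The search is independent of the dynamic program; the open structure
    (energy 0) is always a candidate, so the result is ≤ 0.
    """
    rna = to_rna(sequence)
    best_e = 0
    best_pt = [-1] * len(rna)
    for ptable in enumerate_structures(rna):
        e = structure_energy_int(rna, ptable)
        if e is not None and e < best_e:
            best_e, best_pt = e, ptable
    return best_e / 10.0, _dotbracket(best_pt)
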