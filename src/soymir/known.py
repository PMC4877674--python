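"""Known-miRNA identification.

Clean unique reads are matched against a mature miRNA reference
(miRBase-style FASTA) under the tolerance rule used for isomiR-aware
annotation: length variation at both the 5' and 3' ends (up to
``max_end_shift`` nt per end, default 2) and at most one mismatch strictly
internal to the read. Reads mapping to the arm opposite a precursor's
annotated mature are reported as 5p/3p star-arm candidates. Matching is
performed in the DNA alphabet (U normalised to T on input).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .io import to_dna

logger = logging.getLogger(__name__)

DEFAULT_END_SHIFT = 2
DEFAULT_MAX_MISMATCH = 1
_SEED = 7  # seed k-mer length; pigeonhole-safe for overlaps ≥ 14 with 1 mismatch


@dataclass
class MatureMiRNA:
    id: str
    sequence: str  # stored as DNA
    species: str = ""
    precursor_id: str = ""
    arm: str = ""  # 5p / 3p when known
    family: str = ""

    def __post_init__(self):
        self.sequence = to_dna(self.sequence)
        if not self.species and "-" in self.id:
            self.species = self.id.split("-", 1)[0]
        if not self.family:
            self.family = assign_family(self.id)


@dataclass
class MiRNAMatch:
    read: str
    mature_id: str
    mismatches: int
    five_prime_offset: int   # read start − mature start (nt, signed)
    three_prime_offset: int  # read end − mature end (nt, signed)
    match_class: str = "known-same-arm"
    primary: bool = False


def _align(read: str, mature: str, shift: int, max_mismatch: int) -> int | None:
    """Mismatch count aligning read position i to mature position i+shift.

    Mismatches must be strictly internal to the read (not its first or last
    base). Returns None when the alignment violates the rule.
    """
    lo = max(0, -shift)
    hi = min(len(read), len(mature) - shift)
    if hi <= lo:
        return None
    mism = 0
    for i in range(lo, hi):
        if read[i] != mature[i + shift]:
            if i == 0 or i == len(read) - 1:
                return None
            mism += 1
            if mism > max_mismatch:
                return None
    return mism


class MatureIndex:
    """Seed-and-extend index over a mature reference.

    Seeds are exact 7-mers; with ≤1 internal mismatch and ≥14 nt of read /
    mature overlap every admissible alignment retains an exact run ≥ 7 nt,
    so candidate generation is lossless. An exhaustive-scan oracle
    (:func:`match_mature_bruteforce`) is kept for verification.
    """

    def __init__(self, matures: list[MatureMiRNA]):
        if not matures:
            raise ValueError("empty mature reference")
        ids = [m.id for m in matures]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate mature ids in reference: {dupes}")
        self.matures = matures
        self._kmers: dict[str, list[tuple[int, int]]] = {}
        for idx, m in enumerate(matures):
            seq = m.sequence
            for pos in range(len(seq) - _SEED + 1):
                self._kmers.setdefault(seq[pos:pos + _SEED], []).append((idx, pos))

    def candidates(self, read: str) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for rpos in range(len(read) - _SEED + 1):
            for idx, mpos in self._kmers.get(read[rpos:rpos + _SEED], ()):
                out.add((idx, mpos - rpos))
        return out


def index_reference(matures: list[MatureMiRNA]) -> MatureIndex:
    return MatureIndex(matures)


def _rank(m: MiRNAMatch):
    return (m.mismatches, abs(m.five_prime_offset) + abs(m.three_prime_offset), m.mature_id)


def match_mature(read: str, index: MatureIndex,
                 max_mismatch: int = DEFAULT_MAX_MISMATCH,
                 max_end_shift: int = DEFAULT_END_SHIFT,
                 species: str | None = None) -> list[MiRNAMatch]:
    """All reference matures matching ``read`` under the tolerance rule.

    The best match (fewest mismatches, then smallest total end shift, ties
    lexicographic by mature id) is flagged primary. When ``species`` is
    given, matches to other species are classed ``known-other-species``.
    """
    read = to_dna(read)
    best: dict[int, MiRNAMatch] = {}  # one best alignment per mature
    for idx, shift in index.candidates(read):
        if abs(shift) > max_end_shift:
            continue
        mature = index.matures[idx]
        three = (len(read) + shift) - len(mature.sequence)
        if abs(three) > max_end_shift:
            continue
        mism = _align(read, mature.sequence, shift, max_mismatch)
        if mism is None:
            continue
        cls = "known-same-arm"
        if species is not None and mature.species and mature.species != species:
            cls = "known-other-species"
        cand = MiRNAMatch(read, mature.id, mism, shift, three, cls)
        if idx not in best or _rank(cand) < _rank(best[idx]):
            best[idx] = cand
    matches = list(best.values())
    matches.sort(key=_rank)
    if matches:
        matches[0].primary = True
    return matches


def match_mature_bruteforce(read: str, matures: list[MatureMiRNA],
                            max_mismatch: int = DEFAULT_MAX_MISMATCH,
                            max_end_shift: int = DEFAULT_END_SHIFT) -> list[MiRNAMatch]:
    """Exhaustive-scan oracle: try every mature at every admissible shift."""
    read = to_dna(read)
    matches = []
    for mature in matures:
        found = []
        for shift in range(-max_end_shift, max_end_shift + 1):
            three = (len(read) + shift) - len(mature.sequence)
            if abs(three) > max_end_shift:
                continue
            mism = _align(read, mature.sequence, shift, max_mismatch)
            if mism is not None:
                found.append(MiRNAMatch(read, mature.id, mism, shift, three))
        if found:
            matches.append(min(found, key=_rank))
    matches.sort(key=_rank)
    if matches:
        matches[0].primary = True
    return matches


@dataclass
class Precursor:
    """A hairpin precursor with its annotated mature arm."""

    id: str
    sequence: str
    mature_start: int = -1  # -1 when unannotated
    mature_end: int = -1

    def __post_init__(self):
        self.sequence = to_dna(self.sequence)


def detect_opposite_arm(read: str, precursors: list[Precursor],
                        max_mismatch: int = DEFAULT_MAX_MISMATCH,
                        arm_slack: int = 6) -> MiRNAMatch | None:
    """Star-arm candidate: the read maps opposite the annotated mature arm.

    The expected star location is the mirror image of the mature within the
    precursor (± ``arm_slack`` nt); a hit overlapping the annotated mature
    itself is left to same-arm matching. Precursors without an annotated
    mature are skipped with a warning.
    """
    read = to_dna(read)
    for pre in precursors:
        if pre.mature_start < 0:
            logger.warning("precursor %s has no annotated mature arm; skipped", pre.id)
            continue
        n = len(pre.sequence)
        hit = _find_approx(read, pre.sequence, max_mismatch)
        if hit is None:
            continue
        s, e = hit, hit + len(read)
        if s < pre.mature_end and e > pre.mature_start:
            continue  # overlaps the annotated mature: not a star candidate
        mirror_s, mirror_e = n - pre.mature_end, n - pre.mature_start
        if s >= mirror_s - arm_slack and e <= mirror_e + arm_slack:
            arm = "5p" if (s + e) / 2 < n / 2 else "3p"
            return MiRNAMatch(read, f"{pre.id}-{arm}", 0, 0, 0,
                              match_class="known-opposite-arm", primary=True)
    return None


def _find_approx(read: str, seq: str, max_mismatch: int) -> int | None:
    """Leftmost occurrence of read in seq with ≤ max_mismatch internal mismatches."""
    for s in range(len(seq) - len(read) + 1):
        mism = 0
        ok = True
        for i, c in enumerate(read):
            if seq[s + i] != c:
                if i == 0 or i == len(read) - 1:
                    ok = False
                    break
                mism += 1
                if mism > max_mismatch:
                    ok = False
                    break
        if ok:
            return s
    return None


_FAMILY_RE = re.compile(r"^(?:[a-z]{2,4}[-_])?(?:mir|miR|MIR)[-]?(\d+)", re.IGNORECASE)


def assign_family(mature_id: str) -> str:
    """Family name from a miRBase-style id: gma-miR156a → miR156.

    Species prefix and letter/arm/precursor suffixes are stripped
    (gma-MIR159d-p3 → miR159). Unparseable ids are returned unchanged with
    a warning.
    """
    m = _FAMILY_RE.match(mature_id)
    if not m:
        logger.warning("cannot derive family from id %r", mature_id)
        return mature_id
    return f"miR{m.group(1)}"


def conservation_matrix(families: list[str],
                        species_sets: dict[str, list[str]]):
    """Presence/absence of each family across per-species mature-id sets."""
    import pandas as pd

    if not species_sets:
        raise ValueError("at least one species reference set is required")
    fam_by_species = {
        sp: {assign_family(mid) for mid in ids} for sp, ids in species_sets.items()
    }
    data = {
        sp: [fam in fams for fam in families] for sp, fams in fam_by_species.items()
    }
    return pd.DataFrame(data, index=families)
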