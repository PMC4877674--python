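"""Raw small-RNA read preprocessing: adapter trimming, junk and length
filtering, collapsing to unique sequences, ncRNA annotation, and the
per-category accounting table.

Every input read lands in exactly one accounting category (strict
partition): ``adapter_length`` (no insert, or insert outside the length
window, or no adapter found), ``junk`` (N-containing / low-complexity /
homopolymer), one of the ncRNA/repeat/mRNA classes, or ``clean``. Junk is
an operational definition — pipelines of this era never published theirs —
with thresholds configurable in :class:`PreprocessConfig`.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .io import to_dna

NO_INSERT = ""  # sentinel for adapter-only reads

#: annotation categories in their fixed priority order (first match wins)
NCRNA_PRIORITY = ["rRNA", "tRNA", "snoRNA", "snRNA", "other-Rfam", "repeat", "mRNA"]

CATEGORIES = ["adapter_length", "junk"] + NCRNA_PRIORITY + ["clean"]


@dataclass
class PreprocessConfig:
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_overlap: int = 8          # adapter overlap needing exact match below this
    min_len: int = 18
    max_len: int = 25
    max_base_fraction: float = 0.8  # junk: single base dominance
    max_homopolymer: int = 7        # junk: longest run allowed
    drop_singletons: bool = False   # optional low-copy filter (total count 1)


@dataclass
class CollapsedRead:
    """A unique insert sequence with per-library counts and one annotation."""

    sequence: str
    counts: dict[str, int]
    annotation: str = "clean"

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def trim_adapter(sequence: str, adapter: str, min_overlap: int = 8) -> tuple[str, bool]:
    """Trim the 3' adapter; returns (insert, adapter_found).

    The insert is the prefix before the *leftmost* adapter match. A match at
    position ``p`` aligns the adapter 5' end with the read; overlaps of at
    least ``min_overlap`` nt tolerate one mismatch, shorter terminal
    overlaps must match exactly. An adapter match at position 0 yields the
    ``NO_INSERT`` sentinel. When no match exists the read is returned
    unchanged with ``adapter_found=False`` (idempotent on trimmed reads).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read = to_dna(sequence)
    n, m = len(read), len(adapter)
    for p in range(n):
        overlap = min(m, n - p)
        mism = 0
        for k in range(overlap):
            if read[p + k] != adapter[k]:
                mism += 1
                if mism > 1:
                    break
        allowed = 1 if overlap >= min_overlap else 0
        if mism <= allowed:
            return (read[:p] if p else NO_INSERT), True
    return read, False


def filter_junk(sequence: str, max_base_fraction: float = 0.8,
                max_homopolymer: int = 7) -> bool:
    """True to keep; False for N-containing / low-complexity / homopolymer reads."""
    seq = to_dna(sequence)
    if not seq or "N" in seq:
        return False
    counts = Counter(seq)
    if counts.most_common(1)[0][1] > max_base_fraction * len(seq):
        return False
    run = best = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best <= max_homopolymer


def length_filter(sequence: str, min_len: int = 18, max_len: int = 25) -> bool:
    return min_len <= len(sequence) <= max_len


def collapse_reads(reads) -> list[CollapsedRead]:
    """Collapse (sequence, library) pairs to unique sequences.

    Order is deterministic: descending total count, then lexicographic.
    """
    table: dict[str, Counter] = defaultdict(Counter)
    for seq, library in reads:
        table[to_dna(seq)][library] += 1
    out = [CollapsedRead(seq, dict(cnt)) for seq, cnt in table.items()]
    out.sort(key=lambda r: (-r.total, r.sequence))
    return out


class ReferenceSets:
    """Named ncRNA/repeat/mRNA reference sets supporting substring queries."""

    def __init__(self, sets: dict[str, dict[str, str]]):
        missing = [name for name in NCRNA_PRIORITY if name not in sets]
        if missing:
            raise ValueError(f"missing reference sets: {missing}")
        # concatenate with separators for fast exact-substring membership
        self._blobs = {
            name: "#" + "#".join(to_dna(s) for s in seqs.values()) + "#"
            for name, seqs in sets.items()
        }

    def annotate(self, sequence: str) -> str:
        seq = to_dna(sequence)
        for name in NCRNA_PRIORITY:
            if seq in self._blobs[name]:
                return name
        return "clean"


def annotate_ncrna(collapsed: CollapsedRead, references: ReferenceSets) -> str:
    """Exact-substring annotation in fixed priority order; unmatched → clean."""
    collapsed.annotation = references.annotate(collapsed.sequence)
    return collapsed.annotation


def run_preprocess(reads_by_library: dict[str, list[str]],
                   references: ReferenceSets | None,
                   config: PreprocessConfig | None = None):
    """Full preprocessing of raw reads, one list per library.

    Returns (clean collapsed reads, accounting table DataFrame,
    length-distribution DataFrame). The accounting table is a strict
    partition of the raw reads.
    """
    cfg = config or PreprocessConfig()
    libraries = list(reads_by_library)
    raw = {(lib, cat): 0 for lib in libraries for cat in CATEGORIES}
    survivors = []  # (sequence, library) for collapsing
    for lib, reads in reads_by_library.items():
        for read in reads:
            insert, found = trim_adapter(read, cfg.adapter, cfg.min_overlap)
            if not found or insert == NO_INSERT or not length_filter(insert, cfg.min_len, cfg.max_len):
                raw[(lib, "adapter_length")] += 1
                continue
            if not filter_junk(insert, cfg.max_base_fraction, cfg.max_homopolymer):
                raw[(lib, "junk")] += 1
                continue
            survivors.append((insert, lib))

    collapsed = collapse_reads(survivors)
    if cfg.drop_singletons:
        dropped = [r for r in collapsed if r.total == 1]
        collapsed = [r for r in collapsed if r.total > 1]
        for r in dropped:
            for lib, c in r.counts.items():
                raw[(lib, "adapter_length")] += c
    unique = {(lib, cat): 0 for lib in libraries for cat in CATEGORIES}
    for rec in collapsed:
        cat = annotate_ncrna(rec, references) if references is not None else "clean"
        for lib, c in rec.counts.items():
            raw[(lib, cat)] += c
            unique[(lib, cat)] += 1

    clean = [r for r in collapsed if r.annotation == "clean"]
    table = build_accounting_table(raw, unique, libraries)
    hist = length_distribution(clean, cfg.min_len, cfg.max_len)
    return clean, table, hist


def build_accounting_table(raw: dict, unique: dict, libraries: list[str]) -> pd.DataFrame:
    """Table-1-style accounting: raw and unique counts per category per library."""
    rows = []
    for cat in CATEGORIES + ["total"]:
        row: dict[str, object] = {"category": cat}
        for lib in libraries:
            if cat == "total":
                row[f"{lib}_raw"] = sum(raw[(lib, c)] for c in CATEGORIES)
                row[f"{lib}_unique"] = sum(unique[(lib, c)] for c in CATEGORIES)
            else:
                row[f"{lib}_raw"] = raw[(lib, cat)]
                row[f"{lib}_unique"] = unique[(lib, cat)]
        rows.append(row)
    return pd.DataFrame(rows)


def length_distribution(clean: list[CollapsedRead], min_len: int = 18,
                        max_len: int = 25) -> pd.DataFrame:
    """Redundant and unique read counts per insert length over the window."""
    libraries = sorted({lib for r in clean for lib in r.counts})
    rows = []
    for length in range(min_len, max_len + 1):
        row: dict[str, object] = {"length": length}
        for lib in libraries:
            row[f"{lib}_raw"] = sum(r.counts.get(lib, 0) for r in clean
                                    if len(r.sequence) == length)
            row[f"{lib}_unique"] = sum(1 for r in clean
                                       if len(r.sequence) == length and r.counts.get(lib, 0) > 0)
        rows.append(row)
    return pd.DataFrame(rows)
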