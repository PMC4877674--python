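"""Degradome (PARE) target identification and category 0–4 classification.

Degradome reads mark uncapped mRNA 5' ends; a miRNA-guided cleavage leaves
a 3' fragment whose 5' end sits opposite miRNA nucleotides 10–11 of the
aligned small RNA. The module maps degradome 5' ends to transcripts
(t-plots), scores miRNA:target complementarity with the standard plant
penalty scheme (mismatch 1, G:U wobble 0.5, gap 1; positions 2–13 from the
miRNA 5' end doubled; default cutoff 7), verifies cleavage-site signal, and
assigns categories by the count at the slice site relative to the
transcript's maximum and median:

* 0 — >1 read at the site, equal to the unique transcript maximum;
* 1 — >1 read, equal to a shared maximum;
* 2 — >1 read, below the maximum but above the median;
* 3 — >1 read, at or below the median;
* 4 — exactly one read at the site.

The median is computed over occupied positions (≥1 read) by default; the
all-positions alternative is a flag. Transcript coordinates are 1-based in
all reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import revcomp, to_dna

DEFAULT_MAX_SCORE = 7.0
CORE_START, CORE_END = 2, 13  # miRNA positions (1-based) with doubled penalties

_WOBBLE = {("G", "T"), ("T", "G")}


@dataclass
class TPlot:
    """Per-position degradome 5'-end counts for one transcript (1-based)."""

    transcript_id: str
    length: int
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, position: int, count: int = 1) -> None:
        if not (1 <= position <= self.length):
            raise ValueError("position outside transcript")
        self.counts[position] = self.counts.get(position, 0) + count


@dataclass
class DuplexAlignment:
    mirna: str                 # 5'→3'
    target_window: str         # transcript 5'→3'
    states: list[str]          # per miRNA position: match / wobble / mismatch / gap
    score: float
    target_start: int          # 1-based transcript coords of the site
    target_end: int
    cleavage_position: int     # transcript position opposite miRNA nt 10


@dataclass
class TargetCall:
    mirna_id: str
    transcript_id: str
    alignment: DuplexAlignment
    reads_at_site: int
    category: int


def map_degradome(reads: list[str], transcriptome: dict[str, str]) -> tuple[dict[str, TPlot], int]:
    """Exact-match each read's 5' end; multimappers counted at every locus.

    Returns ({transcript: TPlot}, number of multi-mapping reads).
    """
    if not transcriptome:
        raise ValueError("empty transcriptome")
    seqs = {tid: to_dna(s) for tid, s in transcriptome.items()}
    tplots = {tid: TPlot(tid, len(s)) for tid, s in seqs.items()}
    multimapped = 0
    for read in reads:
        read = to_dna(read)
        hits = []
        for tid, seq in seqs.items():
            pos = seq.find(read)
            while pos >= 0:
                hits.append((tid, pos + 1))  # 1-based 5' end
                pos = seq.find(read, pos + 1)
        if len(hits) > 1:
            multimapped += 1
        for tid, p in hits:
            tplots[tid].add(p)
    return tplots, multimapped


def _pair_state(mirna_base: str, target_base: str) -> str:
    if target_base == revcomp(mirna_base):
        return "match"
    if (mirna_base, target_base) in _WOBBLE:
        return "wobble"
    return "mismatch"


def score_duplex(mirna: str, target_window: str,
                 target_start: int = 1) -> DuplexAlignment:
    """Score an ungapped miRNA:target duplex.

    The window is the transcript-forward site sequence paired antiparallel
    with the miRNA (miRNA 5' end opposite the window's 3' end). Penalties:
    mismatch 1.0, G:U 0.5, doubled at miRNA positions 2–13. The cleavage
    position is the transcript coordinate opposite miRNA nucleotide 10.
    ``target_start`` is the 1-based transcript coordinate of the window.
    """
    mir = to_dna(mirna)
    win = to_dna(target_window)
    if len(win) != len(mir):
        raise ValueError("ungapped duplex needs equal miRNA and window lengths")
    states = []
    score = 0.0
    for p in range(1, len(mir) + 1):  # miRNA position, 1-based from 5' end
        t_base = win[len(win) - p]
        state = _pair_state(mir[p - 1], t_base)
        penalty = {"match": 0.0, "wobble": 0.5, "mismatch": 1.0}[state]
        if CORE_START <= p <= CORE_END:
            penalty *= 2.0
        score += penalty
        states.append(state)
    cleavage = target_start + len(win) - 10  # opposite miRNA nt 10
    return DuplexAlignment(mir, win, states, score, target_start,
                           target_start + len(win) - 1, cleavage)


def align_duplex(mirna: str, target_window: str, target_start: int = 1,
                 max_gaps: int = 1) -> DuplexAlignment:
    """Best duplex alignment allowing up to ``max_gaps`` gaps (penalty 1.0,
    doubled in the core like substitutions).

    The window length may differ from the miRNA length by at most
    ``max_gaps``. The miRNA is consumed 5'→3' against the window 3'→5'; a
    gap either skips a miRNA base (bulged miRNA nucleotide) or a window
    base (bulged target nucleotide).
    """
    mir = to_dna(mirna)
    win = to_dna(target_window)[::-1]  # window 3'->5', paired with miRNA 5'->3'
    if abs(len(win) - len(mir)) > max_gaps:
        raise ValueError("window length outside miRNA length ± allowed gaps")
    nm, nw = len(mir), len(win)
    INF = float("inf")

    def gap_pen(p: int) -> float:
        return 2.0 if CORE_START <= p <= CORE_END else 1.0

    # dp[(i, j, g)] = (score, states) consuming mir[:i], win[:j] with g gaps
    dp: dict[tuple[int, int, int], tuple[float, tuple]] = {(0, 0, 0): (0.0, ())}
    for i in range(nm + 1):
        for j in range(nw + 1):
            for g in range(max_gaps + 1):
                cur = dp.get((i, j, g))
                if cur is None:
                    continue
                score, states = cur
                p = i + 1  # 1-based miRNA position of the next consumed base
                if i < nm and j < nw:
                    state = _pair_state(mir[i], win[j])
                    pen = {"match": 0.0, "wobble": 0.5, "mismatch": 1.0}[state]
                    if CORE_START <= p <= CORE_END:
                        pen *= 2.0
                    key = (i + 1, j + 1, g)
                    cand = (score + pen, states + (state,))
                    if key not in dp or cand < dp[key]:
                        dp[key] = cand
                if g < max_gaps:
                    if i < nm:  # miRNA base bulged out
                        key = (i + 1, j, g + 1)
                        cand = (score + gap_pen(p), states + ("gap",))
                        if key not in dp or cand < dp[key]:
                            dp[key] = cand
                    if j < nw:  # target base bulged out
                        key = (i, j + 1, g + 1)
                        cand = (score + gap_pen(p), states + ("gap",))
                        if key not in dp or cand < dp[key]:
                            dp[key] = cand
    best = min((dp.get((nm, nw, g), (INF, ())) for g in range(max_gaps + 1)))
    score, states = best
    # cleavage: transcript coordinate opposite miRNA nt 10 (ungapped geometry)
    cleavage = target_start + len(target_window) - 10
    return DuplexAlignment(mir, to_dna(target_window), list(states), score,
                           target_start, target_start + len(target_window) - 1,
                           cleavage)


def find_target_sites(mirna: str, transcript: str, transcript_id: str = "",
                      max_score: float = DEFAULT_MAX_SCORE,
                      max_gaps: int = 0) -> list[DuplexAlignment]:
    """All complementarity sites with penalty ≤ max_score.

    The default scan is ungapped; ``max_gaps=1`` additionally tries windows
    one nucleotide shorter/longer with a single gap.
    """
    mir = to_dna(mirna)
    seq = to_dna(transcript)
    sites = []
    for start in range(len(seq) - len(mir) + 1):
        aln = score_duplex(mir, seq[start:start + len(mir)], start + 1)
        if aln.score <= max_score:
            sites.append(aln)
    if max_gaps > 0:
        for wlen in (len(mir) - 1, len(mir) + 1):
            for start in range(len(seq) - wlen + 1):
                aln = align_duplex(mir, seq[start:start + wlen], start + 1, max_gaps)
                if aln.score <= max_score:
                    sites.append(aln)
    return sites


def find_cleavage_candidates(tplot: TPlot, alignments: list[DuplexAlignment],
                             window: int = 1) -> list[tuple[DuplexAlignment, int, int]]:
    """Alignments with degradome signal at the expected slice site.

    A site is a candidate when the t-plot holds ≥1 read within ±``window``
    nt of the position opposite miRNA nucleotides 10–11. Returns
    (alignment, supported position, reads) choosing the highest-count
    position in the window (ties: closest to the canonical site, then 5').
    """
    out = []
    for aln in alignments:
        c = aln.cleavage_position
        best = None
        for pos in range(c - window, c + window + 1):
            reads = tplot.counts.get(pos, 0)
            if reads >= 1:
                key = (-reads, abs(pos - c), pos)
                if best is None or key < best[0]:
                    best = (key, pos, reads)
        if best is not None:
            out.append((aln, best[1], best[2]))
    return out


def classify_category(tplot: TPlot, position: int,
                      median_over_occupied: bool = True) -> int:
    """Category 0–4 for the degradome signal at ``position`` (1-based)."""
    reads = tplot.counts.get(position, 0)
    if reads < 1:
        raise ValueError("no degradome reads at the cleavage position")
    if reads == 1:
        return 4
    values = [c for c in tplot.counts.values() if c >= 1]
    maximum = max(values)
    if median_over_occupied:
        median = float(np.median(values))
    else:
        full = np.zeros(tplot.length)
        for p, c in tplot.counts.items():
            full[p - 1] = c
        median = float(np.median(full))
    if reads == maximum:
        n_max = sum(1 for c in values if c == maximum)
        return 0 if n_max == 1 else 1
    if reads > median:
        return 2
    return 3


def call_targets(mirnas: dict[str, str], transcriptome: dict[str, str],
                 tplots: dict[str, TPlot],
                 max_score: float = DEFAULT_MAX_SCORE,
                 window: int = 1,
                 median_over_occupied: bool = True) -> list[TargetCall]:
    """Full target calling: site scan, cleavage check, categorisation."""
    calls = []
    for mirna_id, mir in sorted(mirnas.items()):
        for tid, seq in sorted(transcriptome.items()):
            tplot = tplots.get(tid)
            if tplot is None or tplot.total == 0:
                continue
            sites = find_target_sites(mir, seq, tid, max_score)
            for aln, pos, reads in find_cleavage_candidates(tplot, sites, window):
                cat = classify_category(tplot, pos, median_over_occupied)
                calls.append(TargetCall(mirna_id, tid, aln, reads, cat))
    return calls


def category_distribution(calls: list[TargetCall]) -> dict[int, int]:
    dist = {c: 0 for c in range(5)}
    for call in calls:
        dist[call.category] += 1
    return dist
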