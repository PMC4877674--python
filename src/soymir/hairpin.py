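"""Pre-miRNA hairpin evaluation and novel miRNA discovery.

Candidate precursor windows are folded (:mod:`soymir.fold`), summarised by
MFE / AMFE / MFEI, and screened with seven structural criteria commonly used
for plant pre-miRNA annotation:

1. the mature miRNA lies in one arm of the stem-loop;
2. no bulge in the stem exceeds ``max_bulge`` (12 nt) and the stem holds
   more than ``min_stem_pairs`` (16) base pairs;
3. the terminal loop is shorter than ``max_loop`` (20 nt) and the whole
   hairpin longer than ``min_hairpin_len`` (50 nt);
4. no single bulge carries more than ``max_bias_per_bulge`` (4 nt) of
   *biased error* — unpaired nucleotides without a counterpart on the
   opposite arm;
5. fewer than two *biased bulges* (bulges whose unpaired bases all sit on
   one arm), fewer than 4 mismatches (symmetric unpaired positions), and
   more than 12 paired bases in the mature region;
6. more than 80% of the mature region lies within the stem;
7. the fold is thermodynamically miRNA-like: MFEI ≥ 0.85 and
   MFE ≤ −25 kcal/mol.

The evaluated hairpin is delimited from the outermost paired mature base
inward to the terminal loop, walking the unbranched helix chain; pairs basal
to the mature duplex are ignored, which keeps the criteria focused on the
miRNA/star region and robust to incidental pairing in flanking genomic
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fold import FoldResult, fold
from .io import revcomp, to_dna

DEFAULT_FLANK = 120


@dataclass
class CriteriaThresholds:
    """Bounds for the seven structural criteria (all configurable)."""

    max_bulge: int = 12            # criterion 2: per-bulge size, exclusive
    min_stem_pairs: int = 16       # criterion 2: stem pairs, exclusive
    max_loop: int = 20             # criterion 3: loop length, exclusive
    min_hairpin_len: int = 50      # criterion 3: hairpin length, exclusive
    max_bias_per_bulge: int = 4    # criterion 4: asymmetric nt per bulge, inclusive
    max_biased_bulges: int = 1     # criterion 5: biased bulges, inclusive
    max_mismatches: int = 3        # criterion 5: stem mismatches, inclusive
    min_mature_pairs: int = 12     # criterion 5: mature paired bases, exclusive
    min_mature_in_stem: float = 0.8  # criterion 6: fraction, exclusive
    min_mfei: float = 0.85         # criterion 7, inclusive
    max_mfe: float = -25.0         # criterion 7 (kcal/mol), inclusive


@dataclass
class HairpinDiagnostics:
    arm: str = "?"                 # 5p / 3p
    stem_pairs: int = 0
    loop_len: int = 0
    hairpin_len: int = 0
    max_bulge: int = 0
    max_bias: int = 0
    biased_bulges: int = 0
    mismatches: int = 0
    mature_pairs: int = 0
    mature_in_stem: float = 0.0


@dataclass
class HairpinCandidate:
    """A genomic precursor window with its fold and per-criterion verdicts."""

    chrom: str
    start: int                     # 0-based half-open genome coordinates
    end: int
    strand: str
    fold: FoldResult
    mature_start: int              # within the precursor window
    mature_end: int
    amfe: float = 0.0
    mfei: float | None = None
    criteria: list[bool] = field(default_factory=list)
    diagnostics: HairpinDiagnostics = field(default_factory=HairpinDiagnostics)

    @property
    def passes(self) -> bool:
        return len(self.criteria) == 7 and all(self.criteria)

    @property
    def mature_sequence(self) -> str:
        return to_dna(self.fold.sequence[self.mature_start:self.mature_end])


def fold_rna(sequence: str, min_len: int = 5, max_len: int = 400, engine=None) -> FoldResult:
    """Fold a candidate precursor window (length bounds configurable)."""
    if not (min_len <= len(sequence) <= max_len):
        raise ValueError(
            f"precursor window length {len(sequence)} outside [{min_len}, {max_len}]")
    return fold(sequence, engine=engine)


def compute_mfe_stats(result: FoldResult) -> tuple[float, float, float | None]:
    """(MFE, AMFE, MFEI); AMFE = |MFE|/length×100, MFEI = AMFE/(GC%).

    Both AMFE and MFEI are reported as positive magnitudes. MFEI is ``None``
    for a GC-free sequence (undefined).
    """
    n = len(result.sequence)
    amfe = abs(result.mfe) / n * 100.0 if n else 0.0
    gc = sum(1 for c in result.sequence if c in "GC") / n * 100.0 if n else 0.0
    mfei = None if gc == 0 else amfe / gc
    return result.mfe, amfe, mfei


def _stem_chain(ptable: list[int], mature_start: int, mature_end: int):
    """Helix chain from the outermost paired mature base to the terminal loop.

    Returns (chain, arm, mature_pairs) where chain is a list of (i, j) pairs
    ordered outer→inner, or (None, arm, pairs) when no mature base is paired
    or mature bases pair inconsistently.
    """
    partners = [(i, ptable[i]) for i in range(mature_start, mature_end) if ptable[i] >= 0]
    if not partners:
        return None, "?", 0
    if any(mature_start <= p < mature_end for _, p in partners):
        return None, "?", len(partners)  # mature pairs with itself
    on_right = [p >= mature_end for _, p in partners]
    if all(on_right):
        arm = "5p"
        i0 = min(i for i, _ in partners)
        outer = (i0, ptable[i0])
    elif not any(on_right):
        arm = "3p"
        j0 = max(i for i, _ in partners)
        outer = (ptable[j0], j0)
    else:
        return None, "?", len(partners)
    # walk inward along the unbranched chain
    chain = [outer]
    while True:
        p, q = chain[-1]
        children = []
        k = p + 1
        while k < q:
            if ptable[k] > k:
                children.append((k, ptable[k]))
                k = ptable[k] + 1
            else:
                k += 1
        if len(children) != 1:
            break  # terminal loop (0) or branching (≥2): stem ends here
        chain.append(children[0])
    return chain, arm, len(partners)


def check_criteria(candidate: HairpinCandidate,
                   thresholds: CriteriaThresholds | None = None) -> list[bool]:
    """Evaluate the seven criteria; fills diagnostics and returns the flags."""
    th = thresholds or CriteriaThresholds()
    ptable = candidate.fold.ptable
    ms, me = candidate.mature_start, candidate.mature_end
    if not (0 <= ms < me <= len(ptable)):
        raise ValueError("mature placement outside the precursor window")

    d = HairpinDiagnostics()
    chain, arm, mature_pairs = _stem_chain(ptable, ms, me)
    d.arm = arm
    d.mature_pairs = mature_pairs

    if chain is None:
        candidate.diagnostics = d
        _, candidate.amfe, candidate.mfei = compute_mfe_stats(candidate.fold)
        c7 = (candidate.mfei is not None and candidate.mfei >= th.min_mfei
              and candidate.fold.mfe <= th.max_mfe)
        candidate.criteria = [False, False, False, False, False, False, c7]
        return candidate.criteria

    p_out, q_out = chain[0]
    p_in, q_in = chain[-1]
    d.stem_pairs = len(chain)
    d.loop_len = q_in - p_in - 1
    d.hairpin_len = max(q_out, me - 1) - min(p_out, ms) + 1
    gaps = []
    for (p1, q1), (p2, q2) in zip(chain, chain[1:]):
        a, b = p2 - p1 - 1, q1 - q2 - 1
        if a or b:
            gaps.append((a, b))
    d.max_bulge = max((max(a, b) for a, b in gaps), default=0)
    d.max_bias = max((abs(a - b) for a, b in gaps), default=0)
    d.biased_bulges = sum(1 for a, b in gaps if min(a, b) == 0)
    d.mismatches = sum(min(a, b) for a, b in gaps)
    if arm == "5p":
        in_stem = sum(1 for i in range(ms, me) if p_out <= i <= p_in)
        spans_loop = (me - 1) >= q_in
    else:
        in_stem = sum(1 for i in range(ms, me) if q_in <= i <= q_out)
        spans_loop = ms <= p_in
    d.mature_in_stem = in_stem / (me - ms)

    _, candidate.amfe, candidate.mfei = compute_mfe_stats(candidate.fold)

    c1 = not spans_loop  # mature confined to one arm (consistent partners already ensured)
    c2 = d.max_bulge < th.max_bulge and d.stem_pairs > th.min_stem_pairs
    c3 = d.loop_len < th.max_loop and d.hairpin_len > th.min_hairpin_len
    c4 = d.max_bias <= th.max_bias_per_bulge
    c5 = (d.biased_bulges <= th.max_biased_bulges
          and d.mismatches <= th.max_mismatches
          and d.mature_pairs > th.min_mature_pairs)
    c6 = d.mature_in_stem > th.min_mature_in_stem
    c7 = (candidate.mfei is not None and candidate.mfei >= th.min_mfei
          and candidate.fold.mfe <= th.max_mfe)

    candidate.diagnostics = d
    candidate.criteria = [c1, c2, c3, c4, c5, c6, c7]
    return candidate.criteria


def evaluate_window(chrom: str, start: int, end: int, strand: str, window_seq: str,
                    mature_offset: int, mature_len: int,
                    thresholds: CriteriaThresholds | None = None,
                    engine=None) -> HairpinCandidate:
    """Fold one genomic window and run the criteria.

    ``window_seq`` is the genome-forward sequence of [start, end); for '-'
    strand loci the reverse complement is folded and the mature offset is
    given on the folded (transcribed) strand.
    """
    seq = revcomp(window_seq) if strand == "-" else window_seq
    result = fold_rna(seq, min_len=max(5, mature_len), max_len=10000 if engine else 400,
                      engine=engine)
    cand = HairpinCandidate(chrom, start, end, strand, result,
                            mature_offset, mature_offset + mature_len)
    check_criteria(cand, thresholds)
    return cand


@dataclass
class NovelMiRNA:
    """A novel miRNA: one mature sequence with one or more precursor loci."""

    name: str
    mature: str
    precursors: list[HairpinCandidate]


def _genome_hits(read: str, genome: dict[str, str]) -> list[tuple[str, int, str]]:
    hits = []
    rc = revcomp(read)
    for chrom, seq in genome.items():
        for query, strand in ((read, "+"), (rc, "-")):
            pos = seq.find(query)
            while pos >= 0:
                hits.append((chrom, pos, strand))
                pos = seq.find(query, pos + 1)
    return hits


def call_novel_mirnas(reads: list[str], genome: dict[str, str],
                      flank: int = DEFAULT_FLANK,
                      thresholds: CriteriaThresholds | None = None,
                      engine=None) -> tuple[list[NovelMiRNA], dict[str, int]]:
    """Screen unannotated reads for novel miRNA loci.

    Each perfect genome hit is extended by ``flank`` nt downstream and,
    separately, upstream (both directions tried); each window is folded and
    criteria-checked; a locus passing on either extension is reported once.
    Candidates sharing an identical mature sequence are grouped into one
    miRNA with numbered precursors. Returns (novel miRNAs, log counters).
    """
    log = {"reads": len(reads), "no_hit": 0, "hits": 0, "loci_pass": 0}
    by_mature: dict[str, list[HairpinCandidate]] = {}
    for read in reads:
        read = to_dna(read)
        hits = _genome_hits(read, genome)
        if not hits:
            log["no_hit"] += 1
            continue
        log["hits"] += len(hits)
        for chrom, pos, strand in hits:
            chrom_seq = genome[chrom]
            m = len(read)
            windows = [
                (max(0, pos - flank), min(len(chrom_seq), pos + m)),   # upstream
                (max(0, pos), min(len(chrom_seq), pos + m + flank)),   # downstream
            ]
            best = None
            for ws, we in windows:
                if strand == "+":
                    offset = pos - ws
                else:
                    offset = we - (pos + m)
                cand = evaluate_window(chrom, ws, we, strand, chrom_seq[ws:we],
                                       offset, m, thresholds, engine=engine)
                if cand.passes:
                    best = cand
                    break
            if best is not None:
                log["loci_pass"] += 1
                by_mature.setdefault(read, []).append(best)

    novel = []
    for idx, (mature, cands) in enumerate(sorted(by_mature.items()), start=1):
        # one record per distinct locus: overlapping windows (e.g. the two
        # strands of the same inverted repeat) collapse to the best fold
        cands = sorted(cands, key=lambda c: (c.chrom, c.start, c.fold.mfe))
        uniq: list[HairpinCandidate] = []
        for c in cands:
            merged = False
            for i, u in enumerate(uniq):
                if c.chrom == u.chrom and c.start < u.end and c.end > u.start:
                    if c.fold.mfe < u.fold.mfe:
                        uniq[i] = c
                    merged = True
                    break
            if not merged:
                uniq.append(c)
        novel.append(NovelMiRNA(f"miRN{idx}", mature, uniq))
    return novel, log


def render_candidate(novel: NovelMiRNA) -> str:
    """Plain-text block per candidate: sequence, dot-bracket, mature marked."""
    lines = []
    for i, c in enumerate(novel.precursors, start=1):
        suffix = f"-{i}" if len(novel.precursors) > 1 else ""
        marker = [" "] * len(c.fold.sequence)
        for p in range(c.mature_start, c.mature_end):
            marker[p] = "*"
        lines += [
            f"> {novel.name}{suffix} {c.chrom}:{c.start}-{c.end}({c.strand}) "
            f"MFE={c.fold.mfe:.1f} AMFE={c.amfe:.1f} "
            f"MFEI={'NA' if c.mfei is None else f'{c.mfei:.2f}'}",
            to_dna(c.fold.sequence),
            c.fold.structure,
            "".join(marker).rstrip(),
            "",
        ]
    return "\n".join(lines)
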