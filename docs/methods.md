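# Methods

This note documents the models, conventions, and numerical choices behind
each stage, what the synthetic data does and does not emulate, and the
known limitations.

## Read preprocessing

Adapter trimming returns the prefix before the *leftmost* adapter match;
overlaps of at least `min_overlap` (8) nt tolerate one mismatch, shorter
terminal overlaps must be exact. A read equal to the adapter yields an
empty insert and is discarded; a read without any adapter match is
returned unchanged (so trimming is idempotent) but routed to the
adapter/length-filter category by the pipeline, since a library built with
3' adapter ligation should show the adapter in every genuine insert.

"Junk" has no published definition in pipelines of this kind; we
operationalise it as: any N, a single base above 80% of the read, or a
homopolymer run of 8+. These thresholds are configurable and the
accounting category is therefore not comparable across tools.

Annotation assigns each unique sequence exactly one class by
exact-substring match against the reference sets in the fixed priority
order rRNA > tRNA > snoRNA > snRNA > other-Rfam > repeat > mRNA. Published
accounting tables from commercial pipelines visibly overlap categories
(their class rows do not sum to their clean-read row); ours is a strict
partition by construction: total = adapter/length + junk + Σclasses +
clean, exactly, per library. Low-copy filtering (unique sequences with
total count 1) exists behind a flag and is off by default because no
defensible universal threshold exists.

## Known-miRNA matching

The tolerance rule is: up to 2 nt of length variation at each end and at
most one mismatch strictly internal to the read (never its first or last
base). The 2 nt bound is our documented choice — descriptions of this
matching style say "length variation" without a bound. One best alignment
per mature is kept (fewest mismatches, then smallest total end shift, ties
lexicographic by id), and a read matching several matures is reported for
all but counted once, under its primary match, to keep RPM totals free of
double-counting.

The index is seed-and-extend with exact 7-mers. With one internal mismatch
and at least 14 nt of overlap (the minimum under the end-shift bounds for
18 nt reads), the longest exact run is ≥ 7 nt, so candidate generation is
lossless; an exhaustive-scan oracle is kept and property-tested against
the index.

Star-arm (opposite-arm) detection approximates the star location as the
mirror image of the annotated mature within the precursor (± 6 nt slack)
rather than folding every precursor; reads overlapping the annotated
mature are left to same-arm matching, and loop-spanning reads fall outside
the mirrored window.

## Folding model

The folder is a self-contained Zuker-style dynamic program over a
simplified nearest-neighbour model, designed to be exactly verifiable
rather than to reproduce any published parameter set:

* all energies are integers in tenths of kcal/mol — the optimisation is
  exact arithmetic, so the DP can be compared bit-for-bit against
  exhaustive enumeration of all nested structures (the acceptance oracle,
  200 random sequences ≤ 20 nt);
* stacked pairs contribute −(S(p₁)+S(p₂)) with S(G:C)=1.6, S(A:U)=1.1,
  S(G:U)=0.6 kcal/mol; isolated pairs gain nothing;
* loop penalties (kcal/mol): hairpin 4.5 + 1.75·ln(L/3), bulge
  3.8 + 1.75·ln L, internal 1.7 + 1.75·ln(L/2); minimum hairpin loop 3 nt;
  two-sided loops are capped at 10 unpaired nt in total — larger
  interruptions are disallowed by the model (the structure scorer enforces
  the same cap, keeping the enumeration oracle consistent);
* multiloops pay 3.4 + 0.4·(branches+1) + 0.1·unpaired.

Tie-breaking is by deterministic traceback with a fixed case order
(interior loops from the stack outward, then multiloop, then hairpin),
which prefers stacked continuations; we do not guarantee a global
maximum-pair tie-break, since identical-energy structures are
interchangeable for criterion-bound decisions. Bit-compatibility with
ViennaRNA or any other published folder is explicitly not promised —
criterion bounds, not exact MFE values, drive the calls — but an external
folder can be plugged in via dot-bracket import, and a test cross-checks
that both engines agree on the stem of a long inverted repeat.

MFE statistics: AMFE = |MFE|/length×100; MFEI = AMFE/GC%. Both are
positive magnitudes; MFEI is undefined (reported missing) at GC = 0.

## Hairpin criteria

The evaluated hairpin is delimited from the outermost *paired mature base*
inward along the unbranched helix chain to the terminal loop. Pairs basal
to the mature duplex are deliberately excluded: in a 140 nt genomic
window, flanking sequence often pairs incidentally, and including those
helices would make the verdict depend on flank noise rather than on the
miRNA/star duplex. Within the chain, a *gap* between consecutive pairs has
a unpaired nt on the 5' arm and b on the 3' arm; we define:

* mismatches: Σ min(a, b) (symmetric unpaired positions);
* biased error: |a − b| per gap (asymmetric unpaired positions);
* biased bulge: a gap with min(a, b) = 0 (all unpaired bases on one arm).

The seven criteria, with defaults: (1) mature confined to one arm, all
partners on the opposite arm; (2) every gap < 12 nt and > 16 stem pairs;
(3) loop < 20 nt and hairpin > 50 nt; (4) per-gap biased error ≤ 4 nt;
(5) ≤ 1 biased bulge, ≤ 3 mismatches, > 12 mature pairs; (6) > 80% of
mature bases within the stem extent; (7) MFEI ≥ 0.85 and MFE ≤ −25
kcal/mol. The criterion-7 bounds are our choices: typical reported ranges
for plant pre-miRNAs (MFEI ≈ 0.9–1.4, MFE ≈ −50 to −80 kcal/mol) pass
with margin. The phrase "no more than 4 nt and two biased errors in one
bulge" that motivates criterion 4 is ambiguous (per bulge vs total); we
apply the 4 nt bound per bulge and note that the two-error clause is
subsumed by criterion 5's stricter biased-bulge count. All bounds are
monotone threshold comparisons on diagnostics, so loosening any threshold
can never turn a pass into a fail (property-tested).

Novel calling extends each perfect genome hit of an unannotated read by
120 nt upstream and, separately, downstream; a locus passing on either
window is reported once, overlapping windows (e.g. the two strands of the
same inverted repeat) are merged keeping the lowest-MFE fold, and
candidates sharing one mature sequence across loci become one miRNA with
numbered precursors. Minus-strand loci are folded on the reverse
complement; coordinates are 0-based half-open genome-forward throughout.

## Differential expression

Normalisation follows the described formula — count / total miRNA reads ×
10⁶ — which is reads-per-million despite sometimes being labelled "RPKM"
in study write-ups; no length term is appropriate for ~21 nt reads. The
two-library test is the Audic–Claverie conditional-binomial form: given
n = x + y, y ~ Binomial(n, N₂/(N₁+N₂)) under the null of equal relative
abundance; the two-sided p-value sums all outcomes no more likely than
observed (minlike), computed by direct summation in log space. Fisher's
exact test is a pluggable alternative. No multiple-testing correction is
applied by default (calls use raw p ≤ 0.001 with |log2| ≥ 1, the
convention this pipeline reproduces); a Benjamini–Hochberg flag exists.
Rounding to two decimals happens only in writers.

Because the test conditions on library totals, a fold change shared by
*all* miRNAs is invisible by construction — only changes in relative
abundance are detectable. This also means a compositional shift: if the
differential miRNAs carry a noticeable share of total miRNA abundance,
every ratio is offset by −log2(total ratio). The synthetic defaults keep
the differential stratum a small share of abundance (see below), which is
also the realistic regime (tens of responsive miRNAs among hundreds).

## Degradome

Mapping is exact-match of each read's 5' end; multi-mapping reads are
counted at every locus and flagged. Duplex scoring uses the standard plant
penalty scheme — mismatch 1, G:U wobble 0.5, gap 1, penalties doubled at
miRNA positions 2–13, cutoff 7 — as a convention choice, configurable; a
single-gap alignment variant is provided. A candidate requires ≥ 1 read
within ±1 nt (configurable) of the position opposite miRNA nucleotide 10.
Categories follow the standard five-class scheme; the median is computed
over occupied positions (≥ 1 read) by default, with the all-positions
alternative behind a flag; maxima are detected by exact integer equality.
Transcript coordinates are 1-based in reports.

## qPCR

ΔCt = Ct_gene − Ct_reference per replicate (replicate-paired when counts
match); ΔΔCt subtracts the calibrator-condition mean; relative expression
is 2^−ΔΔCt, and the calibrator condition is exactly 1 by construction.
Group comparison uses Welch's t on the ΔCt replicates — the two-group
special case of the ANOVA customarily quoted for such designs — with
stars at p < 0.05 (*) and p < 0.01 (**). Tests run on the approximately
normal ΔCt scale, never on fold changes. Amplification-efficiency
correction (Pfaffl) is out of scope.

## Synthetic data: what it emulates, and what it does not

The generator plants perfect inverted repeats (arm 21–24 nt, loop 9–15 nt)
in a uniform random genome; the designated arm is the mature miRNA. Every
accepted locus is verified with the pipeline's own criteria checker, both
bare and through the novel-calling path in its final genomic context —
occasionally a random loop folds onto itself asymmetrically and violates a
bulge bound, and such loci are redrawn. This guarantees the closed loop
(planted ⇒ discoverable) that the recovery tests rely on.

Counts are negative binomial with dispersion 0.1 via a shared Gamma latent
per miRNA and per-library Poisson sampling scaled by the programmed fold
change. The sharing matters: it models biological overdispersion of the
common RNA pool with independent sequencing sampling per library, so under
fold change 1 the two libraries are conditionally exchangeable and the
conditional-binomial test keeps its nominal size (the null acceptance
check: ≤ 0.5% of 1000 null miRNAs at p ≤ 0.001). Independent
negative-binomial draws per library would instead make any single-library
pair test arbitrarily anti-conservative — a real limitation of
replicate-free designs that the pipeline inherits deliberately, since it
reproduces a pooled-library workflow.

Default study conditions: 20 hairpins of which 3 novel, 10 differential at
fold change 4, library depth 50,000 reads, background abundance log-uniform
500–5000 expected counts and differential abundance 100–400 (keeping the
differential share of miRNA abundance near 10%, so the compositional shift
stays near 0.3–0.5 log2 units), degradome signal fraction 0.9 with 20
reads per planted target over a uniform background, Ct noise SD 0.2
cycles with 3 replicates. Reads carry a fixed 3' adapter with
read-through at 36 nt read length; background inserts follow a length
profile dominated by the 21 and 24 nt classes and are rejection-sampled to
survive trimming unchanged, which makes the truth sidecar exactly equal to
re-collapsing the emitted FASTQ after adapter removal.

Not emulated: per-base sequencing error, quality-score structure (constant
Phred+33 'I'), 5'-RACE chemistry, realistic genome composition (GC skew,
repeats), isomiR end heterogeneity, and multi-site targets. Passing the
closed-loop tests therefore demonstrates correctness of the pipeline's
logic under its stated assumptions, not robustness to sequencing-error
modes absent from the simulation.

## Problem sizes and determinism

The test suite and the acceptance script run the full synthetic study at
20 hairpins / 50,000 reads per library, the folding oracle at 200
sequences ≤ 20 nt, the category oracle exhaustively over all count vectors
of length ≤ 5 with counts ≤ 5, and the null size check at 1000 miRNAs —
sizes chosen so the complete closed loop (including exhaustive oracles)
runs in a couple of minutes on one CPU. All randomness flows through
explicit seeds; rerunning any stage with the same configuration and seed
is byte-identical (enforced by a double-run hash test), and output headers
carry the tool version, a configuration hash, and the seed.

## Known limitations

* The folding model is intentionally small: no dangles, no coaxial
  stacking, no asymmetry penalties, two-sided loops capped at 10 nt. MFE
  values are comparable only within this model.
* Novel calling requires a perfect genome hit of the read and tries two
  fixed window extensions; loci needing longer precursors than read+120 nt
  or mismatched genome copies are missed.
* The two-library test has no replicate-aware dispersion estimate; with
  pooled libraries, biological variability is not separable from the
  treatment effect.
* Degradome scoring scans ungapped sites by default (one gap optional) and
  does not model peak noise beyond the category scheme.
* The star-arm mirror approximation can mislabel precursors with very
  asymmetric loops.
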