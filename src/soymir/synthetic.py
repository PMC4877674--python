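"""Synthetic data with known ground truth for closed-loop testing.

The generator emulates the data of a two-condition (control vs chilling)
small-RNA study at the level the pipeline consumes:

* a random genome with planted near-perfect inverted-repeat hairpin loci
  (arms 21–24 nt, loops 9–15 nt) whose designated arm is the mature miRNA;
* two small-RNA libraries in which each miRNA's counts are negative
  binomial — a per-miRNA Gamma latent abundance shared by both libraries
  (biological overdispersion, default dispersion 0.1) with per-library
  Poisson sampling scaled by the programmed fold change, so that under a
  fold change of 1 the two libraries are conditionally exchangeable and
  count-based tests keep their nominal size;
* reads carrying a fixed 3' adapter with read-through, plus background
  reads (random inserts and optional ncRNA decoy fragments) with a length
  profile dominated by the 21 nt and 24 nt classes;
* a transcriptome with planted perfectly complementary target sites and a
  degradome library whose 5' ends pile up opposite miRNA nucleotides 10–11
  of each planted site, over a uniform background;
* replicate Ct tables with Gaussian noise around the programmed relative
  expression.

All randomness flows through one seeded :class:`numpy.random.Generator`;
the same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import revcomp, write_fasta, write_fastq
from .preprocess import trim_adapter

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_DISPERSION = 0.1
DEFAULT_READ_LENGTH = 36

#: insert-length profile of background small-RNA reads (18–25 nt window,
#: dominated by the 21 nt and 24 nt size classes typical of plant libraries)
BACKGROUND_LENGTH_PROFILE = {
    18: 0.04, 19: 0.05, 20: 0.08, 21: 0.30, 22: 0.10, 23: 0.08, 24: 0.30, 25: 0.05,
}


@dataclass
class PlantedHairpin:
    locus_id: str
    chrom: str
    start: int  # 0-based half-open genome coordinates
    end: int
    strand: str
    arm: str          # 5p / 3p
    mature: str       # mature sequence on the transcribed strand
    is_novel: bool = False


@dataclass
class PlantedTarget:
    mirna_id: str
    transcript_id: str
    site_start: int   # 1-based inclusive transcript coordinates
    site_end: int
    cleavage_pos: int  # 1-based; opposite miRNA nt 10
    signal_fraction: float = 1.0


@dataclass
class GroundTruthManifest:
    """Everything the simulators planted, for closed-loop verification."""

    hairpins: list[PlantedHairpin] = field(default_factory=list)
    abundance: dict[str, float] = field(default_factory=dict)       # mean control count
    fold_changes: dict[str, float] = field(default_factory=dict)    # chilling/control
    targets: list[PlantedTarget] = field(default_factory=list)
    qpcr_truth: dict[str, float] = field(default_factory=dict)      # expected ratio

    def mirna_ids(self) -> list[str]:
        return [h.locus_id for h in self.hairpins]

    def mature_of(self, mirna_id: str) -> str:
        for h in self.hairpins:
            if h.locus_id == mirna_id:
                return h.mature
        raise KeyError(mirna_id)

    def validate(self, genome: dict[str, str] | None = None,
                 transcriptome: dict[str, str] | None = None) -> None:
        for mid, fc in self.fold_changes.items():
            if fc <= 0:
                raise ValueError(f"fold change for {mid} must be strictly positive")
        if genome is not None:
            for h in self.hairpins:
                locus = genome[h.chrom][h.start:h.end]
                if h.strand == "-":
                    locus = revcomp(locus)
                if h.mature not in locus:
                    raise ValueError(f"mature of {h.locus_id} not within its locus")
        if transcriptome is not None:
            for t in self.targets:
                seq = transcriptome.get(t.transcript_id)
                if seq is None:
                    raise ValueError(f"unknown transcript {t.transcript_id}")
                if not (1 <= t.site_start <= t.site_end <= len(seq)):
                    raise ValueError(f"target site of {t.mirna_id} outside transcript")

    # -- structured text round-trip ---------------------------------------
    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# soymir ground-truth manifest v1\n")
            fh.write("[hairpins]\nlocus_id\tchrom\tstart\tend\tstrand\tarm\tmature\tis_novel\n")
            for h in self.hairpins:
                fh.write(f"{h.locus_id}\t{h.chrom}\t{h.start}\t{h.end}\t{h.strand}"
                         f"\t{h.arm}\t{h.mature}\t{int(h.is_novel)}\n")
            fh.write("[abundance]\nmirna_id\tmean_control\tfold_change\n")
            for mid in self.abundance:
                fh.write(f"{mid}\t{self.abundance[mid]!r}\t{self.fold_changes.get(mid, 1.0)!r}\n")
            fh.write("[targets]\nmirna_id\ttranscript_id\tsite_start\tsite_end"
                     "\tcleavage_pos\tsignal_fraction\n")
            for t in self.targets:
                fh.write(f"{t.mirna_id}\t{t.transcript_id}\t{t.site_start}\t{t.site_end}"
                         f"\t{t.cleavage_pos}\t{t.signal_fraction!r}\n")
            fh.write("[qpcr]\ngene\texpected_ratio\n")
            for g, r in self.qpcr_truth.items():
                fh.write(f"{g}\t{r!r}\n")

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruthManifest":
        manifest = cls()
        section = None
        header: list[str] = []
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                section = line.strip("[]")
                header = []
                continue
            if not header:
                header = line.split("\t")
                continue
            vals = dict(zip(header, line.split("\t")))
            if section == "hairpins":
                manifest.hairpins.append(PlantedHairpin(
                    vals["locus_id"], vals["chrom"], int(vals["start"]), int(vals["end"]),
                    vals["strand"], vals["arm"], vals["mature"], bool(int(vals["is_novel"]))))
            elif section == "abundance":
                manifest.abundance[vals["mirna_id"]] = float(vals["mean_control"])
                manifest.fold_changes[vals["mirna_id"]] = float(vals["fold_change"])
            elif section == "targets":
                manifest.targets.append(PlantedTarget(
                    vals["mirna_id"], vals["transcript_id"], int(vals["site_start"]),
                    int(vals["site_end"]), int(vals["cleavage_pos"]),
                    float(vals["signal_fraction"])))
            elif section == "qpcr":
                manifest.qpcr_truth[vals["gene"]] = float(vals["expected_ratio"])
        return manifest


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def simulate_genome_with_hairpins(n_hairpins: int, genome_length: int, seed: int,
                                  n_novel: int = 0,
                                  arm_range: tuple[int, int] = (21, 24),
                                  loop_range: tuple[int, int] = (9, 15),
                                  margin: int = 150,
                                  adapter: str = DEFAULT_ADAPTER,
                                  max_tries: int = 2000,
                                  ) -> tuple[dict[str, str], GroundTruthManifest]:
    """Random genome with ``n_hairpins`` planted inverted-repeat loci.

    Each locus is a perfect inverted repeat (arm + loop + revcomp(arm))
    whose designated arm is the mature miRNA; geometry (arm 21–24, loop
    9–15) gives the criteria generous margins, and every constructed locus
    is verified with the hairpin module's own criteria checker — both on
    the bare locus and through the novel-calling path in its final genomic
    context — before it is accepted (the random loop can occasionally fold
    onto itself and break a bulge bound, in which case the locus is
    redrawn). The first ``n_novel`` loci are flagged novel (left out of the
    mature reference by :func:`mature_reference`). Placement keeps
    ``margin`` nt between loci; failure after bounded retries raises.
    """
    from .hairpin import call_novel_mirnas, evaluate_window

    if n_hairpins < 1:
        raise ValueError("n_hairpins must be ≥ 1")
    if n_novel > n_hairpins:
        raise ValueError("n_novel cannot exceed n_hairpins")
    rng = np.random.default_rng(seed)
    genome_seq = list(_random_seq(rng, genome_length))
    occupied: list[tuple[int, int]] = []
    manifest = GroundTruthManifest()
    for idx in range(n_hairpins):
        for attempt in range(max_tries):
            arm_len = int(rng.integers(arm_range[0], arm_range[1] + 1))
            loop_len = int(rng.integers(loop_range[0], loop_range[1] + 1))
            arm = _random_seq(rng, arm_len)
            loop = _random_seq(rng, loop_len)
            hairpin = arm + loop + revcomp(arm)
            # the mature must survive adapter trimming untouched
            arm5, arm3 = arm, revcomp(arm)
            if trim_adapter(arm5 + adapter, adapter)[0] != arm5:
                continue
            if trim_adapter(arm3 + adapter, adapter)[0] != arm3:
                continue
            hp_len = len(hairpin)
            if genome_length < hp_len + 2 * margin:
                raise ValueError("genome too short to place hairpins")
            start = int(rng.integers(margin, genome_length - hp_len - margin))
            end = start + hp_len
            if any(start - margin < e and end + margin > s for s, e in occupied):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            arm_choice = "5p" if rng.random() < 0.5 else "3p"
            mature = arm5 if arm_choice == "5p" else arm3
            # closed loop: the bare locus must pass the criteria checker ...
            tx = hairpin if strand == "+" else revcomp(hairpin)
            cand = evaluate_window("chr1", start, end, "+", tx,
                                   tx.find(mature), len(mature))
            if not cand.passes:
                continue
            # ... and the locus must be discoverable in its genomic context
            # (flanks are final: later loci are placed beyond the margin)
            ctx_lo = max(0, start - margin)
            ctx = ("".join(genome_seq[ctx_lo:start]) + hairpin
                   + "".join(genome_seq[end:end + margin]))
            found, _ = call_novel_mirnas([mature], {"ctx": ctx})
            if not found:
                continue
            genome_seq[start:end] = hairpin
            occupied.append((start, end))
            manifest.hairpins.append(PlantedHairpin(
                f"syn-miR{idx + 1:03d}", "chr1", start, end, strand,
                arm_choice, mature, is_novel=idx < n_novel))
            break
        else:
            raise RuntimeError(
                f"could not place hairpin {idx + 1} after {max_tries} attempts")
    genome = {"chr1": "".join(genome_seq)}
    manifest.validate(genome=genome)
    return genome, manifest


def mature_reference(manifest: GroundTruthManifest,
                     species: str = "syn") -> list[tuple[str, str]]:
    """(id, sequence) records of the non-novel matures (miRBase-style set)."""
    return [(h.locus_id, h.mature) for h in manifest.hairpins if not h.is_novel]


def set_expression(manifest: GroundTruthManifest, rng_or_seed,
                   mean_range: tuple[float, float] = (500.0, 5000.0),
                   de_mean_range: tuple[float, float] = (100.0, 400.0),
                   de_ids: list[str] | None = None,
                   de_fold_change: float = 4.0) -> None:
    """Assign per-miRNA mean counts (log-uniform) and programmed fold changes.

    Differential miRNAs are drawn from a lower abundance stratum than the
    non-differential background. In real libraries the responsive miRNAs
    are a modest share of total miRNA abundance, so normalisation to the
    miRNA total is only mildly perturbed by the programmed changes; making
    half the total abundance differential would confound every ratio with
    the compositional shift.
    """
    rng = np.random.default_rng(rng_or_seed) if isinstance(rng_or_seed, int) else rng_or_seed
    de = set(de_ids or [])
    for h in manifest.hairpins:
        lo, hi = de_mean_range if h.locus_id in de else mean_range
        mean = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        manifest.abundance[h.locus_id] = round(mean, 2)
        manifest.fold_changes[h.locus_id] = de_fold_change if h.locus_id in de else 1.0
        manifest.qpcr_truth[h.locus_id] = manifest.fold_changes[h.locus_id]


def simulate_small_rna_libraries(manifest: GroundTruthManifest,
                                 control_path: str | Path,
                                 chilling_path: str | Path,
                                 depth_per_library: int = 50_000,
                                 dispersion: float = DEFAULT_DISPERSION,
                                 seed: int = 0,
                                 adapter: str = DEFAULT_ADAPTER,
                                 read_length: int = DEFAULT_READ_LENGTH,
                                 decoys: dict[str, str] | None = None,
                                 decoy_fraction: float = 0.3,
                                 ) -> pd.DataFrame:
    """Two FASTQ libraries plus an exact per-sequence truth table.

    miRNA counts: latent abundance λ_i ~ Gamma(1/dispersion,
    mean_i·dispersion) shared by both libraries; per-library counts are
    Poisson(λ_i) and Poisson(λ_i·fold_change) — marginally negative
    binomial, conditionally exchangeable under fold change 1. Background
    reads fill each library up to ``depth_per_library``; every read is
    insert + 3' adapter truncated to ``read_length`` (adapter
    read-through). Returns the truth table (sequence, source, counts).
    """
    if depth_per_library < 1000:
        raise ValueError("depth_per_library must be ≥ 1000")
    if not manifest.abundance:
        raise ValueError("manifest has no abundance; call set_expression first")
    rng = np.random.default_rng(seed)
    shape = 1.0 / dispersion

    counts: dict[str, dict[str, int]] = {}
    sources: dict[str, str] = {}
    for h in manifest.hairpins:
        mean = manifest.abundance[h.locus_id]
        fc = manifest.fold_changes.get(h.locus_id, 1.0)
        lam = rng.gamma(shape, mean * dispersion)
        c_ctrl = int(rng.poisson(lam))
        c_chill = int(rng.poisson(lam * fc))
        entry = counts.setdefault(h.mature, {"control": 0, "chilling": 0})
        entry["control"] += c_ctrl
        entry["chilling"] += c_chill
        sources[h.mature] = h.locus_id

    planted = set(counts)
    lengths = np.array(sorted(BACKGROUND_LENGTH_PROFILE))
    weights = np.array([BACKGROUND_LENGTH_PROFILE[l] for l in lengths], float)
    weights /= weights.sum()
    decoy_seqs = list(decoys.values()) if decoys else []

    def background_insert() -> str:
        while True:
            if decoy_seqs and rng.random() < decoy_fraction:
                src = decoy_seqs[int(rng.integers(len(decoy_seqs)))]
                length = int(rng.choice(lengths, p=weights))
                if len(src) <= length:
                    continue
                pos = int(rng.integers(0, len(src) - length))
                ins = src[pos:pos + length]
            else:
                ins = _random_seq(rng, int(rng.choice(lengths, p=weights)))
            # closed loop: the insert must survive trimming unchanged
            if ins not in planted and trim_adapter(ins + adapter, adapter)[0] == ins:
                return ins

    for lib in ("control", "chilling"):
        mirna_total = sum(entry[lib] for entry in counts.values())
        n_bg = max(0, depth_per_library - mirna_total)
        for _ in range(n_bg):
            ins = background_insert()
            entry = counts.setdefault(ins, {"control": 0, "chilling": 0})
            entry[lib] += 1
            sources.setdefault(ins, "background")

    for path, lib in ((control_path, "control"), (chilling_path, "chilling")):
        reads = []
        for seq, entry in counts.items():
            reads += [(seq + adapter)[:read_length]] * entry[lib]
        order = rng.permutation(len(reads))
        write_fastq(path, ((f"{lib}_{i + 1}", reads[j]) for i, j in enumerate(order)))

    truth = pd.DataFrame(
        {
            "sequence": list(counts),
            "source": [sources[s] for s in counts],
            "control": [counts[s]["control"] for s in counts],
            "chilling": [counts[s]["chilling"] for s in counts],
        }
    ).sort_values(["source", "sequence"]).reset_index(drop=True)
    return truth


def simulate_transcriptome(manifest: GroundTruthManifest, seed: int,
                           transcript_length: int = 400,
                           margin: int = 40,
                           signal_fraction: float = 1.0,
                           mirna_ids: list[str] | None = None,
                           ) -> dict[str, str]:
    """One transcript per selected miRNA with a perfectly complementary
    target site; site coordinates recorded in the manifest."""
    rng = np.random.default_rng(seed)
    ids = mirna_ids if mirna_ids is not None else manifest.mirna_ids()
    transcriptome: dict[str, str] = {}
    for i, mid in enumerate(ids, start=1):
        mature = manifest.mature_of(mid)
        site = revcomp(mature)
        tid = f"transcript{i:03d}"
        seq = _random_seq(rng, transcript_length)
        pos0 = int(rng.integers(margin, transcript_length - len(site) - margin))
        seq = seq[:pos0] + site + seq[pos0 + len(site):]
        transcriptome[tid] = seq
        site_start = pos0 + 1
        site_end = pos0 + len(site)
        cleavage = site_start + len(site) - 10  # opposite miRNA nt 10
        manifest.targets.append(PlantedTarget(mid, tid, site_start, site_end,
                                              cleavage, signal_fraction))
    manifest.validate(transcriptome=transcriptome)
    return transcriptome


def simulate_degradome_library(manifest: GroundTruthManifest,
                               transcriptome: dict[str, str],
                               signal_fraction: float,
                               seed: int,
                               out_path: str | Path | None = None,
                               reads_per_target: int = 20,
                               background_reads: int = 300,
                               read_length: int = 20,
                               ) -> tuple[list[str], pd.DataFrame]:
    """Degradome reads: 5' ends concentrated at each planted cleavage site.

    Per target, Binomial(reads_per_target, signal_fraction) reads start
    exactly at the position opposite miRNA nt 10–11; the rest, plus
    ``background_reads`` per library, start uniformly over the transcript.
    Returns (reads, truth table); writes FASTA when a path is given.
    """
    if not (0 <= signal_fraction <= 1):
        raise ValueError("signal_fraction must be within [0, 1]")
    rng = np.random.default_rng(seed)
    reads: list[str] = []
    rows = []
    for t in manifest.targets:
        seq = transcriptome.get(t.transcript_id)
        if seq is None:
            raise ValueError(f"unknown transcript {t.transcript_id}")
        n_sig = int(rng.binomial(reads_per_target, signal_fraction))
        n_noise = reads_per_target - n_sig
        for _ in range(n_sig):
            reads.append(seq[t.cleavage_pos - 1:t.cleavage_pos - 1 + read_length])
        for _ in range(n_noise):
            p = int(rng.integers(0, len(seq) - read_length))
            reads.append(seq[p:p + read_length])
        rows.append({"mirna_id": t.mirna_id, "transcript_id": t.transcript_id,
                     "cleavage_pos": t.cleavage_pos, "signal_reads": n_sig,
                     "noise_reads": n_noise})
    tids = sorted(transcriptome)
    for _ in range(background_reads):
        tid = tids[int(rng.integers(len(tids)))]
        seq = transcriptome[tid]
        p = int(rng.integers(0, len(seq) - read_length))
        reads.append(seq[p:p + read_length])
    if out_path is not None:
        write_fasta(out_path, ((f"deg_{i + 1}", r) for i, r in enumerate(reads)))
    return reads, pd.DataFrame(rows)


def simulate_qpcr_table(manifest: GroundTruthManifest, n_replicates: int = 3,
                        ct_noise_sd: float = 0.2, seed: int = 0,
                        reference: str = "U6", baseline: float = 30.0,
                        out_path: str | Path | None = None) -> pd.DataFrame:
    """Replicate Ct values around the programmed relative expression.

    Ct = baseline_gene − log2(expression) + Gaussian noise; the reference
    gene has constant expression in both conditions. Expression is 1 in the
    control (calibrator) and the programmed ratio under chilling.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be ≥ 2")
    rng = np.random.default_rng(seed)
    genes = list(manifest.qpcr_truth) + [reference]
    rows = []
    for g_idx, gene in enumerate(genes):
        base = baseline + (g_idx % 7) - 3  # deterministic per-gene baseline offset
        for condition in ("control", "chilling"):
            if gene == reference:
                expr = 1.0
            else:
                expr = 1.0 if condition == "control" else manifest.qpcr_truth[gene]
            for rep in range(1, n_replicates + 1):
                noise = float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd > 0 else 0.0
                rows.append({"gene": gene, "condition": condition, "replicate": rep,
                             "ct": base - float(np.log2(expr)) + noise})
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


def simulate_bundle(out_dir: str | Path, seed: int,
                    n_hairpins: int = 20, n_novel: int = 3, n_de: int = 10,
                    de_fold_change: float = 4.0, genome_length: int = 100_000,
                    depth_per_library: int = 50_000,
                    dispersion: float = DEFAULT_DISPERSION,
                    signal_fraction: float = 0.9,
                    n_targets: int = 10,
                    ct_noise_sd: float = 0.2,
                    adapter: str = DEFAULT_ADAPTER) -> dict:
    """Generate a complete synthetic study into ``out_dir``.

    Emits genome, mature reference, annotation decoy references, two
    small-RNA FASTQ libraries, transcriptome, degradome FASTA, Ct table,
    the ground-truth manifest and truth sidecar tables. The differential
    miRNAs are the first ``n_de`` non-novel loci; planted targets cover the
    first ``n_targets`` non-novel miRNAs. Returns the in-memory objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genome, manifest = simulate_genome_with_hairpins(
        n_hairpins, genome_length, int(rng.integers(2**31)), n_novel=n_novel,
        adapter=adapter)
    known_ids = [h.locus_id for h in manifest.hairpins if not h.is_novel]
    set_expression(manifest, int(rng.integers(2**31)), de_ids=known_ids[:n_de],
                   de_fold_change=de_fold_change)
    decoys = make_decoy_references(int(rng.integers(2**31)))
    decoy_pool = {name: seq for seqs in decoys.values() for name, seq in seqs.items()}
    truth = simulate_small_rna_libraries(
        manifest, out / "control.fastq", out / "chilling.fastq",
        depth_per_library, dispersion, int(rng.integers(2**31)), adapter,
        decoys=decoy_pool)
    transcriptome = simulate_transcriptome(
        manifest, int(rng.integers(2**31)), signal_fraction=signal_fraction,
        mirna_ids=known_ids[:n_targets])
    deg_reads, deg_truth = simulate_degradome_library(
        manifest, transcriptome, signal_fraction, int(rng.integers(2**31)),
        out_path=out / "degradome.fasta")
    qpcr = simulate_qpcr_table(manifest, 3, ct_noise_sd, int(rng.integers(2**31)),
                               out_path=out / "ct_table.tsv")

    write_fasta(out / "genome.fasta", genome.items())
    write_fasta(out / "mature_reference.fasta", mature_reference(manifest))
    write_fasta(out / "transcriptome.fasta", transcriptome.items())
    annotation_paths = {}
    for cls, seqs in decoys.items():
        p = out / f"ref_{cls.replace('-', '_')}.fasta"
        write_fasta(p, seqs.items())
        annotation_paths[cls] = str(p)
    truth.to_csv(out / "truth_counts.tsv", sep="\t", index=False)
    deg_truth.to_csv(out / "truth_degradome.tsv", sep="\t", index=False)
    manifest.write(out / "manifest.txt")
    return {
        "manifest": manifest, "genome": genome, "transcriptome": transcriptome,
        "truth_counts": truth, "degradome_truth": deg_truth, "qpcr_table": qpcr,
        "degradome_reads": deg_reads, "annotation_paths": annotation_paths,
        "adapter": adapter,
    }


def make_decoy_references(seed: int = 17, n_per_class: int = 3,
                          length: int = 120) -> dict[str, dict[str, str]]:
    """Random ncRNA/repeat/mRNA reference sets for annotation testing."""
    rng = np.random.default_rng(seed)
    classes = ["rRNA", "tRNA", "snoRNA", "snRNA", "other-Rfam", "repeat", "mRNA"]
    return {
        cls: {f"{cls}_{i + 1}": _random_seq(rng, length) for i in range(n_per_class)}
        for cls in classes
    }
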