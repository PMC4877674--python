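"""Pipeline orchestration: configuration, stage ordering, and reporting.

Stages run in the order preprocess → known → novel → differential
expression → degradome → qPCR, each consuming the previous stage's outputs
and skipping cleanly when its inputs are not configured. Every output file
carries a header with the tool version, a hash of the effective
configuration, and the seed, and a rerun with the same configuration and
seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .degradome import (call_targets, category_distribution, map_degradome)
from .diffexpr import call_differential, format_de_table
from .hairpin import CriteriaThresholds, call_novel_mirnas, render_candidate
from .io import iter_fastq, read_fasta, write_collapsed_fasta
from .known import (MatureMiRNA, Precursor, detect_opposite_arm, index_reference,
                    match_mature)
from .preprocess import PreprocessConfig, ReferenceSets, run_preprocess
from .qpcr import analyze_ct_table, load_ct_table


class PipelineError(RuntimeError):
    """A stage-labeled pipeline failure; partial outputs are preserved."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs, outputs and thresholds of every stage.

    Threshold defaults are the pipeline's documented operating point:
    18–25 nt length window, one internal mismatch and ±2 nt end shifts for
    known-miRNA matching, the seven hairpin criterion bounds, p ≤ 0.001
    with |log2 ratio| ≥ 1 for differential calls, duplex penalty ≤ 7 and a
    ±1 nt cleavage window for degradome targets.
    """

    # inputs (empty string = stage skipped)
    control_fastq: str = ""
    chilling_fastq: str = ""
    mature_fasta: str = ""
    precursor_fasta: str = ""
    genome_fasta: str = ""
    transcriptome_fasta: str = ""
    degradome_fasta: str = ""
    ct_table: str = ""
    annotation_fastas: dict = field(default_factory=dict)  # class -> FASTA path
    out_dir: str = "soymir_run"

    # preprocess
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_overlap: int = 8
    min_len: int = 18
    max_len: int = 25
    drop_singletons: bool = False

    # known matching
    max_mismatch: int = 1
    max_end_shift: int = 2
    species: str = ""

    # novel calling
    flank: int = 120
    novel_min_count: int = 1
    max_bulge: int = 12
    min_stem_pairs: int = 16
    max_loop: int = 20
    min_hairpin_len: int = 50
    max_bias_per_bulge: int = 4
    max_biased_bulges: int = 1
    max_mismatches_stem: int = 3
    min_mature_pairs: int = 12
    min_mature_in_stem: float = 0.8
    min_mfei: float = 0.85
    max_mfe: float = -25.0

    # differential expression
    p_threshold: float = 0.001
    lfc_threshold: float = 1.0
    pseudocount: float = 0.0

    # degradome
    duplex_max_score: float = 7.0
    cleavage_window: int = 1

    # qpcr
    qpcr_reference: str = "U6"
    calibrator: str = "control"
    treatment: str = "chilling"

    seed: int = 1

    def criteria_thresholds(self) -> CriteriaThresholds:
        return CriteriaThresholds(
            self.max_bulge, self.min_stem_pairs, self.max_loop, self.min_hairpin_len,
            self.max_bias_per_bulge, self.max_biased_bulges, self.max_mismatches_stem,
            self.min_mature_pairs, self.min_mature_in_stem, self.min_mfei, self.max_mfe)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        data = asdict(self)
        data.pop("out_dir")  # the destination does not change the analysis
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    return (f"# soymir v{__version__} config={config.hash()} seed={config.seed}\n")


def _write_tsv(path: Path, df: pd.DataFrame, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns a results dict of DataFrames/objects."""
    for name in ("control_fastq", "chilling_fastq"):
        path = getattr(config, name)
        if not path:
            raise PipelineError("config", f"missing required input: {name}")
        if not Path(path).exists():
            raise PipelineError("config", f"{name} does not exist: {path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "effective_config.yaml")
    results: dict = {}

    # ---- preprocess ------------------------------------------------------
    stage = "preprocess"
    try:
        reads = {
            "control": list(iter_fastq(config.control_fastq)),
            "chilling": list(iter_fastq(config.chilling_fastq)),
        }
        references = None
        if config.annotation_fastas:
            references = ReferenceSets(
                {cls: read_fasta(p) for cls, p in config.annotation_fastas.items()})
        pre_cfg = PreprocessConfig(config.adapter, config.min_overlap, config.min_len,
                                   config.max_len, drop_singletons=config.drop_singletons)
        clean, accounting, lengths = run_preprocess(reads, references, pre_cfg)
        _write_tsv(out / "accounting.tsv", accounting, config)
        _write_tsv(out / "length_distribution.tsv", lengths, config)
        write_collapsed_fasta(out / "clean_collapsed.fasta",
                              ((f"sr{i + 1}", r.sequence, r.total)
                               for i, r in enumerate(clean)))
        results["clean"] = clean
        results["accounting"] = accounting
        results["lengths"] = lengths
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive stage labeling
        raise PipelineError(stage, str(exc)) from exc

    # ---- known miRNAs ----------------------------------------------------
    mirna_counts: dict[str, dict[str, int]] = {}
    mirna_seqs: dict[str, str] = {}
    unmatched = []
    if config.mature_fasta:
        stage = "known"
        try:
            matures = [MatureMiRNA(mid, seq) for mid, seq in
                       read_fasta(config.mature_fasta).items()]
            index = index_reference(matures)
            precursors = []
            if config.precursor_fasta:
                precursors = [Precursor(pid, seq) for pid, seq in
                              read_fasta(config.precursor_fasta).items()]
            match_rows = []
            for rec in results["clean"]:
                matches = match_mature(rec.sequence, index, config.max_mismatch,
                                       config.max_end_shift, config.species or None)
                if not matches and precursors:
                    star = detect_opposite_arm(rec.sequence, precursors,
                                               config.max_mismatch)
                    if star is not None:
                        matches = [star]
                if not matches:
                    unmatched.append(rec)
                    continue
                primary = matches[0]
                entry = mirna_counts.setdefault(primary.mature_id,
                                                {"control": 0, "chilling": 0})
                for lib, c in rec.counts.items():
                    entry[lib] = entry.get(lib, 0) + c
                mirna_seqs.setdefault(primary.mature_id, rec.sequence)
                for m in matches:
                    match_rows.append({
                        "read": m.read, "mature": m.mature_id,
                        "mismatches": m.mismatches,
                        "offset_5p": m.five_prime_offset,
                        "offset_3p": m.three_prime_offset,
                        "class": m.match_class, "primary": m.primary,
                    })
            _write_tsv(out / "known_matches.tsv", pd.DataFrame(match_rows), config)
            results["known_matches"] = pd.DataFrame(match_rows)
        except PipelineError:
            raise
        except Exception as exc:  # pragma: no cover
            raise PipelineError(stage, str(exc)) from exc
    else:
        unmatched = list(results.get("clean", []))

    # ---- novel miRNAs ----------------------------------------------------
    if config.genome_fasta:
        stage = "novel"
        try:
            genome = read_fasta(config.genome_fasta)
            candidates = [r.sequence for r in unmatched
                          if r.total >= config.novel_min_count]
            novel, log = call_novel_mirnas(candidates, genome, config.flank,
                                           config.criteria_thresholds())
            results["novel"] = novel
            results["novel_log"] = log
            with open(out / "novel_candidates.txt", "w") as fh:
                fh.write(_header(config))
                for nv in novel:
                    fh.write(render_candidate(nv) + "\n")
            with open(out / "novel_loci.bed", "w") as fh:
                for nv in novel:
                    for i, c in enumerate(nv.precursors, start=1):
                        suffix = f"-{i}" if len(nv.precursors) > 1 else ""
                        fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{nv.name}{suffix}"
                                 f"\t0\t{c.strand}\n")
            for nv in novel:
                by_read = {r.sequence: r for r in unmatched}
                rec = by_read.get(nv.mature)
                if rec is not None:
                    entry = mirna_counts.setdefault(nv.name, {"control": 0, "chilling": 0})
                    for lib, c in rec.counts.items():
                        entry[lib] = entry.get(lib, 0) + c
                    mirna_seqs.setdefault(nv.name, nv.mature)
        except PipelineError:
            raise
        except Exception as exc:  # pragma: no cover
            raise PipelineError(stage, str(exc)) from exc

    # ---- differential expression ----------------------------------------
    if mirna_counts:
        stage = "diffexp"
        try:
            counts = pd.DataFrame(
                {"control": {m: v.get("control", 0) for m, v in mirna_counts.items()},
                 "chilling": {m: v.get("chilling", 0) for m, v in mirna_counts.items()}})
            de = call_differential(counts, config.p_threshold, config.lfc_threshold,
                                   config.pseudocount)
            _write_tsv(out / "mirna_counts.tsv",
                       counts.rename_axis("mirna_id").reset_index(), config)
            _write_tsv(out / "de_table.tsv", format_de_table(de, mirna_seqs), config)
            results["de"] = de
        except Exception as exc:  # pragma: no cover
            raise PipelineError(stage, str(exc)) from exc

    # ---- degradome -------------------------------------------------------
    if config.degradome_fasta and config.transcriptome_fasta:
        stage = "degradome"
        try:
            transcriptome = read_fasta(config.transcriptome_fasta)
            deg_reads = list(read_fasta(config.degradome_fasta).values())
            tplots, multimapped = map_degradome(deg_reads, transcriptome)
            calls = call_targets(mirna_seqs, transcriptome, tplots,
                                 config.duplex_max_score, config.cleavage_window)
            rows = [{
                "mirna": c.mirna_id, "transcript": c.transcript_id,
                "score": c.alignment.score, "cleavage_pos": c.alignment.cleavage_position,
                "reads": c.reads_at_site, "category": c.category,
            } for c in calls]
            _write_tsv(out / "target_calls.tsv", pd.DataFrame(rows), config)
            tplot_rows = [
                {"transcript": tid, "position": pos, "reads": n}
                for tid in sorted(tplots)
                for pos, n in sorted(tplots[tid].counts.items())
                if any(c.transcript_id == tid for c in calls)
            ]
            _write_tsv(out / "tplots.tsv", pd.DataFrame(tplot_rows), config)
            dist = category_distribution(calls)
            _write_tsv(out / "category_distribution.tsv",
                       pd.DataFrame({"category": list(dist), "targets": list(dist.values())}),
                       config)
            results["targets"] = calls
            results["category_distribution"] = dist
            results["multimapped_degradome_reads"] = multimapped
        except Exception as exc:  # pragma: no cover
            raise PipelineError(stage, str(exc)) from exc

    # ---- qPCR ------------------------------------------------------------
    if config.ct_table:
        stage = "qpcr"
        try:
            table = load_ct_table(config.ct_table)
            qpcr = analyze_ct_table(table, config.qpcr_reference,
                                    config.calibrator, config.treatment)
            _write_tsv(out / "qpcr_results.tsv", qpcr, config)
            results["qpcr"] = qpcr
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    make_report(out, results, config)
    return results


def category_percentages(counts: dict[int, int]) -> dict[int, float]:
    """Per-category percentages with one-decimal rounding."""
    total = sum(counts.values())
    if total == 0:
        return {c: 0.0 for c in counts}
    return {c: round(n / total * 100, 1) for c, n in counts.items()}


def make_report(run_dir: str | Path, results: dict, config: PipelineConfig) -> str:
    """Plain-text summary: accounting, DE list, category distribution, novel
    candidate blocks. Every number is recomputable from the stage TSVs."""
    run_dir = Path(run_dir)
    lines = [_header(config).rstrip(), ""]
    if "accounting" in results:
        lines += ["== Read accounting ==", results["accounting"].to_string(index=False), ""]
    if "de" in results:
        de = results["de"]
        n_up = int((de["call"] == "up").sum())
        n_down = int((de["call"] == "down").sum())
        lines += [f"== Differential expression: {n_down} down, {n_up} up "
                  f"(p ≤ {config.p_threshold}, |log2| ≥ {config.lfc_threshold}) =="]
        sig = de[de["call"].isin(["up", "down"])]
        lines += [format_de_table(sig).to_string(index=False), ""]
    if "category_distribution" in results:
        dist = results["category_distribution"]
        pct = category_percentages(dist)
        lines += ["== Degradome target categories =="]
        lines += [f"category {c}: {dist[c]} ({pct[c]}%)" for c in sorted(dist)]
        lines += [""]
    if "novel" in results:
        lines += [f"== Novel miRNA candidates: {len(results['novel'])} =="]
        for nv in results["novel"]:
            lines += [render_candidate(nv)]
    if "qpcr" in results:
        lines += ["== qPCR relative expression ==",
                  results["qpcr"].to_string(index=False), ""]
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
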