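"""Synthetic-data generators: ground-truth invariants and closed loops."""

import numpy as np
import pandas as pd
import pytest

from soymir.degradome import classify_category, map_degradome
from soymir.diffexpr import call_differential
from soymir.hairpin import evaluate_window
from soymir.io import iter_fastq, revcomp
from soymir.preprocess import collapse_reads, trim_adapter
from soymir.synthetic import (DEFAULT_ADAPTER, GroundTruthManifest,
                              simulate_degradome_library,
                              simulate_genome_with_hairpins,
                              simulate_small_rna_libraries,
                              simulate_transcriptome, set_expression)


@pytest.fixture(scope="module")
def planted():
    genome, manifest = simulate_genome_with_hairpins(6, 30_000, seed=1, n_novel=2)
    set_expression(manifest, 2, de_ids=[manifest.hairpins[2].locus_id])
    return genome, manifest


class TestGenome:
    def test_zero_hairpins_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome_with_hairpins(0, 10_000, seed=1)

    def test_too_small_genome_rejected(self):
        with pytest.raises((ValueError, RuntimeError)):
            simulate_genome_with_hairpins(50, 2_000, seed=1)

    def test_matures_are_substrings_of_their_loci(self, planted):
        genome, manifest = planted
        manifest.validate(genome=genome)  # raises on violation

    def test_single_hairpin_folds_to_stem_loop(self):
        genome, manifest = simulate_genome_with_hairpins(1, 3_000, seed=7)
        h = manifest.hairpins[0]
        locus = genome[h.chrom][h.start:h.end]
        seq = revcomp(locus) if h.strand == "-" else locus
        cand = evaluate_window(h.chrom, h.start, h.end, "+", seq,
                               seq.find(h.mature), len(h.mature))
        assert cand.diagnostics.stem_pairs >= 17

    def test_every_planted_locus_passes_criteria(self, planted):
        genome, manifest = planted
        for h in manifest.hairpins:
            locus = genome[h.chrom][h.start:h.end]
            seq = revcomp(locus) if h.strand == "-" else locus
            offset = seq.find(h.mature)
            assert offset >= 0
            cand = evaluate_window(h.chrom, h.start, h.end, "+", seq,
                                   offset, len(h.mature))
            assert cand.passes, (h.locus_id, cand.criteria, cand.diagnostics)


class TestLibraries:
    def test_depth_floor(self, planted, tmp_path):
        _, manifest = planted
        with pytest.raises(ValueError):
            simulate_small_rna_libraries(manifest, tmp_path / "a", tmp_path / "b",
                                         depth_per_library=10)

    def test_roundtrip_recollapse_equals_truth(self, planted, tmp_path):
        _, manifest = planted
        truth = simulate_small_rna_libraries(
            manifest, tmp_path / "c.fastq", tmp_path / "t.fastq",
            depth_per_library=3000, seed=9)
        pairs = []
        for lib, path in (("control", tmp_path / "c.fastq"),
                          ("chilling", tmp_path / "t.fastq")):
            for read in iter_fastq(path):
                insert, found = trim_adapter(read, DEFAULT_ADAPTER)
                assert found
                pairs.append((insert, lib))
        collapsed = {r.sequence: r.counts for r in collapse_reads(pairs)}
        for _, row in truth.iterrows():
            counts = collapsed.get(row["sequence"], {})
            assert counts.get("control", 0) == row["control"]
            assert counts.get("chilling", 0) == row["chilling"]
        assert sum(truth["control"]) == sum(c.get("control", 0) for c in collapsed.values())

    def test_same_seed_is_byte_identical(self, planted, tmp_path):
        _, manifest = planted
        for tag in ("x", "y"):
            simulate_small_rna_libraries(manifest, tmp_path / f"{tag}c.fastq",
                                         tmp_path / f"{tag}t.fastq",
                                         depth_per_library=2000, seed=4)
        assert (tmp_path / "xc.fastq").read_bytes() == (tmp_path / "yc.fastq").read_bytes()
        assert (tmp_path / "xt.fastq").read_bytes() == (tmp_path / "yt.fastq").read_bytes()

    def test_null_fold_changes_center_log_ratios_on_zero(self, tmp_path):
        genome, manifest = simulate_genome_with_hairpins(10, 40_000, seed=21)
        set_expression(manifest, 22)  # all fold changes 1.0
        truth = simulate_small_rna_libraries(
            manifest, tmp_path / "c.fastq", tmp_path / "t.fastq",
            depth_per_library=30_000, seed=23)
        mir = truth[truth["source"] != "background"]
        log2 = np.log2(mir["chilling"] / mir["control"])
        assert abs(log2.mean()) < 0.2

    def test_fold_change_recovery_sharpens_with_abundance(self, planted, tmp_path):
        """Programmed fold change 4: the DE module's log2 estimate approaches
        2 as counts grow (law of large numbers at three abundance scales)."""
        errors = []
        for scale in (1, 4, 16):
            genome, manifest = simulate_genome_with_hairpins(8, 40_000, seed=31)
            de_id = manifest.hairpins[0].locus_id
            set_expression(manifest, 32, mean_range=(400 * scale, 500 * scale),
                           de_mean_range=(100 * scale, 120 * scale), de_ids=[de_id])
            truth = simulate_small_rna_libraries(
                manifest, tmp_path / f"c{scale}.fastq", tmp_path / f"t{scale}.fastq",
                depth_per_library=2000 * scale, seed=33)
            mir = truth[truth["source"] != "background"]
            counts = pd.DataFrame({"control": mir["control"].to_numpy(),
                                   "chilling": mir["chilling"].to_numpy()},
                                  index=mir["source"])
            de = call_differential(counts).set_index("mirna_id")
            errors.append(abs(de.loc[de_id, "log2_ratio"] - 2.0))
        assert errors[-1] < 0.3
        assert errors[-1] <= errors[0] + 0.05


class TestDegradome:
    @pytest.fixture()
    def targeted(self, planted):
        genome, manifest = planted
        manifest = GroundTruthManifest(hairpins=manifest.hairpins,
                                       abundance=dict(manifest.abundance),
                                       fold_changes=dict(manifest.fold_changes))
        transcriptome = simulate_transcriptome(manifest, seed=41)
        return manifest, transcriptome

    def test_full_signal_yields_category_zero_everywhere(self, targeted):
        manifest, transcriptome = targeted
        reads, truth = simulate_degradome_library(manifest, transcriptome,
                                                  signal_fraction=1.0, seed=42,
                                                  background_reads=0)
        tplots, _ = map_degradome(reads, transcriptome)
        for t in manifest.targets:
            assert classify_category(tplots[t.transcript_id], t.cleavage_pos) == 0

    def test_zero_signal_leaves_sites_weak(self, targeted):
        manifest, transcriptome = targeted
        reads, truth = simulate_degradome_library(manifest, transcriptome,
                                                  signal_fraction=0.0, seed=43,
                                                  background_reads=0)
        tplots, _ = map_degradome(reads, transcriptome)
        cats = []
        for t in manifest.targets:
            tp = tplots[t.transcript_id]
            if tp.counts.get(t.cleavage_pos, 0) >= 1:
                cats.append(classify_category(tp, t.cleavage_pos))
        assert all(c >= 2 for c in cats)

    def test_single_read_at_site_is_category_four(self, targeted):
        manifest, transcriptome = targeted
        t = manifest.targets[0]
        seq = transcriptome[t.transcript_id]
        reads = [seq[t.cleavage_pos - 1:t.cleavage_pos + 19],
                 seq[10:30], seq[10:30], seq[50:70], seq[50:70]]
        tplots, _ = map_degradome(reads, transcriptome)
        assert classify_category(tplots[t.transcript_id], t.cleavage_pos) == 4

    def test_unknown_transcript_rejected(self, targeted):
        manifest, transcriptome = targeted
        manifest.targets[0].transcript_id = "nonexistent"
        with pytest.raises(ValueError):
            simulate_degradome_library(manifest, transcriptome, 1.0, seed=4)

    def test_signal_fraction_bounds(self, targeted):
        manifest, transcriptome = targeted
        with pytest.raises(ValueError):
            simulate_degradome_library(manifest, transcriptome, 1.5, seed=4)


def test_manifest_text_roundtrip(planted, tmp_path):
    _, manifest = planted
    path = tmp_path / "manifest.txt"
    manifest.write(path)
    back = GroundTruthManifest.read(path)
    assert back.abundance == manifest.abundance
    assert back.fold_changes == manifest.fold_changes
    assert [h.__dict__ for h in back.hairpins] == [h.__dict__ for h in manifest.hairpins]
    assert [t.__dict__ for t in back.targets] == [t.__dict__ for t in manifest.targets]


def test_negative_fold_change_rejected(planted):
    _, manifest = planted
    bad = GroundTruthManifest(fold_changes={"x": -2.0})
    with pytest.raises(ValueError):
        bad.validate()
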