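import numpy as np
import pytest

from soymir.pipeline import PipelineConfig, run_pipeline
from soymir.synthetic import simulate_bundle

ANNOTATION_CLASSES = ["rRNA", "tRNA", "snoRNA", "snRNA", "other-Rfam", "repeat", "mRNA"]


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """A small synthetic study bundle shared by the integration tests."""
    out = tmp_path_factory.mktemp("bundle")
    objects = simulate_bundle(out, seed=11, n_hairpins=8, n_novel=2, n_de=4,
                              genome_length=40_000, depth_per_library=12_000,
                              n_targets=5)
    return out, objects


def bundle_config(out, seed=11, run_name="run") -> PipelineConfig:
    return PipelineConfig(
        control_fastq=str(out / "control.fastq"),
        chilling_fastq=str(out / "chilling.fastq"),
        mature_fasta=str(out / "mature_reference.fasta"),
        genome_fasta=str(out / "genome.fasta"),
        transcriptome_fasta=str(out / "transcriptome.fasta"),
        degradome_fasta=str(out / "degradome.fasta"),
        ct_table=str(out / "ct_table.tsv"),
        annotation_fastas={
            cls: str(out / f"ref_{cls.replace('-', '_')}.fasta")
            for cls in ANNOTATION_CLASSES},
        out_dir=str(out / run_name),
        seed=seed,
    )


@pytest.fixture(scope="session")
def pipeline_results(bundle_dir):
    out, objects = bundle_dir
    results = run_pipeline(bundle_config(out))
    return results, objects["manifest"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
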