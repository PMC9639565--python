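import numpy as np
import pytest

from scmscan import pipeline
from scmscan import synthetic_data as sd
from scmscan.gene_model import Transcript


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default synthetic cohort, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("default_ds")
    data = sd.simulate_dataset(sd.SimConfig(), outdir)
    return data, outdir


@pytest.fixture(scope="session")
def default_run(default_dataset):
    """Full pipeline run on the default synthetic cohort."""
    data, outdir = default_dataset
    cfg = pipeline.PipelineConfig(
        genome=str(outdir / "genome.fa"),
        gtf=str(outdir / "annotation.gtf"),
        vcf_dir=str(outdir / "vcf"),
        sam_dir=str(outdir / "sam"),
        out_dir=str(outdir / "out"),
    )
    return data, pipeline.run(cfg)


@pytest.fixture(scope="session")
def quick_dataset(tmp_path_factory):
    """A small cohort for per-module tests."""
    outdir = tmp_path_factory.mktemp("quick_ds")
    cfg = sd.SimConfig(
        n_genes=6,
        n_true_scms=4,
        n_decoy_snvs=2,
        n_individuals=8,
        read_depth=30,
        dropout_rate=0.0,
        carriers_range=(2, 4),
        seed=7,
    )
    data = sd.simulate_dataset(cfg, outdir)
    return data, outdir


@pytest.fixture
def two_exon_plus():
    return Transcript(
        id="T1", gene="G1", chrom="chr1", strand="+",
        exons=[(100, 200), (300, 400)], cds_start=150, cds_end=350,
    )


@pytest.fixture
def two_exon_minus():
    return Transcript(
        id="T2", gene="G2", chrom="chr1", strand="-",
        exons=[(100, 200), (300, 400)], cds_start=150, cds_end=350,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
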