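import numpy as np
import pytest

from tribescope import synthio
from tribescope.formats import UtrAnnotation, UtrRecord


@pytest.fixture(scope="session")
def small_config():
    """A small but non-trivial study configuration shared across tests."""
    return synthio.SimulationConfig(n_genes=40, n_target_genes=6, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    reference, annotation, truth = synthio.gen_reference_and_annotation(small_config)
    return small_config, reference, annotation, truth


@pytest.fixture(scope="session")
def small_sam(tmp_path_factory, small_experiment):
    """agoTRIBE-condition alignments plus reference FASTA on disk."""
    config, reference, annotation, truth = small_experiment
    outdir = tmp_path_factory.mktemp("sam")
    fasta = outdir / "ref.fa"
    sam = outdir / "ago.sam"
    synthio.write_fasta(reference, fasta)
    synthio.gen_bulk_alignments(config, reference, annotation, truth, "agoTRIBE").write_sam(sam)
    return sam, fasta


@pytest.fixture
def toy_annotation():
    """Three hand-built single-interval UTRs on two contigs."""
    return UtrAnnotation([
        UtrRecord("gA", "tA", "chr1", ((100, 300),), "+", "protein_coding"),
        UtrRecord("gB", "tB", "chr1", ((400, 650),), "-", "protein_coding"),
        UtrRecord("gC", "tC", "chr2", ((50, 150),), "+", "retained_intron"),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
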