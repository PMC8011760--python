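import numpy as np
import pytest

from lincberry import synthetic_data as sd
from lincberry.genome_io import GenomicInterval, TranscriptModel


@pytest.fixture(scope="session")
def annotation_and_genome():
    return sd.make_annotation(seed=1, n_chrom=2, n_genes=10)


@pytest.fixture(scope="session")
def planted_fixture(annotation_and_genome):
    ann, genome = annotation_and_genome
    spec = {"LINC": 5, "INTRONIC": 2, "exonAS": 3, "intronAS": 1, "discard": 2}
    transcripts, truth, genome2 = sd.plant_transcripts(ann, genome, spec, seed=1)
    return ann, genome2, transcripts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def simple_transcript():
    """A plain 300-nt noncoding single-exon transcript on the plus strand."""
    seq = sd.noncoding_sequence(np.random.default_rng(42), 300)
    return TranscriptModel(
        "tx1", (GenomicInterval("chr1", 1000, 1300, "+"),), sequence=seq)
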