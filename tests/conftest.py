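import numpy as np
import pytest

from camodark import (
    DuplicationFamily,
    GenomeSequence,
    PlantedVariant,
    SimSpec,
    simulate_genome,
    simulate_reads,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def three_exon_data():
    """Simulated genome/reads for the intra-gene 3-copy family scenario."""
    from camodark.workflow import three_exon_study_spec

    spec = three_exon_study_spec(seed=11)
    genome, transcripts, truth = simulate_genome(spec)
    reads = simulate_reads(genome, truth, spec)
    return spec, genome, transcripts, truth, reads


@pytest.fixture(scope="session")
def two_copy_data():
    """2-copy identical family, no planted variant."""
    spec = SimSpec(
        genome_length=6_000,
        mean_depth=40.0,
        families=(DuplicationFamily(copy_count=2, segment_length=300, identity_pct=100.0),),
        seed=5,
    )
    genome, transcripts, truth = simulate_genome(spec)
    reads = simulate_reads(genome, truth, spec)
    return spec, genome, transcripts, truth, reads


def random_genome(rng: np.random.Generator, n: int, contig: str = "chr1") -> GenomeSequence:
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n).tobytes().decode()
    return GenomeSequence({contig: seq})
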