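import numpy as np
import pytest

from pseudoex.io import (
    AnnotationModel,
    GeneRecord,
    GenomicInterval,
    InMemoryGenome,
    JunctionRecord,
    TranscriptRecord,
)
from pseudoex.simulate import SimulationConfig, simulate_dataset

# The three HTT junctions printed for the worked example: the canonical
# intron spanning the cassette exon and the two flanking inclusion introns,
# all on the plus strand of chr4 (hg38).
HTT_CANONICAL = (3212710, 3213957)
HTT_UPSTREAM = (3212710, 3213621)
HTT_DOWNSTREAM = (3213737, 3213957)
HTT_EXON = (3213622, 3213736)


@pytest.fixture
def htt_junctions():
    return [
        JunctionRecord("chr4", s, e, "+", 20, "s1")
        for s, e in (HTT_CANONICAL, HTT_UPSTREAM, HTT_DOWNSTREAM)
    ]


@pytest.fixture
def htt_annotation():
    """HTT locus annotation with flanking exons but nothing between the
    inclusion junctions."""
    exons = [
        GenomicInterval("chr4", 3212610, 3212709, "+"),
        GenomicInterval("chr4", 3213958, 3214057, "+"),
    ]
    tx = TranscriptRecord("HTT.t1", "HTT", "chr4", "+", exons)
    gene = GeneRecord("HTT", "HTT", "chr4", "+", 3212610, 3214057)
    return AnnotationModel({"HTT": gene}, {"HTT.t1": tx})


@pytest.fixture
def toy_annotation():
    """Two genes: GA (+, two transcripts sharing a partially overlapping
    exon) and GB (-, single transcript)."""
    t1 = TranscriptRecord(
        "GA.t1",
        "GA",
        "chr1",
        "+",
        [GenomicInterval("chr1", 100, 200, "+"), GenomicInterval("chr1", 400, 500, "+")],
    )
    t2 = TranscriptRecord(
        "GA.t2",
        "GA",
        "chr1",
        "+",
        [GenomicInterval("chr1", 150, 250, "+"), GenomicInterval("chr1", 400, 500, "+")],
    )
    t3 = TranscriptRecord(
        "GB.t1",
        "GB",
        "chr1",
        "-",
        [GenomicInterval("chr1", 1000, 1100, "-"), GenomicInterval("chr1", 1300, 1400, "-")],
    )
    genes = {
        "GA": GeneRecord("GA", "GA", "chr1", "+", 100, 500),
        "GB": GeneRecord("GB", "GB", "chr1", "-", 1000, 1400),
    }
    return AnnotationModel(genes, {"GA.t1": t1, "GA.t2": t2, "GB.t1": t3})


@pytest.fixture
def random_genome():
    rng = np.random.default_rng(7)
    return InMemoryGenome(
        {"chr1": "".join(rng.choice(list("ACGT"), size=5000))}
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced simulated cohort shared by read-only tests."""
    cfg = SimulationConfig(seed=11, n_genes=40, n_candidate_sites=80, n_responsive=15)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def washout_dataset():
    cfg = SimulationConfig(
        seed=13,
        n_genes=40,
        n_candidate_sites=80,
        n_responsive=15,
        conditions=("DMSO", "branaplam", "washout"),
        persistent_fraction=0.2,
    )
    return simulate_dataset(cfg)
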