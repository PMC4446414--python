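import numpy as np
import pytest

from seqtu.annotation_io import Gene, GenomeAnnotation
from seqtu.coverage import CoverageTrack
from seqtu.pipeline import run_tu_prediction, simulate_dataset


def make_track(length: int, plus=None, minus=None, genome_id="chr") -> CoverageTrack:
    zero = np.zeros(length, dtype=np.int64)
    return CoverageTrack(
        genome_id=genome_id,
        plus=np.asarray(plus, dtype=np.int64) if plus is not None else zero.copy(),
        minus=np.asarray(minus, dtype=np.int64) if minus is not None else zero.copy(),
    )


def random_annotation(rng, n_genes=20, genome_len=20000, with_sequence=False):
    """Random non-overlapping gene layout on both strands."""
    starts = np.sort(rng.choice(genome_len - 100, size=n_genes, replace=False))
    genes = []
    for i, s in enumerate(starts):
        max_len = (starts[i + 1] - s) if i + 1 < n_genes else genome_len - s
        length = int(rng.integers(20, max(21, min(400, max_len))))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(id=f"g{i}", strand=strand, start=int(s), end=int(s) + length))
    sequence = None
    if with_sequence:
        sequence = "".join(rng.choice(list("ACGT"), size=genome_len))
    return GenomeAnnotation(genome_id="chr", length=genome_len, genes=tuple(genes), sequence=sequence)


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study: ~700 genes, ~0.7 Mb, 100X, seed 17."""
    return simulate_dataset(seed=17)


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full trained pipeline on the default synthetic study."""
    sim = default_sim
    return run_tu_prediction(
        sim.truth.annotation,
        sim.track,
        evidence=sim.evidence,
        mode="illumina_plus_long_read",
        seed=17,
    )
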