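import numpy as np
import pytest

from mthet.io_formats import FORWARD, AlignedRead, MtReference
from mthet.simdata import PlantedVariant, SimConfig, random_reference, simulate_reads


def make_read(
    read_id="r1",
    contig="chrM",
    start=1,
    strand=FORWARD,
    sequence="ACGT",
    quals=None,
    mapq=60,
    aligned_pairs=None,
):
    if quals is None:
        quals = [40] * len(sequence)
    return AlignedRead(
        read_id=read_id,
        contig=contig,
        start=start,
        strand=strand,
        sequence=sequence,
        base_qualities=np.asarray(quals, dtype=np.int16),
        mapq=mapq,
        aligned_pairs=aligned_pairs or [],
    )


@pytest.fixture
def small_ref():
    return random_reference(300, seed=42, name="chrM")


@pytest.fixture
def mid_ref():
    return random_reference(1500, seed=7, name="chrM")


@pytest.fixture
def simulated_sample(mid_ref):
    """A 60x sample with three clearly callable planted heteroplasmies."""
    variants = []
    for pos, frac in [(300, 0.30), (700, 0.25), (1100, 0.20)]:
        ref_base = mid_ref.base(pos)
        minor = "A" if ref_base != "A" else "G"
        variants.append(PlantedVariant(pos, minor, frac))
    cfg = SimConfig(
        seed=11, ref_length=1500, read_length=50, mean_depth=60,
        variants=variants, error_rate=0.001,
    )
    reads, truth = simulate_reads(mid_ref, cfg)
    return reads, truth, cfg
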