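import numpy as np
import pandas as pd
import pytest

from retgnet.cohort import CohortGenotypes
from retgnet.intervals import GenomicInterval, Loop
from retgnet.simulate import SimConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One default planted study shared by read-only tests."""
    return generate_study(SimConfig(seed=7))


@pytest.fixture
def tiny_network():
    """Two genes, one loop each: g1's distal anchor is open, g2's is not."""
    from retgnet.network import build_network, make_promoters, tile_and_classify

    genes = pd.DataFrame(
        {
            "gene": ["g1", "g2"],
            "chrom": ["chr1", "chr1"],
            "start": [10_000, 60_000],
            "end": [30_000, 80_000],
            "strand": ["+", "+"],
            "tss": [10_000, 60_000],
        }
    )
    loops = [
        Loop(GenomicInterval("chr1", 8_000, 13_000),
             GenomicInterval("chr1", 100_000, 105_000), 1e-4),
        Loop(GenomicInterval("chr1", 58_000, 63_000),
             GenomicInterval("chr1", 200_000, 205_000), 1e-3),
    ]
    peaks = [GenomicInterval("chr1", 101_500, 101_900)]
    res = tile_and_classify(loops, peaks)
    promoters = make_promoters(genes)
    return build_network(loops, promoters, res, peaks=peaks), genes


def make_cohort(dosage, labels=None, sex=None, positions=None, chrom="chr1"):
    """Small cohort from a dosage matrix (variants x samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_v, n_s = dosage.shape
    if positions is None:
        positions = list(range(100, 100 + n_v))
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * n_v,
            "pos": positions,
            "ref": ["A"] * n_v,
            "alt": ["C"] * n_v,
        }
    )
    if labels is None:
        labels = ["case"] * (n_s // 2) + ["control"] * (n_s - n_s // 2)
    if sex is None:
        sex = ["M"] * n_s
    return CohortGenotypes(
        samples=[f"s{i}" for i in range(n_s)],
        labels=np.array(labels),
        sex=np.array(sex),
        variants=variants,
        dosage=dosage,
    )
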