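import numpy as np
import pytest

from retromethylmap.copy_catalog import RepeatCopy
from retromethylmap.io_formats import CpGRecord, GenomicInterval
from retromethylmap.synthetic_data import GeneratorConfig, generate_genome, generate_methylomes


def make_copy(chrom="chr1", start=0, end=1000, strand="+", subtype="SVA_A",
              family="SVA", consensus_length=0, is_solo_ltr=False) -> RepeatCopy:
    return RepeatCopy(
        interval=GenomicInterval(chrom, start, end, strand, subtype),
        subtype=subtype,
        family=family,
        consensus_length=consensus_length,
        is_solo_ltr=is_solo_ltr,
    )


def make_cpgs(levels, start=0, spacing=10, depth=10, chrom="chr1"):
    """CpG records at fixed spacing with meth counts level*depth (exact)."""
    recs = []
    for i, lvl in enumerate(levels):
        meth = int(round(lvl * depth))
        recs.append(CpGRecord(chrom, start + i * spacing, meth, depth))
    return recs


@pytest.fixture(scope="session")
def small_fixture():
    """One small generated dataset shared by closure tests."""
    cfg = GeneratorConfig(
        seed=7,
        genome_length=120_000,
        n_copies={"SVA_A": 20, "SVA_D": 15, "L1PA4": 10},
        n_dmrs=2,
    )
    genome, copies, truth = generate_genome(cfg)
    meth1, meth2 = generate_methylomes(truth, cfg, genome)
    return cfg, genome, copies, truth, meth1, meth2


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
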