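import numpy as np
import pytest

import hybridtrace as ht
from hybridtrace.variants_io import GenotypeMatrix, SamplePanel

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##contig=<ID=chr2,length=10000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4\ts5\ts6\ts7
chr1\t100\t.\tC\tT\t.\t.\t.\tGT\t0/0\t0/0\t0/0\t0/1\t1/1\t1/1\t1/1
chr1\t200\t.\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\t0/0\t0/0\t./.\t1/1\t1/1
chr2\t150\t.\tG\tA\t.\t.\t.\tGT\t0|1\t0/0\t0/0\t1/1\t1/1\t1/1\t1/1
"""

TOY_PANELS = {"parentA": ["s1", "s2", "s3"], "parentB": ["s5", "s6", "s7"], "focal": ["s4"]}


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture
def toy_matrix(toy_vcf):
    return ht.read_vcf(toy_vcf, TOY_PANELS)


def make_matrix(records, samples, panels=None):
    """Build a GenotypeMatrix from (chrom, pos, ref, alts, genotypes) tuples.

    ``genotypes`` is a list of per-sample allele-index pairs; ``None``
    marks a missing call.
    """
    chrom, pos, ref, alt, gt = [], [], [], [], []
    for c, p, r, a, g in records:
        chrom.append(c)
        pos.append(p)
        ref.append(r)
        alt.append(tuple(a))
        gt.append([(-1, -1) if pair is None else tuple(sorted(pair)) for pair in g])
    panel_objs = {
        name: SamplePanel(name, tuple(ids)) for name, ids in (panels or {}).items()
    }
    return GenotypeMatrix(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        gt=np.array(gt, dtype=np.int16),
        samples=list(samples),
        panels=panel_objs,
    )


@pytest.fixture(scope="session")
def bc1f1_dataset():
    """One moderately sized BC1F1 simulation shared across tests."""
    cfg = ht.SimConfig(n_chromosomes=3, sites_per_chromosome=2000, seed=42)
    return ht.simulate_dataset(cfg, pedigree="BC1F1")


@pytest.fixture(scope="session")
def clean_bc1f1_dataset():
    """BC1F1 simulation with zero genotype error (truth == observation)."""
    cfg = ht.SimConfig(n_chromosomes=3, sites_per_chromosome=1000, error_rate=0.0, seed=7)
    return ht.simulate_dataset(cfg, pedigree="BC1F1")
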