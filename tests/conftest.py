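import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from balscan.core import HaplotypeMatrix, PopulationPanel, VariantSite
from balscan.simulate import CoalescentConfig, DeepCladeConfig, simulate_deep_clades


def make_matrix(data, coding="ancestral/derived", chrom="chr1", start=100):
    """HaplotypeMatrix from a raw sites x chromosomes 0/1 array."""
    data = np.asarray(data, dtype=np.int8)
    sites = [
        VariantSite(chrom, start + 10 * i, f"rs{i + 1}", "A", "G", ancestral_allele="A")
        for i in range(data.shape[0])
    ]
    samples = [f"s{j // 2}" for j in range(data.shape[1])]
    return HaplotypeMatrix(sites, data, samples, coding=coding)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def deep_clade_scenario():
    """Balanced two-clade locus: 50/50 in EUR, skewed elsewhere, n=100
    chromosomes per group, 20 planted inter-clade differences."""
    cfg = DeepCladeConfig(
        freq_cladeA_per_group={"AFR": 0.2, "EUR": 0.5, "EAS": 0.06},
        n_per_group={"AFR": 100, "EUR": 100, "EAS": 100},
        split_depth=20,
        within_clade=CoalescentConfig(n=2, fixed_S=8),
        locus_length=4000,
        seed=11,
    )
    H, clades, groups = simulate_deep_clades(cfg)
    return cfg, H, clades, groups


@pytest.fixture
def tiny_vcf(tmp_path):
    """Two samples, three phased biallelic SNPs, one multiallelic record,
    one indel, one SNP outside [1000, 1100)."""
    text = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA1\tNA2
chr1\t1001\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1
chr1\t1020\trs2\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1
chr1\t1040\trs3\tG\tA\t.\tPASS\t.\tGT\t1|0\t0|0
chr1\t1060\trs4multi\tG\tA,C\t.\tPASS\t.\tGT\t1|0\t0|2
chr1\t1080\trs5indel\tG\tGA\t.\tPASS\t.\tGT\t0|0\t0|1
chr1\t1200\trs6out\tT\tC\t.\tPASS\t.\tGT\t0|1\t0|0
"""
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    panel = PopulationPanel({"NA1": "P1", "NA2": "P2"}, {"NA1": "EUR", "NA2": "EUR"})
    return path, panel
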