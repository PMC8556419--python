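import numpy as np
import pytest

from introseek import iohub, simulate
from introseek.iohub import (ROLE_AFRICAN, ROLE_OUTGROUP, ROLE_TEST,
                             SitePanel)


def make_panel(alleles, roles_per_hap, positions=None, chrom="1",
               polarized=True, chrom_length=None):
    """Small hand-built panel; alleles is (n_sites, n_hap) of 0/1/-1."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_sites, n_hap = alleles.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    haps = [f"h{i}" for i in range(n_hap)]
    roles = {h: r for h, r in zip(haps, roles_per_hap)}
    panel = SitePanel(chrom=chrom, positions=np.asarray(positions),
                      alleles=alleles, haplotypes=haps, roles=roles,
                      polarized=polarized, chrom_length=chrom_length)
    return iohub.attach_genetic_map(panel)


@pytest.fixture(scope="session")
def small_scenario():
    """A small but non-trivial simulated scenario shared across tests."""
    cfg = simulate.standard_scenario(seed=7, length_bp=5_000_000, n_test=10)
    panel, truth = simulate.simulate_panel(cfg)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def small_pipeline(small_scenario):
    """Polarized panel + decoded segments for the small scenario."""
    from introseek import pipeline
    cfg, panel, truth = small_scenario
    pp = iohub.polarize(panel, "outgroup")
    pp = iohub.attach_genetic_map(pp, simulate.scenario_map(cfg))
    segments, params = pipeline.seek_segments(pp)
    return cfg, pp, truth, segments, params


@pytest.fixture
def toy_vcf(tmp_path):
    """Three diploid samples, five phased biallelic sites, one tri-allelic."""
    text = """##fileformat=VCFv4.2
##contig=<ID=1,length=100000>
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t101\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t0|0\t1|1
1\t202\t.\tC\tT\t.\tPASS\tAA=T\tGT\t0|0\t0|1\t0|0
1\t303\t.\tG\tA\t.\tPASS\tAA=G\tGT\t1|1\t0|0\t0|1
1\t404\t.\tT\tC,G\t.\tPASS\tAA=T\tGT\t0|1\t0|2\t0|0
1\t505\t.\tA\tC\t.\tPASS\tAA=N\tGT\t0|0\t1|0\t0|0
1\t606\t.\tG\tT\t.\tPASS\tAA=G\tGT\t0|1\t1|1\t0|0
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    manifest = {"S1": ROLE_TEST, "S2": ROLE_AFRICAN, "S3": ROLE_OUTGROUP}
    return path, manifest
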