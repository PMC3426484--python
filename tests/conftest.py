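import numpy as np
import pandas as pd
import pytest

from glycoscan.core_io import GroupScheme, HaplotypePanel
from glycoscan.ihs import ihs_scan
from glycoscan.synthetic import SimulationConfig, simulate_panel


def make_panel(haplotypes, positions=None, chromosome="chr1"):
    """Build a HaplotypePanel from a raw 0/1 matrix (rows = haplotypes)."""
    H = np.asarray(haplotypes, dtype=np.int8)
    n_hap, m = H.shape
    assert n_hap % 2 == 0
    if positions is None:
        positions = (np.arange(m) + 1) * 1000
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chromosome": chromosome,
            "position_bp": np.asarray(positions),
            "ancestral_allele": "A",
            "derived_allele": "G",
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"ind{i}" for i in range(n_hap // 2)],
            "population": "POP",
            "continental_group": "G1",
        }
    )
    return HaplotypePanel(H, snps, samples)


def single_group_scheme(panel, group="G1"):
    """A scheme assigning every sample to one group (second label unused)."""
    return GroupScheme([group, "_UNUSED"], {s: group for s in panel.samples["sample_id"]})


@pytest.fixture(scope="session")
def two_group_panel():
    """Two groups differentiated at Wright's F = 0.15; 2,000 SNPs,
    100 haplotypes per group."""
    cfg = SimulationConfig(
        seed=11, n_groups=2, samples_per_group=50, n_snps=2000,
        chromosome_length_bp=20_000_000, wright_F=0.15,
        gene_count=8, background_region_count=20,
    )
    panel = simulate_panel(cfg)
    return panel, GroupScheme.from_samples(panel.samples)


@pytest.fixture(scope="session")
def null_panel():
    """Single undifferentiated deme: 100 haplotypes x 2,000 SNPs."""
    cfg = SimulationConfig(
        seed=3, n_groups=1, samples_per_group=50, n_snps=2000,
        chromosome_length_bp=20_000_000, wright_F=0.0,
        gene_count=8, background_region_count=20,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def neutral_ihs_track(null_panel):
    scheme = single_group_scheme(null_panel)
    return ihs_scan(null_panel, scheme, "G1")


@pytest.fixture(scope="session")
def null_bundle():
    """Full pipeline on a reduced no-sweep study: pathway genes are
    exchangeable with the background, so every significance call is a false
    positive."""
    from glycoscan.pipeline import PipelineConfig, run_full_pipeline
    from glycoscan.synthetic import SimulationConfig

    sim = SimulationConfig(
        seed=29, n_groups=4, samples_per_group=15, n_snps=1500,
        chromosome_length_bp=15_000_000, wright_F=0.10,
        gene_count=12, background_region_count=120,
    )
    cfg = PipelineConfig(simulate=sim, flank_bp=sim.region_flank_bp, snps_per_bin=300, seed=29)
    return run_full_pipeline(cfg)
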