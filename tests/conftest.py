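import numpy as np
import pandas as pd
import pytest

from sweepscan.simulate import SimConfig, simulate_panel
from sweepscan.types import HaplotypeMatrix, VariantTable


def make_variants(positions, chrom="1"):
    return VariantTable(pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(len(positions))],
        "chrom": chrom,
        "pos": list(positions),
        "ref": "A",
        "alt": "G",
    }))


def make_haps(rows, sample_prefix="S"):
    """Haplotype matrix from a list of per-haplotype allele rows."""
    rows = np.asarray(rows, dtype=np.int8)
    n_samples = rows.shape[0] // 2
    return HaplotypeMatrix(rows, [f"{sample_prefix}{k + 1}" for k in range(n_samples)])


@pytest.fixture
def small_panel():
    """Two-population Balding–Nichols panel, 200 SNPs, fixed seed."""
    cfg = SimConfig(n_pops=2, samples_per_pop=(10, 10), pop_labels=("OBJ", "REF"),
                    n_snps=200, chrom_length=5_000_000, divergence_F=0.1, seed=7)
    return simulate_panel(cfg)


@pytest.fixture
def three_pop_panel():
    """Default three-breed-design panel at reduced SNP count."""
    cfg = SimConfig(n_snps=500, chrom_length=10_000_000, seed=11,
                    pop_labels=("MGR", "LNR", "HHG"))
    return simulate_panel(cfg)
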