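import numpy as np
import pandas as pd
import pytest

from rootqtl import SimulationConfig, simulate_panel
from rootqtl.io_model import GenotypeMatrix


@pytest.fixture(scope="session")
def default_panel():
    """Default study-condition panel: 600 cultivated accessions, 5 causal genes."""
    return simulate_panel(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_panel():
    """Light panel for structural tests."""
    cfg = SimulationConfig(
        n_accessions_per_subpop=60,
        n_wild=20,
        n_chromosomes=2,
        chrom_length_bp=600_000,
        n_variants=400,
        n_causal_genes=2,
        seed=11,
    )
    return simulate_panel(cfg)


def make_matrix(dosage, positions=None, chrom="chr1", ref="A", alt="T"):
    """GenotypeMatrix from a plain dosage array (accessions x variants)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": ref,
            "alt": alt,
            "vclass": "SNP",
        },
        index=[f"{chrom}_{p}" for p in positions],
    )
    return GenotypeMatrix(
        accession_ids=[f"acc{i}" for i in range(n)], variants=variants, dosage=dosage
    )
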