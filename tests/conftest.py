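import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from precond.gwas import GenotypePanel
from precond.simulate import SimulationConfig, simulate_panel

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_strains=60, n_variants=300, flies_per_arm=30, seed=11
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_panel(small_config)


def make_panel(dosage: np.ndarray, n_alleles=None) -> GenotypePanel:
    """Hand-built panel around a raw dosage matrix (strains x variants)."""
    n, p = dosage.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(p)],
            "chrom": "2L",
            "pos": 1000 + 500 * np.arange(p),
            "ref": "A",
            "alt": "T",
            "n_alleles": n_alleles if n_alleles is not None else 2,
        }
    )
    return GenotypePanel(
        strains=[f"S{i}" for i in range(n)], variants=variants, dosage=dosage
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
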