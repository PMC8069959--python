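import pandas as pd
import pytest

from imprintguard.config import SimulationConfig


@pytest.fixture
def small_config():
    return SimulationConfig(seed=42, n_genes=6, snps_per_gene=5)


@pytest.fixture
def recovery_config():
    """Deep, dense simulation where planted regimes should be recoverable."""
    return SimulationConfig(
        seed=123,
        n_genes=60,
        snps_per_gene=20,
        annotation_fail_rate=0.0,
        het_fraction=1.0,
        depth_law=("nbinom", {"mean": 60, "dispersion": 10, "min": 30}),
    )


@pytest.fixture
def de_table_example():
    """Hand-built DE table exercising the signature threshold boundaries."""
    return pd.DataFrame(
        {
            "gene": ["up_clear", "q_boundary", "lfc_down_boundary", "down_clear",
                     "null_gene", "up_lfc_boundary"],
            "log2fc": [1.5, 1.5, -0.5, -0.8, 0.1, 1.0],
            "pvalue": [1e-5, 1e-5, 1e-4, 1e-4, 0.8, 1e-5],
            "qvalue": [0.05, 0.1, 0.01, 0.01, 0.9, 0.02],
        }
    )
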