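import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from genotracks import (
    SimulationConfig,
    TrackAesthetics,
    simulate_dataset,
    validate_table,
)


@pytest.fixture
def gwas_df():
    return pd.DataFrame(
        {
            "chromosome": ["1", "1", "2", "2", "10"],
            "position": [10, 500, 40, 90, 7],
            "score": [0.5, 1.3, 2.0, None, 4.0],
        }
    )


@pytest.fixture
def de_df():
    return pd.DataFrame(
        {
            "chromosome": ["1", "1", "2"],
            "start": [100, 300, 50],
            "end": [200, 700, 60],
            "padj": [0.05, 1e-4, None],
            "log2FoldChange": [1.5, -2.0, 0.3],
        }
    )


@pytest.fixture
def candidate_df():
    return pd.DataFrame(
        {
            "chromosome": ["1", "2"],
            "start": [100, 40],
            "end": [200, 40],
            "name": ["GeneA", None],
            "source": ["lit", "lit"],  # extra column, must be preserved
        }
    )


@pytest.fixture
def gwas_table(gwas_df):
    return validate_table(gwas_df, "gwas", label="GWAS")


@pytest.fixture
def de_table(de_df):
    return validate_table(de_df, "de", label="DE")


@pytest.fixture
def candidate_table(candidate_df):
    return validate_table(candidate_df, "candidate", label="CAN")


@pytest.fixture
def custom_aes():
    return {
        "QTL": TrackAesthetics(
            y_label="QTL regions", line_colour="darkgoldenrod", point_shape=18, show_name=True
        ),
        "DMR": TrackAesthetics(
            y_label="Diff. methylated regions",
            line_colour="orchid",
            point_shape=24,
            show_name=False,
            fill_scale="magma",
        ),
    }


@pytest.fixture(scope="session")
def sim_small():
    """A small but complete simulated dataset shared across test modules."""
    return simulate_dataset(
        SimulationConfig(n_markers=3000, n_genes=800, n_polygwas_markers=200, seed=7)
    )
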