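import numpy as np
import pandas as pd
import pytest

from cerna.io_formats import ExpressionMatrix
from cerna.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def demographics_path():
    """The packaged 51-sample demographic table (printed cohort table)."""
    from importlib.resources import files

    return files("cerna").joinpath("data/gse17612_demographics.tsv")


@pytest.fixture(scope="session")
def small_config():
    """A miniature but complete study: fast enough for per-test simulation."""
    return SimulationConfig(
        n_case=10,
        n_control=10,
        n_genes=120,
        n_lncrna=12,
        n_mirna=6,
        n_axes=4,
        n_extra_de_mrna=10,
        n_extra_de_lnc=2,
        n_decoy_interactions=15,
        n_decoy_ppi=10,
        n_gene_sets=5,
        gene_set_size=12,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def two_group_meta():
    """Plain 6+6 metadata frame for matrix-level tests."""
    n = 12
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:02d}" for i in range(n)],
            "source_name": ["Brain BA10 post-mortem schizophrenic"] * 6
            + ["Brain BA10 post-mortem control"] * 6,
            "group": ["schizophrenic"] * 6 + ["control"] * 6,
            "age": np.linspace(30, 90, n),
            "gender": ["male", "female"] * 6,
            "ph": [6.3] * n,
            "pmd_hours": [8.0] * n,
        }
    )


def make_matrix(values, scale="log2", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale)
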