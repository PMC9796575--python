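import numpy as np
import pandas as pd
import pytest

from porescreen.otu import OtuTable
from porescreen.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def table1():
    from porescreen.physics import load_table1

    layers, meta = load_table1()
    return layers


@pytest.fixture
def small_table():
    """Hand-built 4-sample x 5-OTU table with organelle lineages."""
    counts = pd.DataFrame(
        [
            [10, 5, 0, 3, 2],
            [8, 6, 1, 0, 5],
            [12, 2, 2, 4, 0],
            [9, 7, 3, 1, 1],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=["otu1", "otu2", "otu3", "otu4", "otu5"],
    )
    meta = pd.DataFrame(
        {
            "site_id": ["a", "a", "b", "b"],
            "depth_cm": [2.5, 7.5, 2.5, 7.5],
        },
        index=counts.index,
    )
    taxonomy = pd.Series(
        {
            "otu1": "d__Bacteria;p__Proteobacteria;c__Gamma",
            "otu2": "d__Bacteria;p__Chloroflexi;c__Anaerolineae",
            "otu3": "d__Bacteria;p__Cyanobacteria;o__Chloroplast",
            "otu4": "d__Bacteria;p__Proteobacteria;f__Mitochondria",
            "otu5": "Unassigned",
        },
        name="lineage",
    )
    return OtuTable(counts=counts, sample_meta=meta, taxonomy=taxonomy)


@pytest.fixture(scope="session")
def small_dataset():
    """One deterministic small synthetic dataset shared across tests."""
    config = SimConfig(seed=7, n_otus=120, sequencing_depth=20_000)
    return simulate_dataset(config, mixing=0.0)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, n_otus=120, sequencing_depth=20_000)
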