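import numpy as np
import pytest

from rumenet.synthetic import SyntheticConfig, generate_dataset
from rumenet.tables_io import Bloat, CountTable, SampleMetadata, Treatment


@pytest.fixture
def toy_table() -> CountTable:
    counts = np.array(
        [
            [10, 0, 5, 1],
            [3, 7, 0, 2],
            [0, 4, 9, 6],
        ]
    )
    return CountTable(
        sample_ids=["s1", "s2", "s3"],
        taxon_ids=["t1", "t2", "t3", "t4"],
        counts=counts,
        taxonomy=[
            "k__Fungi;p__Neocallimastigomycota;g__Piromyces",
            "k__Fungi;p__Ascomycota;g__X",
            "k__Fungi;p__Neocallimastigomycota;g__Caecomyces",
            "k__Fungi;p__Basidiomycota;g__Y",
        ],
    )


@pytest.fixture
def toy_meta() -> list[SampleMetadata]:
    return [
        SampleMetadata("s1", "S01", 0, Treatment.BASELINE, Bloat.NA),
        SampleMetadata("s2", "S01", 1, Treatment.PA, Bloat.B),
        SampleMetadata("s3", "S02", 1, Treatment.PA, Bloat.NB),
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """A small but full-structure synthetic dataset shared across tests."""
    cfg = SyntheticConfig(
        n_fungal_taxa=12,
        n_offtarget_fungi=3,
        n_bacterial_taxa=30,
        n_hubs=2,
        partners_per_hub=4,
        depth_fungal=(np.log(9000.0), 0.3),
        depth_bacterial=(np.log(30000.0), 0.2),
        seed=7,
    )
    return cfg, generate_dataset(cfg)
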