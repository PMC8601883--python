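import numpy as np
import pytest

from replidepth import (
    ReplicateMetadata,
    SyntheticConfig,
    TaxonTable,
    simulate_experiment,
)


@pytest.fixture
def small_table() -> TaxonTable:
    """4 taxa x 3 replicates with lineage, for parser/aggregation tests."""
    counts = np.array(
        [
            [5, 0, 2],
            [2, 3, 1],
            [0, 1, 0],
            [7, 7, 7],
        ]
    )
    return TaxonTable(
        taxon_ids=["sp1", "sp2", "sp3", "sp4"],
        replicate_ids=["r1", "r2", "r3"],
        counts=counts,
        lineage=[
            "family:Poaceae;genus:Poa;species:Poa annua",
            "family:Poaceae;genus:Festuca",
            "family:Rosaceae",
            "",
        ],
    )


@pytest.fixture
def control_design():
    """24 samples + 4 negative controls + 1 positive control, one extract."""
    rows = [(f"s{i:02d}", "E1", "M1", "sample") for i in range(24)]
    rows += [("ec0", "control", "M1", "extraction_control")]
    rows += [(f"pc{i}", "control", "M1", "pcr_control") for i in range(3)]
    rows += [("pos0", "positive", "M1", "positive_control")]
    return ReplicateMetadata.from_rows(rows)


@pytest.fixture(scope="session")
def mini_experiment():
    """Scaled-down paper-shaped synthetic run shared across tests.

    2 extracts x 12 replicates keeps per-test cost low while preserving
    the control structure and abundance model of the full design.
    """
    cfg = SyntheticConfig(
        n_extracts=2,
        replicates_per_extract=12,
        richness_per_extract=150,
        depth_log_mean=9.5,
        depth_log_sd=0.5,
        depth_min=3000,
        depth_max=60000,
        seed=7,
    )
    table, meta, truth = simulate_experiment(cfg)
    return cfg, table, meta, truth
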