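import warnings

import numpy as np
import pandas as pd
import pytest

from omicnet import (
    OmicsMatrix,
    SampleInfo,
    SimConfig,
    simulate_multiomics,
)

warnings.filterwarnings("ignore", category=UserWarning)


SMALL_SIM = dict(
    seed=11,
    n_kinases=3,
    n_tfs=6,
    n_targets=20,
    n_null_targets=150,
    n_null_phospho=80,
    n_null_proteins=50,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic time course shared across tests."""
    return simulate_multiomics(SimConfig(**SMALL_SIM))


@pytest.fixture()
def two_batch_design():
    """2 batches x (2 samples + 1 reference each), for normalization tests."""
    rows = []
    for b in (1, 2):
        for i, treatment in enumerate(("mock", "treated")):
            rows.append((f"b{b}s{i}", treatment, 15, b, f"batch{b}", f"ch{i}", False))
        rows.append((f"b{b}ref", "reference", 15, b, f"batch{b}", "ch9", True))
    return SampleInfo(
        pd.DataFrame(
            rows,
            columns=[
                "sample_id",
                "treatment",
                "timepoint_min",
                "replicate",
                "batch",
                "channel",
                "is_reference",
            ],
        )
    )


def simple_design(timepoints=(15, 30), replicates=3, batch="b1"):
    """Single-batch design without reference channels."""
    rows = []
    for tp in timepoints:
        for treatment in ("mock", "treated"):
            for rep in range(1, replicates + 1):
                rows.append(
                    (f"t{tp}_{treatment}_{rep}", treatment, tp, rep, batch, "ch", False)
                )
    return SampleInfo(
        pd.DataFrame(
            rows,
            columns=[
                "sample_id",
                "treatment",
                "timepoint_min",
                "replicate",
                "batch",
                "channel",
                "is_reference",
            ],
        )
    )


def matrix_from(values, sample_info, layer="protein", features=None):
    ids = sample_info.sample_ids
    arr = np.asarray(values, dtype=float)
    features = features or [f"f{i+1}" for i in range(arr.shape[0])]
    return OmicsMatrix(layer, pd.DataFrame(arr, index=features, columns=ids[: arr.shape[1]]))
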