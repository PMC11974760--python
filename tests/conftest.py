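import numpy as np
import pandas as pd
import pytest

from repdrift import SimulationConfig, simulate_study
from repdrift.io import add_derived_columns


@pytest.fixture(scope="session")
def default_sim():
    """One 2-subject x 2-timepoint x 6-replicate simulation shared by tests."""
    cfg = SimulationConfig(n_sequences_per_replicate=400, seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_records(default_sim):
    return default_sim[0]


@pytest.fixture(scope="session")
def default_truth(default_sim):
    return default_sim[1]


def make_records(rows):
    """Build a minimal validated repertoire frame from compact row tuples.

    Each row: (v_gene, j_gene, cdrh3_aa[, isotype, v_mut, subject, timepoint,
    replicate, junction_nt]).
    """
    out = []
    for i, row in enumerate(rows):
        v, j, cdrh3 = row[0], row[1], row[2]
        isotype = row[3] if len(row) > 3 else "IgM"
        v_mut = row[4] if len(row) > 4 else 0
        subject = row[5] if len(row) > 5 else "S1"
        timepoint = row[6] if len(row) > 6 else "T1"
        replicate = row[7] if len(row) > 7 else "R1"
        junction_nt = row[8] if len(row) > 8 else ""
        out.append({
            "sequence_id": f"seq{i:04d}",
            "subject": subject, "timepoint": timepoint, "replicate": replicate,
            "v_call": v, "j_call": j,
            "junction": junction_nt,
            "junction_aa": "C" + cdrh3 + "W",
            "isotype": isotype, "v_mutation_count": v_mut, "duplicate_count": 1,
        })
    return add_derived_columns(pd.DataFrame(out))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
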