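import numpy as np
import pandas as pd
import pytest

from metaboclock import (
    AbundanceTable,
    SimulationConfig,
    normalize,
    simulate_metabolome,
)
from metaboclock.tables import make_metadata

#: reduced elastic-net tuning grid used where a test only needs a working
#: clock, not the full-density penalty search
FAST_GRID = dict(l1_ratios=(0.2, 0.5, 0.8, 1.0), n_alphas=20, eps=1e-2)


@pytest.fixture(scope="session")
def study_table():
    """Default study-shaped simulation: 80 samples x 202 metabolites."""
    return simulate_metabolome(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def normalized_small():
    """Smaller normalized table (60 metabolites) for model-fitting tests."""
    table, truth = simulate_metabolome(SimulationConfig(seed=1, n_metabolites=60))
    return normalize(table), truth


def manual_table(values, metadata_rows, stage="raw", metabolites=None):
    """Build an AbundanceTable from plain lists for hand-arithmetic tests."""
    meta = make_metadata(metadata_rows)
    values = np.asarray(values, dtype=float)
    cols = metabolites or [f"met_{j + 1:04d}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=meta.index, columns=cols)
    return AbundanceTable(values=frame, metadata=meta, stage=stage)


def meta_row(i, regime="A", history="long", replicate=None, age=21, batch=1):
    return {
        "sample_id": f"S{i:03d}",
        "regime": regime,
        "history": history,
        "replicate": replicate or f"{regime}-{history}-1",
        "age_days": age,
        "batch": batch,
        "n_pooled": 50,
    }
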