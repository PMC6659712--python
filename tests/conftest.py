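import numpy as np
import pandas as pd
import pytest

from qminet.containers import MFIMatrix
from qminet.synthdata import SimulationDesign, make_panel


@pytest.fixture
def small_panel():
    """3 capture x 4 probe panel: 12 interactions, 3 bead regions."""
    return make_panel(3, 4, seed=42)


@pytest.fixture
def small_design():
    return SimulationDesign(
        n_experiments=2,
        n_replicates=2,
        beads_per_interaction_per_well=100,
        seed=7,
    )


def make_mfi_matrix(values, batch=None, condition=None, replicate=None):
    """MFIMatrix from a 2-D array with minimal sample annotations."""
    values = np.asarray(values, float)
    n_int, n_samp = values.shape
    cols = [f"S{j + 1}" for j in range(n_samp)]
    frame = pd.DataFrame(values, index=[f"I{i + 1}" for i in range(n_int)], columns=cols)
    samples = pd.DataFrame(
        {
            "condition": condition if condition is not None else ["c"] * n_samp,
            "experiment": batch if batch is not None else [1] * n_samp,
            "replicate": replicate if replicate is not None else [1] * n_samp,
        },
        index=pd.Index(cols, name="sample_id"),
    )
    return MFIMatrix(frame, samples)


@pytest.fixture
def mfi_matrix_factory():
    return make_mfi_matrix
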