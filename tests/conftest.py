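import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from utriclemap.quantify import classify_cells
from utriclemap.simulate import SimParams, generate_dataset


@pytest.fixture(scope="session")
def wt_params():
    """Wild-type-like synthetic organ: defaults, fixed seed."""
    return SimParams(seed=11)


@pytest.fixture(scope="session")
def wt_table(wt_params):
    table, _ = generate_dataset(wt_params)
    return table


@pytest.fixture(scope="session")
def wt_classified(wt_table):
    return classify_cells(wt_table)


@pytest.fixture(scope="session")
def rotated_organ():
    """Organ generated at an oblique rotation, classified."""
    table, _ = generate_dataset(SimParams(seed=7, rotation_deg=37.0))
    return classify_cells(table)


def angle_diff_deg(a, b):
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.minimum(d, 360.0 - d)
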