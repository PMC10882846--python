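from pathlib import Path

import numpy as np
import pytest

from stpanel.autocorr import AttributeField
from stpanel.regression import build_design
from stpanel.synthetic import gen_lattice_units, generate_reference_dataset
from stpanel.weights import queen_contiguity, row_standardize

FIXTURE_DIR = Path(__file__).parent / "fixtures" / "reference"


@pytest.fixture(scope="session")
def reference_dataset():
    return generate_reference_dataset()


@pytest.fixture(scope="session")
def reference_design(reference_dataset):
    return build_design(reference_dataset.panel)


@pytest.fixture(scope="session")
def lattice_4x4():
    return gen_lattice_units(4, 4)


@pytest.fixture(scope="session")
def rook_4x4(lattice_4x4):
    return queen_contiguity(lattice_4x4, rook=True)


@pytest.fixture(scope="session")
def lattice_30():
    """The 30-unit study-area lattice with row-standardized queen weights."""
    units = gen_lattice_units(10, 3)
    return units, row_standardize(queen_contiguity(units))


def checkerboard_field(units, wm):
    """±1 alternating by lattice parity, aligned with the weight matrix."""
    parity = {u.unit_id: (int(u.unit_id[1:u.unit_id.index("c")]) + int(u.unit_id.split("c")[1])) % 2
              for u in units}
    x = np.array([parity[uid] * 2.0 - 1.0 for uid in wm.unit_ids])
    return AttributeField(list(wm.unit_ids), x)
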