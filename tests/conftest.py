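import numpy as np
import pytest

from fragscreen.fragmaps import FragMapSet
from fragscreen.grid import GFEGrid, GridSpec
from fragscreen.nmr import PeakAssignment, PeakList


@pytest.fixture
def grid_spec():
    return GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(10, 10, 10))


@pytest.fixture
def single_well_maps(grid_spec):
    """One APOLAR map with a smooth −3 kcal/mol Gaussian well at the center."""
    centers = grid_spec.voxel_centers()
    values = -3.0 * np.exp(
        -np.sum((centers - np.array([5.5, 5.5, 5.5])) ** 2, axis=-1) / (2 * 1.6**2)
    )
    return FragMapSet(
        {"APOLAR": GFEGrid(spec=grid_spec, values=values, map_type="APOLAR")}
    )


def make_peak(residue_index, delta_h=8.2, delta_n=118.0, intensity=100.0,
              chain="A", name="A"):
    return PeakAssignment(
        residue_index=residue_index,
        residue_name=name,
        chain_id=chain,
        delta_H=delta_h,
        delta_N=delta_n,
        intensity=intensity,
    )


@pytest.fixture
def reference_peaklist():
    return PeakList.from_assignments(
        [make_peak(i) for i in range(1, 11)], label="reference"
    )
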