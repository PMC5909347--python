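import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from vascquant import phantoms as ph


@pytest.fixture
def small_tissue_spec():
    """4x4x2 three-class DWI phantom spec, noiseless."""
    tmap = np.zeros((4, 4, 2), dtype=np.uint8)
    tmap[0:2, :, :] = ph.VIABLE
    tmap[2, :, :] = ph.NECROSIS
    tmap[3, :, :] = ph.STROMA
    params = {
        ph.VIABLE: ph.IVIMParams(s0=100.0, f=0.05, d=166e-6, d_star=10e-3),
        ph.NECROSIS: ph.IVIMParams(s0=100.0, f=0.0, d=1695e-6),
        ph.STROMA: ph.IVIMParams(s0=100.0, f=0.2, d=900e-6, d_star=10e-3),
    }
    return ph.DWIPhantomSpec(grid_shape=(4, 4, 2), voxel_spacing=(1.8, 1.8, 1.8),
                             tissue_map=tmap, class_params=params, seed=7)


@pytest.fixture
def mono_stack():
    """Noiseless monoexponential stack factory."""
    def make(d, grid_shape=(3, 3, 2), s0=100.0):
        tmap = np.full(grid_shape, ph.VIABLE, np.uint8)
        spec = ph.DWIPhantomSpec(
            grid_shape=grid_shape, voxel_spacing=(1.8, 1.8, 1.8),
            tissue_map=tmap,
            class_params={ph.VIABLE: ph.IVIMParams(s0=s0, f=0.0, d=d)})
        stack, _ = ph.generate_dwi_phantom(spec)
        return stack
    return make
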