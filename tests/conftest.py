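import numpy as np
import pytest

from othg.core import ImageVolume, LabelVolume
from othg.synthetic import MotionSpec, OpticsSpec, PhantomSpec


@pytest.fixture
def uniform_volume():
    """Uniform-intensity cube, 2 µm isotropic voxels, 60 slices."""
    return ImageVolume(np.full((60, 24, 24), 10.0, dtype=np.float32), (2.0, 2.0, 2.0))


@pytest.fixture
def constant_power_log():
    import pandas as pd
    return pd.DataFrame({"z_um": [0.0, 2000.0], "power_mW": [1.0, 1.0]})


@pytest.fixture
def single_ventricle_spec():
    return PhantomSpec(organoid_radius=100.0, n_ventricles=1,
                       ventricle_radius_range=(30.0, 30.0),
                       vz_shell_thickness=20.0, cp_soma_density=5e3,
                       voxel_size=(2.0, 2.0, 2.0))


@pytest.fixture
def default_optics():
    return OpticsSpec()


def ball_mask(shape, center, radius, voxel_size=(1.0, 1.0, 1.0)):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) * v) ** 2 for g, c, v in zip(grids, center, voxel_size))
    return d2 <= radius ** 2


@pytest.fixture
def digital_ball():
    """Solid ball r = 20 µm at 1 µm isotropic voxels."""
    mask = ball_mask((51, 51, 51), (25, 25, 25), 20.0)
    return LabelVolume(mask.astype(np.int32), (1.0, 1.0, 1.0))
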