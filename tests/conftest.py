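import logging

import numpy as np
import pytest

import susim as s

logging.getLogger("susim").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def phantom():
    return s.make_head_phantom((64, 64, 32), 3.0, seed=1)


@pytest.fixture(scope="session")
def protocol():
    return s.desk_protocol("AP")


@pytest.fixture(scope="session")
def b0_image(phantom, protocol):
    return s.synthesize_dwi_signal(phantom, 0.0, (1, 0, 0), te=protocol.te)


@pytest.fixture(scope="session")
def prepared_field(phantom):
    """The simulation's off-resonance input: dipole solution, fieldmap-style
    preparation (erode/smooth/extrapolate) and brain-mean shim."""
    return s.prepare_susceptibility_field(phantom, b0=3.0)


@pytest.fixture(scope="session")
def bump_field(phantom, protocol):
    """Smooth synthetic field whose displacement is a 2-voxel Gaussian bump."""
    x, y, z = np.meshgrid(*[np.arange(n) for n in phantom.grid_shape], indexing="ij")
    bump = 2.0 * np.exp(
        -(((x - 32) / 14.0) ** 2 + ((y - 40) / 12.0) ** 2 + ((z - 16) / 10.0) ** 2)
    )
    values = bump * protocol.bw_per_pixel / protocol.pe_polarity
    return s.FieldMap(values, phantom.voxel_size)
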