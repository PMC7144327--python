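import numpy as np
import pytest

from trisynapse import io, localize, simulate


@pytest.fixture()
def tiny_table() -> io.LocalizationTable:
    """Three localisations over two channels, hand-written."""
    return io.make_table(
        channel=np.array(["bassoon", "bassoon", "Homer1"], dtype=object),
        frame=np.array([0, 1, 2]),
        xyz=np.array([[0.0, 0.0, 0.0], [100.0, 50.0, -20.0], [120.0, 0.0, 0.0]]),
        photons=np.array([1000.0, 800.0, 1200.0]),
        bg=np.array([5.0, 5.0, 5.0]),
        sigma_xy=np.array([10.0, 10.0, 10.0]),
        sigma_z=np.array([25.0, 25.0, 25.0]),
    )


@pytest.fixture(scope="session")
def small_cfg() -> simulate.SimulationConfig:
    """A desk-scale scene: 6 synapses in a 6 x 6 x 2 um field."""
    return simulate.SimulationConfig(seed=7, n_synapses=6, field_size_nm=(6000.0, 6000.0, 2000.0))


@pytest.fixture(scope="session")
def small_scene(small_cfg):
    return simulate.make_scene(small_cfg)


@pytest.fixture(scope="session")
def small_imaged(small_cfg, small_scene):
    return simulate.image_scene(small_scene, small_cfg)


@pytest.fixture(scope="session")
def bead_calibration() -> tuple[localize.PSFCalibration, simulate.SimulationConfig]:
    """PSF calibration recovered from a simulated bead z-stack (one channel)."""
    cfg = simulate.SimulationConfig(seed=11)
    stacks, _ = simulate.make_bead_stack(cfg, n_beads=4, channels=("GLT1",))
    return localize.calibrate_psf(stacks["GLT1"]), cfg
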