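import numpy as np
import pytest

import magtrack as mt


@pytest.fixture(scope="session")
def array() -> mt.SensorArray:
    return mt.build_array()


@pytest.fixture(scope="session")
def magnet_10x10() -> mt.Magnet:
    return mt.get_magnet("10x10")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


@pytest.fixture()
def ideal_sensor_model() -> mt.SensorModel:
    """Noise-free, effectively unquantised measurement chain."""
    return mt.SensorModel.ideal()


def noiseless_frame(
    array: mt.SensorArray,
    magnet: mt.Magnet,
    pose: mt.Pose,
    geomagnetic: mt.GeomagneticField | None = None,
) -> mt.MeasurementFrame:
    """Exact dipole (+ optional background) readings at the sensors."""
    geo = geomagnetic if geomagnetic is not None else mt.GeomagneticField.zero()
    rng = np.random.default_rng(0)  # unused: the chain below is deterministic
    return mt.simulate_measurement(
        array, mt.SensorModel.ideal(), magnet, pose, geo, rng
    )
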