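import pytest

from mibgcal import build_phantom
from mibgcal.simulate import AcquisitionSettings, simulate_planar

#: Calibration acquisitions in tests run long enough (3600 s at 55.5 MBq)
#: that integer count quantization of the piecewise-constant phantom is
#: negligible (<0.2% per compartment level).
CALIBRATION_SETTINGS = AcquisitionSettings(duration_s=3600.0)


@pytest.fixture(scope="session")
def anterior_map():
    return build_phantom(CALIBRATION_SETTINGS.pixel_mm, "anterior")


@pytest.fixture(scope="session")
def posterior_map():
    return build_phantom(CALIBRATION_SETTINGS.pixel_mm, "posterior")


@pytest.fixture(scope="session")
def ideal_anterior_image(anterior_map):
    """Noise-free rendering through a perfect system (no blur, no haze)."""
    return simulate_planar(anterior_map, None, CALIBRATION_SETTINGS, noise=False)


@pytest.fixture(scope="session")
def ideal_posterior_image(posterior_map):
    return simulate_planar(posterior_map, None, CALIBRATION_SETTINGS, noise=False)
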