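import numpy as np
import pytest

from physarum_morph import phantom
from physarum_morph.imaging_io import ScaleCalibration


@pytest.fixture(scope="session")
def cal10() -> ScaleCalibration:
    """10 µm/px calibration used by most phantom fixtures."""
    return ScaleCalibration(pixel_pitch=10.0, source="fixture")


@pytest.fixture(scope="session")
def vein_phantom():
    """Separated-stroke vein network, width 20 px (200 µm at 10 µm/px)."""
    spec = phantom.PhantomSpec(
        kind="vein_network", shape=(420, 420), seed=11,
        stroke_width_px=20.0, n_branches=4, layout="separated",
        noise_sigma=0.0,
    )
    frame, truth = phantom.make_vein_network(spec)
    return frame, truth, spec


@pytest.fixture(scope="session")
def pulsating_phantom():
    """900-frame pulsating network at Fs = 0.25 Hz, f = 0.010 Hz."""
    spec = phantom.PhantomSpec(
        kind="pulsating_network", shape=(160, 160), seed=4,
        stroke_width_px=14.0, n_branches=2, layout="separated",
        mod_frequency_hz=0.010, mod_amplitude=0.2, fs_hz=0.25,
        n_frames=900, noise_sigma=2.0,
    )
    series, truth = phantom.make_pulsating_series(spec)
    return series, truth


@pytest.fixture(scope="session")
def doubling_disk(cal10):
    """Hard-edged disc whose area exactly doubles over 24 frames (hours)."""
    n = 25
    r0 = 16.0
    k = (r0 * np.sqrt(2) - r0) / (n - 1)
    spec = phantom.PhantomSpec(
        kind="growing_disk", shape=(256, 256), seed=1,
        disk_radius0=r0, disk_growth_px_per_frame=k,
        n_frames=n, interval_s=3600.0, noise_sigma=0.0, antialias=False,
    )
    series, truth = phantom.make_growing_disk_series(spec)
    return series, truth
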