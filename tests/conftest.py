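import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cranioflow.synthetic import AcquisitionSpec, VesselSpec, rasterize_cine
from cranioflow.waveforms import WaveformSpec


@pytest.fixture
def small_acq():
    """Small noise-free blood-plane acquisition for fast fixtures."""
    return AcquisitionSpec(venc=80.0, matrix=(48, 48), cardiac_period=0.9,
                           noise_sigma=0.0, seed=0)


@pytest.fixture
def disk_scene(small_acq):
    """One sinusoidal artery (mean 600 ml/min, amplitude 300) on static
    background, noise-free."""
    vessel = VesselSpec(
        label="ICA_L", center=(24, 24), lumen_area=28.0, direction_sign=-1,
        waveform=WaveformSpec(mean_flow=600.0, pulse_amplitude=300.0),
    )
    stack, truth = rasterize_cine([vessel], small_acq)
    return vessel, stack, truth
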