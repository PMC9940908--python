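import numpy as np
import pytest

from ciliakit import PatchSpec, Recording, SceneSpec, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tone_recording(
    f=25.0, fs=100.0, n=1000, shape=(8, 8), phase=0.0, amplitude=1.0, pixel_size=0.75
):
    """Noise-free single-tone stack: every pixel A*cos(2 pi f t + phase)."""
    t = np.arange(n) / fs
    series = amplitude * np.cos(2 * np.pi * f * t + phase)
    stack = np.broadcast_to(series[:, None, None], (n, *shape)).copy()
    return Recording(stack, frame_rate=fs, pixel_size=pixel_size)


@pytest.fixture
def single_patch_scene():
    """One clean 25 Hz plane-wave patch filling a 64x64 frame."""
    spec = SceneSpec(
        patches=[
            PatchSpec(
                region=(0, 64, 0, 64), frequency=25.0, theta_deg=30.0, wavelength=20.0,
                phase_jitter_sd=0.0,
            )
        ],
        frame_count=1000,
        shape=(64, 64),
        pixel_noise_sd=0.0,
        seed=7,
    )
    return generate_recording(spec, dtype=np.float64)


@pytest.fixture
def two_patch_scene():
    """Two touching patches at 20 and 40 Hz on a noisy background."""
    spec = SceneSpec(
        patches=[
            PatchSpec(region=(4, 34, 4, 34), frequency=20.0, theta_deg=0.0, wavelength=20.0),
            PatchSpec(region=(4, 34, 34, 60), frequency=40.0, theta_deg=90.0, wavelength=10.0),
        ],
        frame_count=1000,
        shape=(64, 64),
        seed=11,
    )
    return generate_recording(spec)
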