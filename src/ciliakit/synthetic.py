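"""Synthetic recordings with known ground truth.

A scene is a set of disjoint oscillating regions ("patches") on a noisy
background.  Each patch oscillates at one frequency with a plane-wave phase
field, so the whole analysis chain - spectra, signal masking, patch
segmentation, coherence, phase gradients - can be exercised against exact
ground truth:

    I(x, t) = B(x) + sum_p 1_p(x) A_p cos(2 pi f_p t + phi_p(x)) + eps(x, t)
    phi_p(x) = wrap(-(k_p . x) + jitter),  k_p = 2 pi/lambda_p (-sin th_p, cos th_p)

With the minus sign, the rendered wave propagates along +k_p, i.e. the
analysis pipeline should report exactly (theta_p, lambda_p).  ``eps`` is
i.i.d. Gaussian pixel noise; the per-pixel static phase jitter models
imperfect local synchrony.  An ``incoherent`` patch re-randomizes its
global phase every Welch-window interval: it keeps high spectral power at
its frequency but is incoherent with any fixed reference - cilia beating at
the same frequency by coincidence.

Defaults follow the imaging conditions the package targets: 100 frames/s,
2000 frames, 128 x 128 pixels at 0.75 um/px (the post-downsampling scale of
a 0.15 um/px acquisition), oscillation amplitude 1 with pixel noise SD 0.2
(amplitude SNR 5) and phase jitter SD 0.2 rad.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Recording
from .lattice import angle_to_wavevector

__all__ = ["PatchSpec", "SceneSpec", "GroundTruth", "generate_recording", "generate_pair"]


@dataclass
class PatchSpec:
    """One oscillating region with plane-wave ground truth.

    ``region`` is either a rectangle (r0, r1, c0, c1) (half-open) or a
    boolean mask of the scene shape.
    """

    region: tuple[int, int, int, int] | np.ndarray
    frequency: float  # Hz
    amplitude: float = 1.0
    theta_deg: float = 0.0
    wavelength: float = 20.0  # um
    phase_jitter_sd: float = 0.2  # rad, static per pixel
    incoherent: bool = False

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        if isinstance(self.region, np.ndarray):
            m = np.asarray(self.region, dtype=bool)
            if m.shape != shape:
                raise ValueError("patch mask does not match scene shape")
            return m
        r0, r1, c0, c1 = self.region
        m = np.zeros(shape, dtype=bool)
        m[r0:r1, c0:c1] = True
        return m


@dataclass
class SceneSpec:
    """Full scene description; the generator is deterministic given ``seed``."""

    patches: list[PatchSpec] = field(default_factory=list)
    frame_count: int = 2000
    frame_rate: float = 100.0
    shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.75  # um/px
    background_level: float = 100.0
    background_noise_sd: float = 0.0  # static spatial variation of the baseline
    pixel_noise_sd: float = 0.2  # temporal i.i.d. noise per pixel-frame
    seed: int = 0
    incoherent_segment: int = 100  # frames between phase re-randomizations

    def validate(self) -> None:
        nyq = self.frame_rate / 2.0
        occupied = np.zeros(self.shape, dtype=bool)
        for p in self.patches:
            if not (15.0 < p.frequency < nyq):
                raise ValueError(
                    f"patch frequency {p.frequency} Hz outside the open band (15, {nyq})"
                )
            if p.wavelength <= 2.0 * self.pixel_size:
                raise ValueError(
                    f"wavelength {p.wavelength} um violates the spatial Nyquist limit "
                    f"(> {2 * self.pixel_size} um)"
                )
            m = p.mask(self.shape)
            if (occupied & m).any():
                raise ValueError("patch regions overlap")
            occupied |= m


@dataclass
class GroundTruth:
    """What the generator actually drew: per-patch table and per-pixel phase."""

    patch_table: pd.DataFrame  # patch, frequency_hz, theta_deg, wavelength_um, n_pixels
    phase: np.ndarray  # rad, NaN outside patches
    labels: np.ndarray  # 0 background, 1..n patches


def _wrap(a: np.ndarray) -> np.ndarray:
    return np.pi - np.mod(np.pi - a, 2.0 * np.pi)


def generate_recording(
    spec: SceneSpec, dtype: np.dtype = np.float32
) -> tuple[Recording, GroundTruth]:
    """Render a scene into a :class:`Recording` plus its ground truth.

    float32 is ample for camera-like data; pass float64 for
    bit-level experiments.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t_frames, (rows, cols) = spec.frame_count, spec.shape
    t = np.arange(t_frames) / spec.frame_rate

    stack = np.empty((t_frames, rows, cols), dtype=dtype)
    baseline = np.full((rows, cols), spec.background_level, dtype=np.float64)
    if spec.background_noise_sd > 0:
        baseline += rng.normal(0.0, spec.background_noise_sd, (rows, cols))
    stack[:] = baseline.astype(dtype)

    labels = np.zeros((rows, cols), dtype=np.int32)
    phase_truth = np.full((rows, cols), np.nan)
    records = []
    yy, xx = np.indices((rows, cols))
    x_um = xx * spec.pixel_size
    y_um = yy * spec.pixel_size

    for i, p in enumerate(spec.patches, start=1):
        m = p.mask((rows, cols))
        k = angle_to_wavevector(p.theta_deg, p.wavelength)
        phi = -(k.kx * x_um + k.ky * y_um)
        if p.phase_jitter_sd > 0:
            phi = phi + rng.normal(0.0, p.phase_jitter_sd, (rows, cols))
        phi = _wrap(phi)
        phase_truth[m] = phi[m]
        labels[m] = i
        records.append(
            {
                "patch": i,
                "frequency_hz": p.frequency,
                "theta_deg": p.theta_deg % 360.0,
                "wavelength_um": p.wavelength,
                "amplitude": p.amplitude,
                "incoherent": p.incoherent,
                "n_pixels": int(m.sum()),
            }
        )
        carrier = np.exp(2j * np.pi * p.frequency * t)
        osc_phase = np.exp(1j * phi[m])
        if p.incoherent:
            # re-randomize the patch's global phase every Welch-length segment
            seg = spec.incoherent_segment
            offsets = rng.uniform(0.0, 2.0 * np.pi, size=(t_frames + seg - 1) // seg)
            carrier = carrier * np.exp(1j * np.repeat(offsets, seg)[:t_frames])
        wave = p.amplitude * np.real(np.outer(carrier, osc_phase))
        flat_idx = np.flatnonzero(m.ravel())
        stack.reshape(t_frames, -1)[:, flat_idx] += wave.astype(dtype)

    if spec.pixel_noise_sd > 0:
        if dtype == np.float32:
            stack += rng.standard_normal(stack.shape, dtype=np.float32) * np.float32(
                spec.pixel_noise_sd
            )
        else:
            stack += rng.normal(0.0, spec.pixel_noise_sd, stack.shape).astype(dtype)

    rec = Recording(
        stack,
        frame_rate=spec.frame_rate,
        pixel_size=spec.pixel_size,
        origin_note=f"synthetic scene (seed={spec.seed})",
    )
    truth = GroundTruth(
        patch_table=pd.DataFrame.from_records(records),
        phase=phase_truth,
        labels=labels,
    )
    return rec, truth


def generate_pair(
    f: float,
    lag: float,
    snr: float,
    n: int,
    fs: float = 100.0,
    seed: int | None = None,
    resample_lag_every: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two unit tones with phase lag ``lag`` plus independent noise.

    ``snr`` is the amplitude signal-to-noise ratio (``np.inf`` for clean
    tones).  With ``resample_lag_every`` set, the lag of the second series
    is re-drawn uniformly every that many samples - a same-frequency pair
    with no fixed phase relation, whose coherence should be low.
    """
    if not (0 < f < fs / 2):
        raise ValueError(f"tone frequency {f} must lie in (0, {fs / 2})")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    x = np.cos(2.0 * np.pi * f * t)
    if resample_lag_every is not None:
        seg = int(resample_lag_every)
        lags = rng.uniform(0.0, 2.0 * np.pi, size=(n + seg - 1) // seg)
        y = np.cos(2.0 * np.pi * f * t + np.repeat(lags, seg)[:n])
    else:
        y = np.cos(2.0 * np.pi * f * t + lag)
    if np.isfinite(snr):
        noise_sd = 1.0 / snr
        x = x + rng.normal(0.0, noise_sd, n)
        y = y + rng.normal(0.0, noise_sd, n)
    return x, y
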