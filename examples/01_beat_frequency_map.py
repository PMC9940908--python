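"""Per-pixel ciliary beat frequency (CBF) map from a synthetic recording.

Builds a 10 s, 64x64 recording with two cilia patches beating at 22 and
37 Hz on a noisy background, computes each pixel's spectrum, takes the
peak frequency in the 15 Hz-Nyquist band, and separates signal from noise
by the local standard deviation of the frequency map.
"""

import numpy as np

from ciliakit import (
    PatchSpec,
    SceneSpec,
    generate_recording,
    peak_frequency_map,
    pixel_spectra,
    signal_mask,
)

scene = SceneSpec(
    patches=[
        PatchSpec(region=(6, 30, 6, 58), frequency=22.0, wavelength=18.0),
        PatchSpec(region=(34, 58, 6, 58), frequency=37.0, wavelength=12.0),
    ],
    frame_count=1000,
    shape=(64, 64),
    seed=0,
)
rec, truth = generate_recording(scene)

spectra = pixel_spectra(rec)
freq_map = peak_frequency_map(spectra)  # 15 Hz .. Nyquist band
mask = signal_mask(freq_map, min_region=400)

signal = mask.values
print(f"recording: {rec.n_frames} frames, {rec.frame_shape}, {rec.frame_rate} Hz")
print(f"signal pixels: {signal.sum()} of {signal.size}")
for label in (1, 2):
    cbf = np.median(freq_map.values[truth.labels == label])
    print(f"patch {label}: median CBF {cbf:.2f} Hz "
          f"(truth {truth.patch_table.loc[label - 1, 'frequency_hz']} Hz)")
noise_rejected = 1.0 - signal[truth.labels == 0].mean()
print(f"background rejected as noise: {100 * noise_rejected:.1f} %")
# The median CBF per patch should match the generated frequency to the FFT
# resolution (0.1 Hz here), and the noise background should be masked out.
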