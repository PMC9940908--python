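"""Metachronal wave direction and wavelength from phase gradients.

Two frequency patches carry traveling plane waves with known direction and
wavelength.  The pipeline segments the CBF map into patches, reads each
pixel's Fourier phase at its patch's dominant frequency, and converts the
phase-gradient field into a per-patch wave direction (degrees from the +y
image axis), circular SD (confidence) and wavelength.
"""

from ciliakit import PatchSpec, RunConfig, SceneSpec, generate_recording, run_pipeline

scene = SceneSpec(
    patches=[
        PatchSpec(region=(4, 34, 4, 34), frequency=20.0, theta_deg=0.0, wavelength=20.0),
        PatchSpec(region=(4, 34, 34, 60), frequency=40.0, theta_deg=90.0, wavelength=10.0),
    ],
    frame_count=1000,
    shape=(64, 64),
    seed=11,
)
rec, truth = generate_recording(scene)

result = run_pipeline(rec, RunConfig(downsample=1, min_region=300))
cols = ["label", "dominant_freq_hz", "n_pixels", "mean_direction_deg", "circular_sd",
        "wavelength_um", "wavelength_mode_um"]
print(result.wave_table[cols].round(3).to_string(index=False))
print("\nground truth:")
print(truth.patch_table[["patch", "frequency_hz", "theta_deg", "wavelength_um"]]
      .to_string(index=False))
# Each recovered direction should be within ~2 degrees and each wavelength
# within ~5 % of the generated values; circular_sd near 0 means the
# gradient field is highly ordered.
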