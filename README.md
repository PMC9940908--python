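# ciliakit

Quantify how motile cilia coordinate across a ciliated epithelium from
high-speed time-lapse microscopy.

Beating cilia modulate transmitted light, so in a ~100 frames/s recording
every pixel carries an intensity time series whose spectrum encodes the
local ciliary beat. `ciliakit` turns such recordings (multi-page grayscale
TIFF plus frame rate and pixel size) into:

- **CBF maps** — the ciliary beat frequency per pixel, the argmax of the
  one-sided Fourier magnitude in a 15 Hz–Nyquist band, with automatic
  signal/noise segmentation (local SD of the frequency map < 3 Hz over a
  3×3 kernel, regions < 500 px removed);
- **synchronization scores** — the magnitude-squared coherence
  C_xy(f) = |P_xy(f)|² / (P_xx(f) P_yy(f)) of pixel pairs, estimated by
  Welch's method (Hamming window 100, overlap 80, nfft 100), which is 1 at
  the beat frequency for phase-locked cilia at *any* fixed lag and small
  for cilia sharing a frequency only by coincidence; reference-pixel
  coherence maps, coherence/power pixel classification, and
  coherence-versus-distance histograms (0.5 µm × 0.04 bins);
- **frequency patches** — connected regions of equal CBF bin (100 bins over
  [0, Nyquist], ~0.5 Hz; 8-connected; ≥ 200 px), the unit at which Fourier
  phase is comparable;
- **metachronal wave fields** — per patch, the Fourier phase φ(x) at the
  patch's dominant frequency, its Prewitt gradient computed on wrapped
  phase differences, and from it the wave direction (circular mean of
  gradient angles, reported as the propagation direction of the crest,
  measured from the +y image axis), the circular SD √(−2 ln R̄) as a
  confidence measure, and the wavelength λ = 2π/|k̄| from the mean gradient
  vector (modal-magnitude estimate reported alongside);
- **a triangular-lattice wave model** — the finite set of traveling waves
  k = 2π/λ (−sin θ, cos θ) compatible with periodic boundary conditions on
  a 16×16 cell of cilia spaced 18 µm apart, plus noisy plane-wave phase
  fields for carpet simulations;
- **a synthetic recording generator** — scenes of disjoint plane-wave
  patches with pixel noise, static phase jitter and "incoherent" patches
  (phase re-randomized per Welch window), providing exact ground truth for
  every stage.

It is a library first (see `examples/`), with a thin `ciliakit` CLI for
shell use (`cbf`, `patch`, `coherence`, `cohdist`, `waves`, `lattice`,
`synth`, `morpho`, `run`).

## Worked example

`examples/04_metachronal_waves.py` renders two frequency patches carrying
known traveling waves and runs the full pipeline:

```text
 label  dominant_freq_hz  n_pixels  mean_direction_deg  circular_sd  wavelength_um  wavelength_mode_um
     1              20.0       900             359.594        0.383         20.006              17.699
     2              40.0       780              89.996        0.170          9.988              10.217

ground truth:
 patch  frequency_hz  theta_deg  wavelength_um
     1          20.0        0.0           20.0
     2          40.0       90.0           10.0
```

Each patch's dominant frequency lands in the generated frequency bin, the
recovered propagation directions (359.6°, 90.0°) are within half a degree
of the generated 0° and 90°, and the wavelengths (20.0, 10.0 µm) within a
fraction of a percent. `circular_sd` near zero says the gradient field is
highly ordered; it grows toward √(−2 ln R̄) ≫ 1 for disordered patches.

The other examples cover CBF mapping (`01`), coherence-based separation of
synchronization from frequency coincidence (`02`), coherence decay with
distance (`03`), the lattice wave set (`05`) and cell-level cilia packing
statistics (`06`); each prints the numbers it computes and a line on what
they mean.

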