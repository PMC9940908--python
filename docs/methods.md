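# Methods

This note records the models, estimators, conventions and numerical
choices behind `ciliakit`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Signal model

A recording is a grayscale stack I(x, t) sampled at frame rate Fs
(~100 Hz) with pixel size h (µm). Cilia sweeping through a pixel modulate
transmitted light, so a cilia-covered pixel is modelled as

    I(x, t) = B(x) + A(x) cos(2π f(x) t + φ(x)) + ε(x, t),

a locally narrow-band oscillation at the ciliary beat frequency (CBF)
f ∈ (15 Hz, Fs/2) riding on a static background with broadband noise ε.
All analyses work on the mean-subtracted per-pixel time series.

## CBF map and signal mask

`pixel_spectra` takes the one-sided DFT of every pixel (DC forced to zero);
`peak_frequency_map` returns the frequency of maximal |X(f)| inside
[f_min, f_max] (defaults 15 Hz, Nyquist), ties broken toward the lowest
frequency so output is deterministic. Mean subtraction exists so the DC
line can never win and so that Parseval bookkeeping in the tests is exact.

Noise pixels draw their peak frequency approximately uniformly from the
band while cilia-covered pixels agree with their neighbours, so signal is
defined by local agreement: a pixel is signal iff some kernel×kernel
window containing it (default 3×3) has a population SD of the CBF map
below 3 Hz. This is implemented as a centered rolling SD, thresholded,
then dilated by the kernel footprint. Border windows are truncated — no
padding values are invented, since zero-padding would fabricate low-SD
borders. Eight-connected signal components smaller than `min_region`
(default 500 px) are discarded. The SD rule is applied on the
(downsampled) analysis grid, so `min_region` counts downsampled pixels.

Spatial downsampling (default block-averaging 5×5) exists for throughput;
it multiplies the effective pixel size accordingly.

## Frequency patches

Fourier phases are only comparable when read at one frequency, and phases
of nearby Fourier modes of a finite series are correlated; therefore phase
is evaluated per *patch*. Peak frequencies are quantized into 100 uniform
bins over [0, Nyquist] (0.5 Hz at Fs = 100; 0.54 Hz at Fs = 108) and
connected components are formed per bin over the signal mask (8-connected
by default, ≥ 200 px). Patches are labelled 1..n in raster order of their
first pixel, so labelling is reproducible. Each patch's *dominant
frequency* is the spectral line maximizing patch-summed power within the
patch's bin — the spectrally dominant reading of "the patch's main
frequency"; on single-tone patches it coincides with the per-pixel mode.

## Coherence

For pixel series x, y the magnitude-squared coherence is

    C_xy(f) = |P_xy(f)|² / (P_xx(f) P_yy(f)),

with Welch-estimated spectra: Hamming taper of length 100 (symmetric),
overlap 80, nfft 100, per-segment mean removal, density scaling. The
number of segments ⌊(N − 80)/20⌋ controls the null level: for independent
signals E[C] ≈ 1/(number of segments), and a single segment gives C ≡ 1,
which is why `msc` rejects inputs that fit fewer than two segments. C is a
normalization-free ratio, so the Welch scaling convention cancels; this is
asserted by test against both a naive segment-loop oracle and an
independent library implementation. Zero-power bins have undefined
coherence and are reported as 0 with a flag. The cross-spectrum convention
is P_xy = ⟨X(f) conj(Y(f))⟩, so arg P_xy at a tone equals the phase
advance of x over y (2π f τ when y lags by τ).

Reference-pixel maps reduce C(f) over the band by its maximum ("peak
coherence"; reduction at the reference CBF line is available as an
option — the two differ only by sub-bin offsets for narrow-band signals).
The companion map `power_at_ref` is the percentage of a pixel's band power
concentrated at the reference pixel's CBF line; a percentage is used
because absolute spectral power depends on illumination and gain.
Pixels are classified against the reference as synchronized
(C ≥ 0.5 and power ≥ 10 %), same-frequency-unsynchronized (C ≤ 0.3 and
power ≥ 25 %), different-frequency (C ≤ 0.5 and power ≤ 25 %), or other,
in that priority order (the boxes touch on measure-zero boundaries).

`coherence_vs_distance` evaluates peak coherence for unordered
signal-pixel pairs and accumulates a 2-D histogram over distance (0.5 µm
bins, post-downsampling pixel size) and coherence (0.04 bins), with the
per-distance-bin mean and the fraction exceeding 0.25. All pairs are used
up to `max_pairs` (default 2×10⁶); beyond that a uniform random subsample
with a fixed seed is drawn, which leaves every per-bin statistic unchanged
in expectation. Pairs are taken globally (not within patches), matching
the all-pairs reading of the distance analysis.

## Phase gradients and wave fields

For each patch, φ(x) is the argument of the complex Fourier coefficient at
the patch's dominant frequency, wrapped to (−π, π]. Under the e^{−i2πft}
transform convention, I = A cos(2πft + φ) yields exactly φ, and a plane
wave propagating along the unit vector u with wavelength λ has
φ(x) = −(2π/λ) u·x + const: crests travel from leading (large φ) to
lagging pixels, i.e. along −∇φ.

The gradient is a Prewitt operator (gain 6, divided out; then divided by
pixel size → rad/µm) evaluated on *wrapped pairwise differences*: each
Prewitt response is a sum of differences across a two-pixel span, and
wrapping every difference to (−π, π] before summing makes the operator
exact on the circle. This is equivalent to the common two-pass scheme
(gradient of φ and of wrap(φ + π), keeping the seam-free estimate)
wherever that scheme is well posed, but remains correct at short
wavelengths (|k| h ≳ 1 rad/px), where the seam-corrupted variant can have
the *smaller* magnitude and a per-pixel min-magnitude rule would select
reversed gradients. Pixels whose 3×3 neighbourhood leaves their patch are
dropped; patches thinner than 3 px therefore yield no gradient and are
flagged.

Per patch:

- **direction** — the circular mean (unit-vector average) of per-pixel
  gradient angles, flipped by 180° to give the propagation direction and
  expressed in the wave-vector convention θ measured from the +y image
  axis (θ = 0 along +y, θ = 90° along −x), matching
  k = 2π/λ (−sin θ, cos θ). Patches with fewer than 10 valid gradient
  pixels, or mean resultant length R̄ ≈ 0, are flagged low-confidence.
- **dispersion** — the circular standard deviation √(−2 ln R̄), invariant
  under global phase offsets; rendered as transparency/confidence.
- **wavelength** — default λ = 2π/|mean gradient vector|. Two reductions
  of the gradient field to one wavenumber are in circulation: the mean
  gradient *vector* length and the *mode* of per-pixel gradient
  magnitudes (histogram bin 0.01 rad/µm, giving λ from 5 µm to a 628 µm
  cap; the zero bin winning means a near-synchronous patch, reported as
  capped). Vector averaging cancels zero-mean per-pixel phase noise,
  whereas any per-pixel magnitude reduction inherits the upward Rice bias
  of |k + noise| — with 0.2 rad static jitter at 0.75 µm/px the gradient
  noise SD is ≈ 0.11 rad/µm per component, which biases the modal estimate
  by >10 % for λ ≥ 20 µm while the vector estimate stays within ~1 %.
  The modal estimate is robust to mixtures (a 70/30 two-wavelength patch
  reports the majority wavelength, not an average) and is reported in a
  separate column; both are available via `wavelength(..., method=...)`.

Coordinates are row-major with the origin top-left, x along columns and y
along rows; all angles are reported in this frame. The propagation-sign
convention is fixed by the generator round-trip test; an analysis code
using the opposite convention would differ by exactly 180°.

## Triangular-lattice wave model

Cilia sit at x_ij = i a1 + j a2 with a1 = a(1, 0), a2 = a(1/2, √3/2),
default a = 18 µm (site density 2/(√3 a²) ≈ 0.0036 µm⁻²) on a 16×16 unit
cell with periodic boundary conditions. Admissible traveling waves are
k = (p/n1) b1 + (q/n2) b2 (reciprocal basis b_i·a_j = 2π δ_ij), reduced
to the first Brillouin zone by minimal |k| over reciprocal translates with
lexicographic tie-breaking — the set of 256 waves is unique; only the
choice of boundary representative is conventional. The set is closed under
the 60° lattice rotation and under k → −k. Noisy phase fields add i.i.d.
N(0, σ²) per site plus a global Uniform[0, 2π) offset to the plane-wave
phases. The effective-stroke axis is mapped to +y so the θ formula applies
verbatim; hydrodynamic couplings, pumping rates and steric limits are out
of scope.

## Synthetic scenes

`generate_recording` renders I(x,t) = B + Σ_p 1_p(x) A_p cos(2π f_p t +
φ_p(x)) + ε with φ_p(x) = wrap(−k_p·x + jitter): the minus sign makes the
rendered wave propagate along +k_p, so the pipeline should report exactly
(θ_p, λ_p). Defaults encode the targeted imaging conditions: 100 frames/s,
2000 frames, 128×128 px at 0.75 µm/px (the post-downsampling scale of a
0.15 µm/px acquisition), amplitude 1 with pixel noise SD 0.2 (amplitude
SNR 5) and static per-pixel phase jitter SD 0.2 rad. "Incoherent" patches
re-randomize a patch-wide phase offset every Welch-window interval
(100 frames), producing the key negative control: full spectral power at a
frequency with no stable phase relation to anything. Stacks are float32 by
default (ample for camera-like data; float64 available); generation is
bit-reproducible given the scene seed per dtype.

What the generator does *not* emulate: optics (cilia shapes, defocus,
motion blur), illumination drift, spatially correlated noise, frequency
drift within a patch, or curved/defected wave fronts. Passing the
recovery suites therefore demonstrates correctness of the estimators under
the stated signal model, not robustness to every experimental artifact.

## Problem sizes in the test suite

Simulation-based suites run at sizes chosen for a single desktop core:
wave-recovery replicates use 64×64 scenes of 1000 frames (320 replicates
across a θ × λ grid at SNR 5, jitter 0.2 rad — recovery tolerances 2° and
5 % are met 20/20 per condition at this size); coherence-classification
scenes use 30 s (3000 frames), the recording length the Welch parameters
are designed for, since with much shorter recordings the few independent
phase blocks make the incoherent patch's peak coherence fluctuate around
the 0.3 classification boundary. Pair subsampling in
coherence-versus-distance is exact (all pairs) at test sizes.

## Known limitations

- Phase is read at one spectral line per patch; patches with strong
  within-patch frequency drift violate the model and show up as high
  circular SD rather than being detected explicitly.
- The wavelength cap (2π/mag_bin) makes "near-synchronous" explicit but
  censors genuinely long wavelengths beyond the cap.
- `coherence_vs_distance` holds all signal-pixel segment spectra in
  memory (complex64); very large masks need a coarser downsampling or a
  smaller band.
- The signal-mask SD rule assumes noise peak frequencies are spatially
  incoherent; structured artifacts (e.g. global flicker at a band
  frequency) would pass it.
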