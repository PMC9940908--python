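import numpy as np
import pytest
from scipy import signal as sps

from ciliakit import (
    CLASS_NAMES,
    WelchSpec,
    classify_pixels,
    coherence_map,
    coherence_vs_distance,
    cross_spectrum,
    generate_pair,
    generate_recording,
    msc,
    welch_psd,
)
from ciliakit.coherence import CoherenceResult
from ciliakit.io import MapImage, Recording
from ciliakit.synthetic import PatchSpec, SceneSpec

SPEC = WelchSpec(window_length=100, overlap=80, n_fft=100, frame_rate=100.0)


def naive_msc(x, y, spec):
    """Independent oracle: explicit segment loop with an O(N^2) DFT."""
    win = np.hamming(spec.window_length)  # symmetric, as the implementation uses
    step = spec.window_length - spec.overlap
    n_seg = (len(x) - spec.overlap) // step
    k = np.arange(spec.n_fft // 2 + 1)
    t = np.arange(spec.n_fft)
    dft = np.exp(-2j * np.pi * np.outer(k, t) / spec.n_fft)
    pxx = pyy = 0.0
    pxy = 0.0
    for s in range(n_seg):
        seg_x = x[s * step : s * step + spec.window_length]
        seg_y = y[s * step : s * step + spec.window_length]
        seg_x = (seg_x - seg_x.mean()) * win
        seg_y = (seg_y - seg_y.mean()) * win
        fx = dft[:, : spec.window_length] @ seg_x
        fy = dft[:, : spec.window_length] @ seg_y
        pxx = pxx + np.abs(fx) ** 2
        pyy = pyy + np.abs(fy) ** 2
        pxy = pxy + fx * np.conj(fy)
    with np.errstate(invalid="ignore"):
        c = np.abs(pxy) ** 2 / (pxx * pyy)
    return np.nan_to_num(c, nan=0.0)


class TestWelch:
    def test_white_noise_density_integrates_to_variance(self, rng):
        x = rng.normal(0, 1.0, 3000)
        f, pxx = welch_psd(x, SPEC)
        assert np.trapezoid(pxx, f) == pytest.approx(x.var(), rel=0.05)

    def test_tone_single_dominant_line(self):
        t = np.arange(3000) / 100.0
        f, pxx = welch_psd(np.cos(2 * np.pi * 25 * t), SPEC)
        assert f[pxx.argmax()] == pytest.approx(25.0)
        assert pxx.max() > 50 * np.median(pxx)

    def test_density_scales_quadratically(self, rng):
        x = rng.normal(size=1000)
        _, p1 = welch_psd(x, SPEC)
        _, p2 = welch_psd(3.0 * x, SPEC)
        np.testing.assert_allclose(p2, 9.0 * p1, rtol=1e-10)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(np.zeros(50), SPEC)


class TestCrossSpectrum:
    def test_self_cross_spectrum_real_nonnegative(self, rng):
        x = rng.normal(size=1000)
        _, pxx = cross_spectrum(x, x, SPEC)
        np.testing.assert_allclose(pxx.imag, 0.0, atol=1e-12)
        assert (pxx.real >= 0).all()

    def test_hermitian_symmetry(self, rng):
        x, y = rng.normal(size=(2, 1000))
        _, pxy = cross_spectrum(x, y, SPEC)
        _, pyx = cross_spectrum(y, x, SPEC)
        np.testing.assert_allclose(pxy, np.conj(pyx), rtol=1e-10)

    def test_lag_phase_of_delayed_tone(self):
        """For y(t) = x(t - tau), arg P_xy at the tone is 2 pi f tau."""
        fs, f, lag_samples = 100.0, 25.0, 3
        t = np.arange(2000) / fs
        x = np.cos(2 * np.pi * f * t)
        y = np.roll(x, lag_samples)  # y(t) = x(t - tau), tau = 3/fs
        freqs, pxy = cross_spectrum(x, y, SPEC)
        measured = np.angle(pxy[freqs == f][0])
        expected = 2 * np.pi * f * lag_samples / fs
        assert measured == pytest.approx(np.angle(np.exp(1j * expected)), abs=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            cross_spectrum(np.zeros(500), np.zeros(400), SPEC)


class TestMsc:
    def test_self_coherence_is_one(self, rng):
        x = rng.normal(size=1000)
        _, c = msc(x, x, SPEC)
        np.testing.assert_allclose(c, 1.0, atol=1e-10)

    def test_bounded_and_symmetric(self, rng):
        x, y = rng.normal(size=(2, 1500))
        _, cxy = msc(x, y, SPEC)
        _, cyx = msc(y, x, SPEC)
        assert (cxy >= 0).all() and (cxy <= 1).all()
        np.testing.assert_allclose(cxy, cyx, atol=1e-12)

    def test_affine_invariance(self, rng):
        x, y = rng.normal(size=(2, 1500))
        _, c1 = msc(x, y, SPEC)
        _, c2 = msc(2.5 * x - 3.0, -0.7 * y + 10.0, SPEC)
        np.testing.assert_allclose(c1, c2, rtol=1e-9)

    def test_lag_invariance_of_identical_tones(self):
        """Synchronization is independent of the phase lag between the two."""
        t = np.arange(3000) / 100.0
        x = np.cos(2 * np.pi * 25 * t)
        values = []
        for lag in (0.0, np.pi / 3, np.pi / 2, 2.9):
            y = np.cos(2 * np.pi * 25 * t + lag)
            freqs, c = msc(x, y, SPEC)
            values.append(c[freqs == 25.0][0])
        np.testing.assert_allclose(values, 1.0, atol=1e-6)

    def test_locked_noisy_tones_highly_coherent(self):
        x, y = generate_pair(f=25.0, lag=np.pi / 3, snr=10.0, n=3000, seed=5)
        freqs, c = msc(x, y, SPEC)
        assert c[freqs == 25.0][0] >= 0.9

    def test_per_segment_random_lag_destroys_coherence(self):
        x, y = generate_pair(f=25.0, lag=0.0, snr=10.0, n=3000, seed=6,
                             resample_lag_every=100)
        freqs, c = msc(x, y, SPEC)
        assert c[freqs == 25.0][0] < 0.3

    def test_independent_noise_mean_coherence_low(self, rng):
        """E[C] ~ 1/n_segments for independent series; band mean stays < 0.2."""
        means = []
        for _ in range(5):
            x, y = rng.normal(size=(2, 3000))
            freqs, c = msc(x, y, SPEC)
            means.append(c[(freqs >= 15) & (freqs <= 50)].mean())
        assert max(means) < 0.2

    def test_matches_naive_oracle(self, rng):
        for _ in range(10):
            x, y = rng.normal(size=(2, 500))
            freqs, c = msc(x, y, SPEC)
            np.testing.assert_allclose(c, naive_msc(x, y, SPEC), atol=1e-8)

    def test_matches_scipy_coherence(self, rng):
        """Independent cross-check against scipy's reference implementation."""
        x, y = rng.normal(size=(2, 2000))
        freqs, c = msc(x, y, SPEC)
        f2, c2 = sps.coherence(
            x, y, fs=100.0, window=sps.windows.hamming(100, sym=True),
            noverlap=80, nfft=100,
        )
        np.testing.assert_allclose(c, c2, atol=1e-10)

    def test_single_segment_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            msc(np.zeros(100), np.zeros(100), SPEC)

    def test_zero_power_bins_flagged_as_zero(self):
        t = np.arange(1000) / 100.0
        x = np.cos(2 * np.pi * 25 * t)
        freqs, c, undefined = msc(x, x, SPEC, return_flags=True)
        assert not undefined[freqs == 25.0][0]
        assert (c[undefined] == 0).all()


@pytest.fixture(scope="module")
def incoherent_scene():
    spec = SceneSpec(
        patches=[
            PatchSpec(region=(0, 64, 0, 28), frequency=25.0, wavelength=20.0),
            PatchSpec(region=(0, 64, 36, 64), frequency=25.0, wavelength=20.0,
                      incoherent=True),
        ],
        frame_count=1500, shape=(64, 64), seed=3,
    )
    return generate_recording(spec)


class TestCoherenceMap:
    def test_reference_pixel_is_one(self, incoherent_scene):
        rec, _ = incoherent_scene
        res = coherence_map(rec, (32, 10), spec=WelchSpec(frame_rate=rec.frame_rate))
        assert res.peak_coherence.values[32, 10] == pytest.approx(1.0, abs=1e-9)

    def test_coherent_patch_high_background_low(self, incoherent_scene):
        rec, truth = incoherent_scene
        res = coherence_map(rec, (32, 10), spec=WelchSpec(frame_rate=rec.frame_rate))
        c = res.peak_coherence.values
        assert c[truth.labels == 1].mean() >= 0.9
        assert c[truth.labels == 0].mean() < 0.2

    def test_same_frequency_incoherent_patch(self, incoherent_scene):
        """Cilia can beat at the same frequency by coincidence: high spectral
        power at the reference CBF but low coherence."""
        rec, truth = incoherent_scene
        res = coherence_map(rec, (32, 10), spec=WelchSpec(frame_rate=rec.frame_rate))
        other = truth.labels == 2
        assert res.reference_cbf == pytest.approx(25.0)
        assert res.power_at_ref.values[other].mean() >= 25.0
        assert res.peak_coherence.values[other].mean() <= 0.3

    def test_reference_outside_mask_rejected(self, incoherent_scene):
        rec, truth = incoherent_scene
        with pytest.raises(ValueError, match="reference"):
            coherence_map(rec, (32, 10), mask=truth.labels == 2,
                          spec=WelchSpec(frame_rate=rec.frame_rate))


def _result(c, p):
    m = MapImage(values=np.array([[c]]), units="dimensionless", pixel_size=1.0)
    pw = MapImage(values=np.array([[p]]), units="%", pixel_size=1.0)
    return CoherenceResult(peak_coherence=m, power_at_ref=pw, reference=(0, 0),
                           reference_cbf=25.0, band=(15.0, 50.0))


@pytest.mark.parametrize(
    "c,p,expected",
    [
        (0.9, 40.0, "synchronized"),
        (0.1, 30.0, "same_freq_unsynchronized"),
        (0.2, 10.0, "different_freq"),
        (0.4, 18.0, "different_freq"),  # inside the green box (C<=0.5, power<=25)
        (0.4, 30.0, "other"),  # between blue and red in coherence, too much power for green
    ],
)
def test_classification_thresholds(c, p, expected):
    classes = classify_pixels(_result(c, p))
    assert CLASS_NAMES[int(classes.values[0, 0])] == expected


class TestCoherenceVsDistance:
    def test_identical_series_fully_coherent(self, rng):
        series = rng.normal(size=500)
        stack = np.broadcast_to(series[:, None, None], (500, 5, 5)).copy()
        rec = Recording(stack, frame_rate=100.0, pixel_size=0.75)
        hist = coherence_vs_distance(rec, spec=SPEC)
        occupied = ~np.isnan(hist.mean_per_distance)
        np.testing.assert_allclose(hist.mean_per_distance[occupied], 1.0, atol=1e-9)
        np.testing.assert_allclose(hist.fraction_above_threshold[occupied], 1.0)

    def test_histogram_counts_every_sampled_pair(self, rng):
        rec = Recording(rng.normal(size=(400, 6, 6)), frame_rate=100.0, pixel_size=0.75)
        hist = coherence_vs_distance(rec, spec=SPEC)
        n_pix = 36
        assert hist.n_pairs == n_pix * (n_pix - 1) // 2  # all pairs, (i, i) excluded
        assert hist.counts.sum() == hist.n_pairs

    def test_subsampling_is_seeded(self, rng):
        rec = Recording(rng.normal(size=(300, 10, 10)), frame_rate=100.0, pixel_size=0.75)
        h1 = coherence_vs_distance(rec, spec=SPEC, max_pairs=500, seed=9)
        h2 = coherence_vs_distance(rec, spec=SPEC, max_pairs=500, seed=9)
        np.testing.assert_array_equal(h1.counts, h2.counts)

    def test_coherent_patch_decays_beyond_patch_scale(self):
        """A 15 um coherent patch in an incoherent surround: mean coherence is
        high below the patch size and drops beyond it."""
        patch = PatchSpec(region=(6, 26, 6, 26), frequency=25.0, wavelength=30.0)
        spec = SceneSpec(patches=[patch], frame_count=1200, shape=(32, 32),
                         pixel_size=0.75, seed=21)
        rec, truth = generate_recording(spec)
        hist = coherence_vs_distance(rec, spec=WelchSpec(frame_rate=100.0))
        centers = hist.distance_centers
        near = hist.mean_per_distance[(centers > 1) & (centers < 10)]
        far = hist.mean_per_distance[(centers > 25)]
        assert np.nanmean(near) > 2 * np.nanmean(far)

    def test_too_few_pixels_rejected(self, rng):
        rec = Recording(rng.normal(size=(300, 4, 4)), frame_rate=100.0, pixel_size=0.75)
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        with pytest.raises(ValueError, match="2 signal pixels"):
            coherence_vs_distance(rec, mask=mask, spec=SPEC)
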