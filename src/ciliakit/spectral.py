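"""Per-pixel Fourier analysis: CBF maps and the signal/noise mask.

Each pixel's intensity time series is transformed once (one-sided DFT of the
mean-subtracted series); the ciliary beat frequency (CBF) of a pixel is the
frequency of maximal spectral magnitude within a search band, by default
15 Hz to Nyquist.  Because noise pixels draw their peak frequency roughly
uniformly from the band while cilia-covered pixels agree with their
neighbours, a low local standard deviation of the CBF map identifies signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import MapImage, Recording

__all__ = [
    "PixelSpectra",
    "FrequencyMap",
    "downsample_stack",
    "pixel_spectra",
    "peak_frequency_map",
    "signal_mask",
]


@dataclass
class PixelSpectra:
    """One-sided DFT of every pixel's mean-subtracted intensity series.

    ``coefficients`` has shape (n_freq, rows, cols) with
    ``n_freq = n_frames // 2 + 1``; ``freqs`` spans 0..frame_rate/2.
    """

    coefficients: np.ndarray
    freqs: np.ndarray
    frame_rate: float
    pixel_size: float

    def __post_init__(self) -> None:
        if self.coefficients.shape[0] != self.freqs.shape[0]:
            raise ValueError("coefficients and frequency axis disagree")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency axis must be strictly increasing")

    @property
    def n_freq(self) -> int:
        return self.freqs.shape[0]

    def freq_index(self, f: float) -> int:
        """Index of the spectral line closest to frequency ``f`` (Hz)."""
        return int(np.argmin(np.abs(self.freqs - f)))


@dataclass
class FrequencyMap(MapImage):
    """Peak-frequency (CBF) map in Hz with the search band that produced it."""

    band: tuple[float, float] = (0.0, np.inf)
    frame_rate: float = 0.0


def downsample_stack(rec: Recording, factor: int = 5) -> Recording:
    """Spatially downsample each frame by block-averaging factor x factor blocks.

    Trailing rows/columns that do not fill a block are dropped.  The time
    axis is untouched and the pixel size is multiplied by ``factor``.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"downsampling factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return rec
    t, r, c = rec.stack.shape
    if r < factor or c < factor:
        raise ValueError(f"frame {r}x{c} smaller than block size {factor}")
    rr, cc = r // factor, c // factor
    cropped = rec.stack[:, : rr * factor, : cc * factor]
    down = cropped.reshape(t, rr, factor, cc, factor).mean(axis=(2, 4))
    return Recording(
        down,
        frame_rate=rec.frame_rate,
        pixel_size=rec.pixel_size * factor,
        origin_note=rec.origin_note,
    )


def pixel_spectra(rec: Recording, min_frames: int = 200) -> PixelSpectra:
    """One-sided DFT of the mean-subtracted time series of every pixel.

    Mean subtraction zeroes the DC line so that it can never win the peak
    search and so that Parseval bookkeeping is exact; the coefficient at
    frequency 0 is set to zero by construction.
    """
    if rec.n_frames < min_frames:
        raise ValueError(
            f"need at least {min_frames} frames for spectral analysis, got {rec.n_frames}"
        )
    x = rec.stack - rec.stack.mean(axis=0, keepdims=True)
    coeff = np.fft.rfft(x, axis=0)
    coeff[0] = 0.0
    freqs = np.fft.rfftfreq(rec.n_frames, d=1.0 / rec.frame_rate)
    return PixelSpectra(
        coefficients=coeff,
        freqs=freqs,
        frame_rate=rec.frame_rate,
        pixel_size=rec.pixel_size,
    )


def peak_frequency_map(
    spectra: PixelSpectra, f_min: float = 15.0, f_max: float | None = None
) -> FrequencyMap:
    """Per-pixel frequency of maximal |DFT| within [f_min, f_max].

    Ties are broken toward the lowest frequency for deterministic output.
    The returned mask is all-true; signal/noise discrimination is a separate
    step (:func:`signal_mask`).
    """
    nyquist = spectra.frame_rate / 2.0
    if f_max is None:
        f_max = nyquist
    if not (f_min < f_max <= nyquist + 1e-12):
        raise ValueError(f"invalid band [{f_min}, {f_max}] for Nyquist {nyquist}")
    in_band = (spectra.freqs >= f_min) & (spectra.freqs <= f_max)
    if not in_band.any():
        raise ValueError(f"band [{f_min}, {f_max}] contains no spectral line")
    band_freqs = spectra.freqs[in_band]
    mag = np.abs(spectra.coefficients[in_band])
    # argmax returns the first (= lowest-frequency) maximum
    peak = band_freqs[np.argmax(mag, axis=0)]
    return FrequencyMap(
        values=peak,
        units="Hz",
        pixel_size=spectra.pixel_size,
        mask=np.ones(peak.shape, dtype=bool),
        band=(f_min, f_max),
        frame_rate=spectra.frame_rate,
    )


def _windowed_sd(values: np.ndarray, kernel: int) -> np.ndarray:
    """Population SD over each kernel x kernel window, truncated at borders.

    Border windows use only the pixels that exist; no padding values are
    invented, so low-SD borders cannot be fabricated.
    """
    ones = np.ones(values.shape)
    footprint = np.ones((kernel, kernel))
    count = ndimage.correlate(ones, footprint, mode="constant", cval=0.0)
    s1 = ndimage.correlate(values, footprint, mode="constant", cval=0.0)
    s2 = ndimage.correlate(values * values, footprint, mode="constant", cval=0.0)
    var = s2 / count - (s1 / count) ** 2
    return np.sqrt(np.maximum(var, 0.0))


def signal_mask(
    freq_map: FrequencyMap,
    kernel: int = 3,
    sd_threshold: float = 3.0,
    min_region: int = 500,
) -> MapImage:
    """Classify pixels as signal when they belong to a locally uniform CBF area.

    A pixel is signal iff at least one kernel x kernel window containing it
    has a population standard deviation of peak frequency below
    ``sd_threshold`` (window semantics: threshold the centered rolling SD,
    then dilate by the kernel footprint).  Eight-connected signal components
    with fewer than ``min_region`` pixels are then removed as specks.
    """
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError(f"kernel must be an odd integer >= 3, got {kernel}")
    values = np.asarray(freq_map.values, dtype=np.float64)
    if not np.isfinite(values).all():
        raise ValueError("frequency map contains non-finite values")
    low_sd_center = _windowed_sd(values, kernel) < sd_threshold
    signal = ndimage.binary_dilation(low_sd_center, structure=np.ones((kernel, kernel), bool))
    labels, n = ndimage.label(signal, structure=np.ones((3, 3), int))
    if n:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_region
        keep[0] = False
        signal = keep[labels]
    return MapImage(
        values=signal,
        units="bool",
        pixel_size=freq_map.pixel_size,
        mask=np.ones(signal.shape, dtype=bool),
    )
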