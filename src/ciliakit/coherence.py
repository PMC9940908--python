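"""Pairwise synchronization via magnitude-squared coherence.

Two cilia are synchronized when they keep a fixed phase relation, not merely
the same frequency.  The magnitude-squared coherence

    C_xy(f) = |P_xy(f)|^2 / (P_xx(f) P_yy(f))

of two pixel intensity series measures exactly this: it reaches 1 at the
beat frequency for a fixed phase lag of any size, and averages toward
1/(number of Welch segments) for independent signals.  Spectra are estimated
by Welch's method (Hamming taper, segment length 100, overlap 80, 100-point
FFT by default), which is what makes the estimate informative: a
single-segment coherence is identically 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import MapImage, Recording

__all__ = [
    "WelchSpec",
    "CoherenceResult",
    "CoherenceDistanceHistogram",
    "welch_psd",
    "cross_spectrum",
    "msc",
    "coherence_map",
    "classify_pixels",
    "coherence_vs_distance",
    "CLASS_NAMES",
]

CLASS_NAMES = {
    0: "other",
    1: "synchronized",
    2: "same_freq_unsynchronized",
    3: "different_freq",
}


@dataclass
class WelchSpec:
    """Welch estimation parameters (Hamming taper)."""

    window_length: int = 100
    overlap: int = 80
    n_fft: int = 100
    frame_rate: float = 100.0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < self.window_length <= self.n_fft):
            raise ValueError(
                f"need 0 <= overlap < window_length <= n_fft, got "
                f"{self.overlap}/{self.window_length}/{self.n_fft}"
            )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def step(self) -> int:
        return self.window_length - self.overlap

    def n_segments(self, n_samples: int) -> int:
        return (n_samples - self.overlap) // self.step

    @property
    def window(self) -> np.ndarray:
        return sps.windows.hamming(self.window_length, sym=True)

    @property
    def freqs(self) -> np.ndarray:
        return np.fft.rfftfreq(self.n_fft, d=1.0 / self.frame_rate)


def _check_lengths(spec: WelchSpec, *series: np.ndarray) -> int:
    lengths = {len(x) for x in series}
    if len(lengths) != 1:
        raise ValueError(f"series lengths differ: {sorted(lengths)}")
    (n,) = lengths
    if n < spec.window_length:
        raise ValueError(f"series of length {n} shorter than one window ({spec.window_length})")
    return n


def welch_psd(x: np.ndarray, spec: WelchSpec) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density (density scaling), Hz and power/Hz."""
    _check_lengths(spec, x)
    return sps.welch(
        np.asarray(x, dtype=np.float64),
        fs=spec.frame_rate,
        window=spec.window,
        noverlap=spec.overlap,
        nfft=spec.n_fft,
        detrend="constant",
        scaling="density",
    )


def cross_spectrum(x: np.ndarray, y: np.ndarray, spec: WelchSpec) -> tuple[np.ndarray, np.ndarray]:
    """Segment-averaged cross-spectral density ``P_xy = <X(f) conj(Y(f))>``.

    With this convention ``arg P_xy`` at a tone equals the phase advance of
    x over y, i.e. ``2 pi f tau`` when ``y(t) = x(t - tau)``.
    """
    _check_lengths(spec, x, y)
    freqs, pxy = sps.csd(
        np.asarray(x, dtype=np.float64),
        np.asarray(y, dtype=np.float64),
        fs=spec.frame_rate,
        window=spec.window,
        noverlap=spec.overlap,
        nfft=spec.n_fft,
        detrend="constant",
        scaling="density",
    )
    # scipy averages conj(X) Y; flip to X conj(Y)
    return freqs, np.conj(pxy)


def msc(
    x: np.ndarray,
    y: np.ndarray,
    spec: WelchSpec,
    return_flags: bool = False,
):
    """Magnitude-squared coherence ``C_xy(f) = |P_xy|^2 / (P_xx P_yy)``.

    Requires at least two Welch segments; with a single segment the ratio is
    identically 1 and carries no information, so such input is rejected.
    Frequency bins where either series has zero power have undefined
    coherence; they are reported as 0 and flagged.

    Returns ``(freqs, C)`` or ``(freqs, C, undefined_flags)``.
    """
    n = _check_lengths(spec, x, y)
    if spec.n_segments(n) < 2:
        raise ValueError(
            f"{spec.n_segments(n)} Welch segment(s) fit {n} samples; at least 2 are "
            "required for a meaningful coherence estimate"
        )
    freqs, pxx = welch_psd(x, spec)
    _, pyy = welch_psd(y, spec)
    _, pxy = cross_spectrum(x, y, spec)
    denom = pxx * pyy
    undefined = denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.abs(pxy) ** 2 / denom
    c = np.where(undefined, 0.0, c)
    c = np.clip(c, 0.0, 1.0)
    if return_flags:
        return freqs, c, undefined
    return freqs, c


# ---------------------------------------------------------------------------
# vectorized Welch core for whole-image maps
# ---------------------------------------------------------------------------


def _segment_rfft(x: np.ndarray, spec: WelchSpec) -> np.ndarray:
    """Tapered, per-segment-demeaned segment rFFTs of columns of ``x``.

    ``x`` has shape (n_samples, n_pixels); the result has shape
    (n_segments, n_rfft, n_pixels), complex64.
    """
    n = x.shape[0]
    n_seg = spec.n_segments(n)
    if n_seg < 2:
        raise ValueError("need at least 2 Welch segments")
    win = spec.window.astype(np.float32)
    segs = np.lib.stride_tricks.sliding_window_view(x, spec.window_length, axis=0)
    segs = segs[:: spec.step][:n_seg]  # (n_seg, n_pix, wl)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    tapered = segs.astype(np.float32) * win
    spec_fft = np.fft.rfft(tapered, n=spec.n_fft, axis=-1).astype(np.complex64)
    return np.transpose(spec_fft, (0, 2, 1))


@dataclass
class CoherenceResult:
    """Reference-pixel coherence and spectral-power maps."""

    peak_coherence: MapImage
    power_at_ref: MapImage  # percent of each pixel's band power at the reference CBF
    reference: tuple[int, int]
    reference_cbf: float
    band: tuple[float, float]


def coherence_map(
    rec: Recording,
    reference: tuple[int, int],
    mask: MapImage | np.ndarray | None = None,
    spec: WelchSpec | None = None,
    band: tuple[float, float | None] = (15.0, None),
    reduction: str = "peak",
) -> CoherenceResult:
    """Coherence of one reference pixel with every masked pixel.

    Per masked pixel the map holds the maximum of C_ref,pixel(f) over the
    band (``reduction="peak"``) or C at the reference pixel's CBF line
    (``reduction="at_ref_cbf"``).  ``power_at_ref`` is 100 x the pixel's
    Welch power at the reference CBF line divided by the pixel's total band
    power; synchronized neighbours show both high coherence and high power,
    while cilia beating at the reference frequency only by coincidence show
    high power but low coherence.
    """
    if spec is None:
        spec = WelchSpec(frame_rate=rec.frame_rate)
    if reduction not in ("peak", "at_ref_cbf"):
        raise ValueError(f"unknown reduction {reduction!r}")
    rows, cols = rec.frame_shape
    mask_arr = (
        np.ones((rows, cols), bool)
        if mask is None
        else np.asarray(getattr(mask, "values", mask), bool)
    )
    r0, c0 = reference
    if not (0 <= r0 < rows and 0 <= c0 < cols) or not mask_arr[r0, c0]:
        raise ValueError(f"reference pixel {reference} is outside the mask")

    f_min, f_max = band
    if f_max is None:
        f_max = rec.nyquist
    freqs = spec.freqs
    in_band = (freqs >= f_min) & (freqs <= f_max)
    if not in_band.any():
        raise ValueError(f"band [{f_min}, {f_max}] contains no Welch line")

    flat = rec.stack.reshape(rec.n_frames, -1)
    idx = np.flatnonzero(mask_arr.ravel())
    ref_flat = r0 * cols + c0

    seg_ref = _segment_rfft(flat[:, [ref_flat]], spec)[:, :, 0]  # (n_seg, n_rfft)
    pxx_ref = np.mean(np.abs(seg_ref) ** 2, axis=0)
    ref_band_idx = np.flatnonzero(in_band)
    f_ref_idx = int(ref_band_idx[np.argmax(pxx_ref[in_band])])
    reference_cbf = float(freqs[f_ref_idx])

    peak = np.full((rows, cols), np.nan)
    power = np.full((rows, cols), np.nan)
    chunk = 4096
    for start in range(0, idx.size, chunk):
        sel = idx[start : start + chunk]
        seg = _segment_rfft(flat[:, sel], spec)  # (n_seg, n_rfft, p)
        pxx = np.mean(np.abs(seg) ** 2, axis=0)
        pxy = np.mean(seg * np.conj(seg_ref[:, :, None]), axis=0)
        denom = pxx * pxx_ref[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.abs(pxy) ** 2 / denom
        c = np.clip(np.nan_to_num(c, nan=0.0), 0.0, 1.0)
        if reduction == "peak":
            red = c[in_band].max(axis=0)
        else:
            red = c[f_ref_idx]
        band_power = pxx[in_band].sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * pxx[f_ref_idx] / band_power
        peak.ravel()[sel] = red
        power.ravel()[sel] = np.nan_to_num(pct, nan=0.0)

    return CoherenceResult(
        peak_coherence=MapImage(
            values=np.nan_to_num(peak, nan=0.0), units="dimensionless",
            pixel_size=rec.pixel_size, mask=mask_arr,
        ),
        power_at_ref=MapImage(
            values=np.nan_to_num(power, nan=0.0), units="%",
            pixel_size=rec.pixel_size, mask=mask_arr,
        ),
        reference=(r0, c0),
        reference_cbf=reference_cbf,
        band=(f_min, f_max),
    )


def classify_pixels(
    result: CoherenceResult,
    red: tuple[float, float] = (0.5, 10.0),
    blue: tuple[float, float] = (0.3, 25.0),
    green: tuple[float, float] = (0.5, 25.0),
) -> MapImage:
    """Classify masked pixels by coherence/power against the reference.

    red / "synchronized" (code 1): C >= 0.5 and power >= 10 %;
    blue / "same_freq_unsynchronized" (code 2): C <= 0.3 and power >= 25 %;
    green / "different_freq" (code 3): C <= 0.5 and power <= 25 %;
    everything else is "other" (code 0).  Classes are assigned in that
    order, so the (measure-zero) threshold overlaps resolve deterministically.
    """
    c = result.peak_coherence.values
    p = result.power_at_ref.values
    out = np.zeros(c.shape, dtype=np.int8)
    is_green = (c <= green[0]) & (p <= green[1])
    is_blue = (c <= blue[0]) & (p >= blue[1])
    is_red = (c >= red[0]) & (p >= red[1])
    out[is_green] = 3
    out[is_blue] = 2
    out[is_red] = 1
    out[~result.peak_coherence.mask] = 0
    return MapImage(
        values=out,
        units="class",
        pixel_size=result.peak_coherence.pixel_size,
        mask=result.peak_coherence.mask,
    )


@dataclass
class CoherenceDistanceHistogram:
    """2-D histogram of pairwise peak coherence against pixel distance."""

    distance_edges: np.ndarray  # um
    coherence_edges: np.ndarray
    counts: np.ndarray  # (n_dist_bins, n_coh_bins) ints
    mean_per_distance: np.ndarray  # NaN where a distance bin is empty
    fraction_above_threshold: np.ndarray
    threshold: float
    n_pairs: int

    @property
    def distance_centers(self) -> np.ndarray:
        return 0.5 * (self.distance_edges[:-1] + self.distance_edges[1:])


def coherence_vs_distance(
    rec: Recording,
    mask: MapImage | np.ndarray | None = None,
    spec: WelchSpec | None = None,
    band: tuple[float, float | None] = (15.0, None),
    distance_bin: float = 0.5,
    coherence_bin: float = 0.04,
    threshold: float = 0.25,
    max_pairs: int = 2_000_000,
    all_pairs: bool = False,
    seed: int = 0,
) -> CoherenceDistanceHistogram:
    """Peak coherence of signal-pixel pairs binned by Euclidean distance.

    All unordered pairs are used when their number does not exceed
    ``max_pairs`` (or when ``all_pairs`` is set); otherwise a uniform random
    subsample of ``max_pairs`` pairs (fixed ``seed``) is drawn, which leaves
    the histogram unchanged in expectation.  Distances use the recording's
    pixel size, so the recording should already be downsampled if the
    analysis calls for it.
    """
    if spec is None:
        spec = WelchSpec(frame_rate=rec.frame_rate)
    rows, cols = rec.frame_shape
    mask_arr = (
        np.ones((rows, cols), bool)
        if mask is None
        else np.asarray(getattr(mask, "values", mask), bool)
    )
    idx = np.flatnonzero(mask_arr.ravel())
    n_pix = idx.size
    if n_pix < 2:
        raise ValueError("need at least 2 signal pixels")

    f_min, f_max = band
    if f_max is None:
        f_max = rec.nyquist
    in_band = (spec.freqs >= f_min) & (spec.freqs <= f_max)

    flat = rec.stack.reshape(rec.n_frames, -1)
    seg = _segment_rfft(flat[:, idx], spec)[:, in_band, :]  # (n_seg, n_band, n_pix)
    pxx = np.mean(np.abs(seg) ** 2, axis=0)  # (n_band, n_pix)

    n_total = n_pix * (n_pix - 1) // 2
    rng = np.random.default_rng(seed)
    if all_pairs or n_total <= max_pairs:
        ii, jj = np.triu_indices(n_pix, k=1)
    else:
        ii = rng.integers(0, n_pix, size=max_pairs)
        jj = rng.integers(0, n_pix, size=max_pairs)
        keep = ii != jj
        ii, jj = ii[keep], jj[keep]

    rr = idx // cols
    cc = idx % cols
    dist = np.hypot(rr[ii] - rr[jj], cc[ii] - cc[jj]) * rec.pixel_size

    peak = np.empty(ii.shape, dtype=np.float64)
    # keep each chunk's (n_seg, n_band, chunk) workspace near ~30M complex64
    chunk = max(1024, int(3e7 / max(1, seg.shape[0] * seg.shape[1])))
    for start in range(0, ii.size, chunk):
        si, sj = ii[start : start + chunk], jj[start : start + chunk]
        pxy = np.mean(seg[:, :, si] * np.conj(seg[:, :, sj]), axis=0)
        denom = pxx[:, si] * pxx[:, sj]
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.abs(pxy) ** 2 / denom
        c = np.clip(np.nan_to_num(c, nan=0.0), 0.0, 1.0)
        peak[start : start + chunk] = c.max(axis=0)

    d_max = float(dist.max()) if dist.size else distance_bin
    distance_edges = np.arange(0.0, d_max + distance_bin, distance_bin)
    if distance_edges[-1] <= d_max:
        distance_edges = np.append(distance_edges, distance_edges[-1] + distance_bin)
    n_coh = int(round(1.0 / coherence_bin))
    coherence_edges = np.linspace(0.0, 1.0, n_coh + 1)
    counts, _, _ = np.histogram2d(dist, peak, bins=(distance_edges, coherence_edges))

    which = np.digitize(dist, distance_edges) - 1
    n_dist = distance_edges.size - 1
    per_bin_n = np.bincount(which, minlength=n_dist).astype(float)
    per_bin_sum = np.bincount(which, weights=peak, minlength=n_dist)
    per_bin_above = np.bincount(which, weights=(peak > threshold), minlength=n_dist)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_per_distance = np.where(per_bin_n > 0, per_bin_sum / per_bin_n, np.nan)
        fraction_above = np.where(per_bin_n > 0, per_bin_above / per_bin_n, np.nan)

    return CoherenceDistanceHistogram(
        distance_edges=distance_edges,
        coherence_edges=coherence_edges,
        counts=counts.astype(np.int64),
        mean_per_distance=mean_per_distance[:n_dist],
        fraction_above_threshold=fraction_above[:n_dist],
        threshold=threshold,
        n_pairs=int(ii.size),
    )
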