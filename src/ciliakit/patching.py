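"""Segmentation of the signal region into same-frequency patches.

Peak frequencies are quantized into uniform bins spanning [0, Nyquist]
(100 bins by default, i.e. ~0.5 Hz at a ~100 Hz frame rate) and connected
components are formed per bin over the signal mask.  Phases of Fourier
modes are only comparable when read at a single frequency, so these patches
are the unit at which phase is later evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import MapImage
from .spectral import FrequencyMap, PixelSpectra

__all__ = ["PatchMap", "segment_frequency_patches", "patch_dominant_frequency"]

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass
class PatchMap:
    """Integer label image partitioning signal pixels into frequency patches.

    ``labels`` is 0 on background; patches are numbered 1..n_patches in
    raster order of their first pixel.  ``bin_index`` and ``bin_width`` give
    each patch's frequency bin (bin i spans [i*w, (i+1)*w) Hz);
    ``dominant_freq`` is filled by :func:`patch_dominant_frequency`.
    """

    labels: np.ndarray
    bin_width: float
    bin_index: np.ndarray  # per patch, int
    n_pixels: np.ndarray  # per patch, int
    dominant_freq: np.ndarray | None = None  # per patch, Hz
    connectivity: int = 8
    pixel_size: float = field(default=1.0)

    @property
    def n_patches(self) -> int:
        return int(self.bin_index.shape[0])

    def patch_mask(self, label: int) -> np.ndarray:
        """Boolean mask of the 1-based patch ``label``."""
        return self.labels == label

    def bin_range(self, label: int) -> tuple[float, float]:
        """Frequency bin [lo, hi) of patch ``label`` in Hz."""
        i = int(self.bin_index[label - 1])
        return i * self.bin_width, (i + 1) * self.bin_width


def segment_frequency_patches(
    freq_map: FrequencyMap,
    mask: MapImage | np.ndarray,
    n_bins: int = 100,
    connectivity: int = 8,
    min_patch: int = 200,
) -> PatchMap:
    """Group same-frequency-bin signal pixels into connected patches.

    Frequencies are binned into ``n_bins`` uniform bins over [0, Nyquist];
    connected components (default 8-connected) are computed per bin on the
    masked pixels and components smaller than ``min_patch`` pixels are
    discarded.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    mask_arr = np.asarray(getattr(mask, "values", mask), dtype=bool)
    if mask_arr.shape != freq_map.values.shape:
        raise ValueError("frequency map and mask must share geometry")
    nyquist = freq_map.frame_rate / 2.0
    if nyquist <= 0:
        raise ValueError("frequency map is missing its frame rate")
    bin_width = nyquist / n_bins
    bins = np.clip((freq_map.values / bin_width).astype(int), 0, n_bins - 1)

    labels = np.zeros(freq_map.values.shape, dtype=np.int32)
    structure = _STRUCTURES[connectivity]
    found: list[tuple[int, int, np.ndarray, int]] = []  # (first_flat_idx, bin, mask, size)
    for b in np.unique(bins[mask_arr]):
        comp, n = ndimage.label(mask_arr & (bins == b), structure=structure)
        if not n:
            continue
        sizes = np.bincount(comp.ravel())
        for lab in range(1, n + 1):
            if sizes[lab] >= min_patch:
                m = comp == lab
                first = int(np.flatnonzero(m.ravel())[0])
                found.append((first, int(b), m, int(sizes[lab])))
    found.sort(key=lambda item: item[0])
    bin_index = np.array([b for _, b, _, _ in found], dtype=int)
    n_pixels = np.array([s for _, _, _, s in found], dtype=int)
    for new_label, (_, _, m, _) in enumerate(found, start=1):
        labels[m] = new_label
    return PatchMap(
        labels=labels,
        bin_width=bin_width,
        bin_index=bin_index,
        n_pixels=n_pixels,
        connectivity=connectivity,
        pixel_size=freq_map.pixel_size,
    )


def patch_dominant_frequency(patch_map: PatchMap, spectra: PixelSpectra) -> np.ndarray:
    """Dominant spectral line per patch, in Hz.

    For each patch, the discrete frequency maximizing |coefficient|^2 summed
    over the patch's pixels, restricted to the spectral lines inside the
    patch's frequency bin.  The result is also stored on ``patch_map``.
    """
    if spectra.coefficients.shape[1:] != patch_map.labels.shape:
        raise ValueError("patch map and spectra must share geometry")
    out = np.empty(patch_map.n_patches, dtype=np.float64)
    power = np.abs(spectra.coefficients) ** 2
    for label in range(1, patch_map.n_patches + 1):
        lo, hi = patch_map.bin_range(label)
        in_bin = (spectra.freqs >= lo) & (spectra.freqs < hi)
        if not in_bin.any():  # bin narrower than the line spacing: use nearest line
            in_bin = np.zeros_like(in_bin)
            in_bin[spectra.freq_index((lo + hi) / 2)] = True
        m = patch_map.patch_mask(label)
        total = power[:, m].sum(axis=1)
        masked = np.where(in_bin, total, -np.inf)
        out[label - 1] = spectra.freqs[int(np.argmax(masked))]
    patch_map.dominant_freq = out
    return out
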