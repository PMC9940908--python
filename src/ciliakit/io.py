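"""Recording and map containers, TIFF/JSON input-output.

A recording is a grayscale time-lapse stack of a beating cilia carpet,
acquired by light transmission or light-sheet microscopy at ~100 frames/s.
Beating cilia modulate the transmitted light, so each pixel carries an
intensity time series whose spectrum encodes the local ciliary beat.

Coordinate convention: arrays are row-major and 0-based with the origin at
the top-left; ``stack[t, r, c]`` is pixel (row r, column c) of frame t as
stored in the file.  The image x axis points along columns (rightward) and
the y axis along rows (downward); all angles are reported in this frame
unless an explicit axis rotation is supplied downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = ["Recording", "MapImage", "load_recording", "save_map", "load_map"]

#: frames required so that at least two Welch windows (length 100) fit
MIN_FRAMES = 200


@dataclass
class Recording:
    """A grayscale time-lapse stack with acquisition metadata.

    Parameters
    ----------
    stack
        Intensity array of shape (frames, rows, cols), arbitrary units.
        Integer input is promoted to 64-bit float so that windowed products
        in the spectral stages cannot overflow.
    frame_rate
        Acquisition rate in Hz.
    pixel_size
        Pixel pitch in micrometers per pixel.
    origin_note
        Free-text provenance (organ, side, condition).
    """

    stack: np.ndarray
    frame_rate: float
    pixel_size: float
    origin_note: str = ""

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 3:
            raise ValueError(
                f"stack must be 3-D (frames, rows, cols); got shape {self.stack.shape}"
            )
        if np.issubdtype(self.stack.dtype, np.integer):
            self.stack = self.stack.astype(np.float64)
        if self.stack.shape[0] < 2:
            raise ValueError("a recording needs at least 2 frames")
        if not (self.frame_rate > 0):
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if not np.isfinite(self.stack).all():
            raise ValueError("stack contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.stack.shape[1:]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.frame_rate

    @property
    def nyquist(self) -> float:
        return self.frame_rate / 2.0


@dataclass
class MapImage:
    """A 2-D analysis product on (possibly downsampled) recording geometry.

    ``values`` must be finite exactly where ``mask`` is true; outside the
    mask values are undefined and serialized as NaN.
    """

    values: np.ndarray
    units: str
    pixel_size: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("map values must be 2-D")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must share geometry")
        if self.values.dtype != bool and not np.isfinite(self.values[self.mask]).all():
            raise ValueError("map contains non-finite values inside the mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def masked(self) -> np.ndarray:
        """Float copy with NaN outside the mask."""
        out = self.values.astype(np.float64, copy=True)
        out[~self.mask] = np.nan
        return out


def load_recording(
    path: str | Path,
    frame_rate: float,
    pixel_size: float,
    origin_note: str = "",
    min_frames: int = MIN_FRAMES,
) -> Recording:
    """Load a multi-page grayscale TIFF as a :class:`Recording`.

    The frame order and pixel layout of the file are preserved exactly:
    pixel (r, c) of page t equals ``stack[t, r, c]``.

    Raises
    ------
    ValueError
        For multi-channel (RGB/RGBA) input or stacks shorter than
        ``min_frames`` frames.
    """
    with tifffile.TiffFile(str(path)) as tif:
        if tif.pages[0].samplesperpixel > 1:
            raise ValueError(f"single-channel required: {path} is multi-channel")
        arr = tif.asarray()
    if arr.ndim == 4:
        raise ValueError(f"single-channel required: {path} is multi-channel (shape {arr.shape})")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"cannot interpret {path} as frames x rows x cols (shape {arr.shape})")
    if arr.shape[0] < min_frames:
        raise ValueError(
            f"{path} has {arr.shape[0]} frames; at least {min_frames} are required "
            "for spectral analysis (>= 2x the Welch window). Record longer or "
            "lower min_frames explicitly."
        )
    return Recording(arr, frame_rate=frame_rate, pixel_size=pixel_size, origin_note=origin_note)


def save_map(
    map_image: MapImage, path: str | Path, parameters: dict | None = None
) -> Path:
    """Write a map as a float TIFF (NaN outside the mask) plus a JSON sidecar.

    The sidecar ``<path>.json`` records units, pixel size and any analysis
    parameters so that a map remains interpretable on its own.
    """
    path = Path(path)
    if not map_image.mask.any():
        logger.warning("saving map %s with an empty mask (all values NaN)", path)
    tifffile.imwrite(str(path), map_image.masked())
    sidecar = {
        "units": map_image.units,
        "pixel_size_um": map_image.pixel_size,
        "parameters": parameters or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_map(path: str | Path) -> MapImage:
    """Reload a map written by :func:`save_map`; NaN pixels become the mask."""
    path = Path(path)
    values = tifffile.imread(str(path))
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    mask = np.isfinite(values)
    return MapImage(
        values=values,
        units=sidecar["units"],
        pixel_size=float(sidecar["pixel_size_um"]),
        mask=mask,
    )
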