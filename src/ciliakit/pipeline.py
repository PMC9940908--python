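"""End-to-end analysis pipeline with a reproducible run manifest.

Stages: spatial downsampling -> per-pixel spectra -> CBF map -> signal
mask -> frequency patches -> patch dominant frequencies -> phase maps ->
gradient wave extraction, with optional reference-pixel coherence and
coherence-versus-distance stages.  Every parameter is echoed into a
``manifest.json`` next to the outputs, and given the same configuration,
seed and input the outputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coherence import (
    WelchSpec,
    classify_pixels,
    coherence_map,
    coherence_vs_distance,
)
from .io import MapImage, Recording, load_recording, save_map
from .patching import patch_dominant_frequency, segment_frequency_patches
from .spectral import downsample_stack, peak_frequency_map, pixel_spectra, signal_mask
from .wavefield import analyze_wavefield

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """All stage parameters, defaulting to the standard analysis settings."""

    downsample: int = 5
    f_min: float = 15.0
    f_max: float | None = None  # None = Nyquist
    sd_kernel: int = 3
    sd_threshold: float = 3.0  # Hz
    min_region: int = 500  # px
    n_bins: int = 100
    connectivity: int = 8
    min_patch: int = 200  # px
    welch_window: int = 100
    welch_overlap: int = 80
    welch_nfft: int = 100
    distance_bin: float = 0.5  # um
    coherence_bin: float = 0.04
    coherence_threshold: float = 0.25
    red_thresholds: tuple[float, float] = (0.5, 10.0)
    blue_thresholds: tuple[float, float] = (0.3, 25.0)
    green_thresholds: tuple[float, float] = (0.5, 25.0)
    mag_bin: float = 0.01  # rad/um
    wavelength_method: str = "vector"
    min_gradient_pixels: int = 10
    max_pairs: int = 2_000_000
    seed: int = 0
    # optional stages
    coherence_reference: tuple[int, int] | None = None  # post-downsampling (row, col)
    coherence_distance: bool = False
    # sliding-window analysis; None = analyze the full recording once
    window_s: float | None = None
    stride_s: float = 10.0


@dataclass
class PipelineResult:
    """In-memory results of one pipeline run (one entry per time window)."""

    wave_tables: list[pd.DataFrame]
    manifest: dict
    outdir: Path | None = None

    @property
    def wave_table(self) -> pd.DataFrame:
        return self.wave_tables[0]


def _analyze_window(rec: Recording, config: RunConfig):
    spectra = pixel_spectra(rec)
    freq_map = peak_frequency_map(spectra, f_min=config.f_min, f_max=config.f_max)
    mask = signal_mask(
        freq_map,
        kernel=config.sd_kernel,
        sd_threshold=config.sd_threshold,
        min_region=config.min_region,
    )
    patches = segment_frequency_patches(
        freq_map,
        mask,
        n_bins=config.n_bins,
        connectivity=config.connectivity,
        min_patch=config.min_patch,
    )
    patch_dominant_frequency(patches, spectra)
    waves = analyze_wavefield(
        spectra,
        patches,
        mag_bin=config.mag_bin,
        wavelength_method=config.wavelength_method,
        min_pixels=config.min_gradient_pixels,
    )
    return spectra, freq_map, mask, patches, waves


def run_pipeline(
    recording: Recording | str | Path,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
    frame_rate: float | None = None,
    pixel_size: float | None = None,
) -> PipelineResult:
    """Run the full analysis on a recording (path or in-memory).

    When ``recording`` is a path, ``frame_rate`` and ``pixel_size`` are
    required acquisition metadata.  When ``outdir`` is given, all maps
    (TIFF + JSON sidecars), per-patch tables (CSV) and the run manifest are
    written there.
    """
    config = config or RunConfig()
    t_start = time.time()
    if not isinstance(recording, Recording):
        if frame_rate is None or pixel_size is None:
            raise ValueError(
                "frame_rate and pixel_size metadata are required to load a recording"
            )
        recording = load_recording(recording, frame_rate=frame_rate, pixel_size=pixel_size)

    rec = downsample_stack(recording, config.downsample)
    timings: dict[str, float] = {"downsample": time.time() - t_start}

    # time windows
    if config.window_s is None:
        starts = [0]
        win_frames = rec.n_frames
    else:
        win_frames = int(round(config.window_s * rec.frame_rate))
        stride = max(1, int(round(config.stride_s * rec.frame_rate)))
        if win_frames > rec.n_frames:
            raise ValueError(
                f"window of {config.window_s}s exceeds the recording ({rec.duration:.1f}s)"
            )
        starts = list(range(0, rec.n_frames - win_frames + 1, stride))

    outdir_path = Path(outdir) if outdir is not None else None
    if outdir_path is not None:
        outdir_path.mkdir(parents=True, exist_ok=True)

    wave_tables = []
    for w, start in enumerate(starts):
        sub = Recording(
            rec.stack[start : start + win_frames],
            frame_rate=rec.frame_rate,
            pixel_size=rec.pixel_size,
            origin_note=rec.origin_note,
        )
        t0 = time.time()
        spectra, freq_map, mask, patches, waves = _analyze_window(sub, config)
        timings[f"window_{w}"] = time.time() - t0
        table = waves.table.copy()
        table.insert(0, "window", w)
        table.insert(1, "t_start_s", start / rec.frame_rate)
        wave_tables.append(table)

        if outdir_path is not None:
            suffix = "" if config.window_s is None else f"_w{w:03d}"
            params = {"config": _jsonable(asdict(config))}
            save_map(freq_map, outdir_path / f"frequency_map{suffix}.tif", params)
            save_map(mask, outdir_path / f"signal_mask{suffix}.tif", params)
            save_map(
                MapImage(
                    values=patches.labels.astype(np.float64),
                    units="label",
                    pixel_size=freq_map.pixel_size,
                ),
                outdir_path / f"patch_labels{suffix}.tif",
                params,
            )
            save_map(waves.direction_map, outdir_path / f"wave_direction{suffix}.tif", params)
            save_map(waves.wavelength_map, outdir_path / f"wavelength{suffix}.tif", params)
            table.to_csv(outdir_path / f"wave_table{suffix}.csv", index=False)

        if w == 0 and config.coherence_reference is not None:
            spec = WelchSpec(
                window_length=config.welch_window,
                overlap=config.welch_overlap,
                n_fft=config.welch_nfft,
                frame_rate=sub.frame_rate,
            )
            result = coherence_map(
                sub, config.coherence_reference, mask, spec, band=(config.f_min, config.f_max)
            )
            classes = classify_pixels(
                result, config.red_thresholds, config.blue_thresholds, config.green_thresholds
            )
            timings["coherence_map"] = time.time() - t0
            if outdir_path is not None:
                save_map(result.peak_coherence, outdir_path / "peak_coherence.tif")
                save_map(result.power_at_ref, outdir_path / "power_at_reference.tif")
                save_map(classes, outdir_path / "coherence_classes.tif")

        if w == 0 and config.coherence_distance:
            spec = WelchSpec(
                window_length=config.welch_window,
                overlap=config.welch_overlap,
                n_fft=config.welch_nfft,
                frame_rate=sub.frame_rate,
            )
            hist = coherence_vs_distance(
                sub,
                mask,
                spec,
                band=(config.f_min, config.f_max),
                distance_bin=config.distance_bin,
                coherence_bin=config.coherence_bin,
                threshold=config.coherence_threshold,
                max_pairs=config.max_pairs,
                seed=config.seed,
            )
            timings["coherence_distance"] = time.time() - t0
            if outdir_path is not None:
                summary = pd.DataFrame(
                    {
                        "distance_bin_center_um": hist.distance_centers,
                        "mean_coherence": hist.mean_per_distance,
                        f"fraction_gt_{hist.threshold}": hist.fraction_above_threshold,
                    }
                )
                summary.to_csv(outdir_path / "coherence_vs_distance.csv", index=False)

    manifest = {
        "ciliakit_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": _jsonable(asdict(config)),
        "input": {
            "n_frames": recording.n_frames,
            "frame_shape": list(recording.frame_shape),
            "frame_rate_hz": recording.frame_rate,
            "pixel_size_um": recording.pixel_size,
            "origin_note": recording.origin_note,
        },
        "n_windows": len(starts),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    if outdir_path is not None:
        (outdir_path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.info("pipeline outputs written to %s", outdir_path)
    return PipelineResult(wave_tables=wave_tables, manifest=manifest, outdir=outdir_path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
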