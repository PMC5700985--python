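"""Reading, writing and cropping of TIRF image stacks.

Stacks are multi-frame grayscale TIFFs of 16-bit camera counts.  On input the
raw counts are converted to photoelectrons through the linear camera model
``pe = (raw - offset) / em_gain`` (clipped at zero); EMCCD excess noise is not
inverted.  All physical positions are expressed in nm from the centre of the
top-left pixel; pixel indices are 0-based, row-major ``(y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "AcquisitionConfig",
    "ImageSequence",
    "read_stack",
    "write_stack",
    "read_config",
    "write_config",
    "select_roi",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera and optics parameters of an acquisition.

    Parameters
    ----------
    pixel_pitch_nm
        Sample-plane pixel pitch in nm.
    em_gain
        Electron-multiplying register gain (dimensionless, > 0).
    sensitivity_e_per_count
        A/D sensitivity of the readout in electrons per camera count; the
        effective system gain is ``em_gain / sensitivity_e_per_count``
        counts per photoelectron.  Without this divisor a single ~250-pe
        emission event at EM gain 300 would saturate the 16-bit range.
    offset_counts
        Camera bias offset in counts (>= 0).
    read_noise_counts
        Std. dev. of additive Gaussian read noise, in counts.
    psf_sigma_nm
        Width of the optical Gaussian PSF model in nm.  The default 82 nm
        is the diffraction-limited sigma ~ 0.21 lambda/NA of a NA 1.49 TIRF
        objective at ~580 nm emission; pixelation is NOT folded in here
        because both the simulator and the analysis integrate the PSF over
        pixels explicitly.  Raise it for samples with appreciable fixation
        blur or residual aberrations.
    frame_time_s
        Exposure time per frame in seconds.
    """

    pixel_pitch_nm: float = 105.0
    em_gain: float = 300.0
    sensitivity_e_per_count: float = 10.0
    offset_counts: float = 100.0
    read_noise_counts: float = 10.0
    psf_sigma_nm: float = 82.0
    frame_time_s: float = 0.032

    @property
    def counts_per_pe(self) -> float:
        return self.em_gain / self.sensitivity_e_per_count

    def __post_init__(self) -> None:
        for name in ("pixel_pitch_nm", "em_gain", "sensitivity_e_per_count",
                     "read_noise_counts", "psf_sigma_nm", "frame_time_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.offset_counts < 0:
            raise ValueError("offset_counts must be non-negative")


@dataclass
class ImageSequence:
    """An ordered stack of 2D photoelectron-count rasters.

    Attributes
    ----------
    frames
        Array of shape ``(T, H, W)`` of photoelectron counts (>= 0).
    pixel_pitch_nm
        Sample-plane pixel pitch in nm.
    frame_time_s
        Exposure per frame in seconds.
    """

    frames: np.ndarray
    pixel_pitch_nm: float
    frame_time_s: float = 0.032

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        if self.pixel_pitch_nm <= 0:
            raise ValueError("pixel_pitch_nm must be positive")
        if np.any(self.frames < 0):
            raise ValueError("photoelectron counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames


def read_stack(path: str | Path, config: AcquisitionConfig) -> ImageSequence:
    """Read a multi-frame TIFF and convert camera counts to photoelectrons.

    Raises a descriptive error for missing files, single-frame TIFFs and
    stacks whose pages disagree in shape.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    if len(pages) < 1:
        raise ValueError(f"{path} contains no image pages")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"{path}: pages have inconsistent shapes {sorted(shapes)}")
    if pages[0].ndim != 2:
        raise ValueError(f"{path}: expected 2D grayscale pages, got shape {pages[0].shape}")
    raw = np.stack(pages).astype(np.float64)
    pe = np.clip((raw - config.offset_counts) / config.counts_per_pe, 0.0, None)
    return ImageSequence(pe, pixel_pitch_nm=config.pixel_pitch_nm,
                         frame_time_s=config.frame_time_s)


def write_stack(path: str | Path, seq: ImageSequence, config: AcquisitionConfig) -> None:
    """Write a sequence as a 16-bit multi-frame TIFF of raw camera counts.

    Inverse of the :func:`read_stack` conversion: ``raw = pe * em_gain +
    offset``, rounded and clipped to the 16-bit range.
    """
    raw = seq.frames * config.counts_per_pe + config.offset_counts
    raw = np.clip(np.rint(raw), 0, 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), raw, photometric="minisblack")


def read_config(path: str | Path) -> AcquisitionConfig:
    """Load an :class:`AcquisitionConfig` from a YAML/JSON key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of config fields")
    known = AcquisitionConfig.__dataclass_fields__.keys()
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
    return AcquisitionConfig(**data)


def write_config(path: str | Path, config: AcquisitionConfig) -> None:
    data = {k: float(getattr(config, k))
            for k in AcquisitionConfig.__dataclass_fields__}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def select_roi(seq: ImageSequence, center_um: tuple[float, float],
               side_um: float) -> ImageSequence:
    """Crop a square region of interest centred at ``center_um`` (x, y in µm).

    The side length is converted to the nearest integer number of pixels,
    ``round(side_um * 1000 / pixel_pitch_nm)``.  The ROI must lie fully
    inside the field.
    """
    if side_um <= 0:
        raise ValueError("side_um must be positive")
    pitch = seq.pixel_pitch_nm
    side_px = int(round(side_um * 1000.0 / pitch))
    cx_px = center_um[0] * 1000.0 / pitch
    cy_px = center_um[1] * 1000.0 / pitch
    x0 = int(round(cx_px - side_px / 2.0))
    y0 = int(round(cy_px - side_px / 2.0))
    H, W = seq.shape
    if x0 < 0 or y0 < 0 or x0 + side_px > W or y0 + side_px > H:
        raise ValueError(
            f"ROI of {side_px} px at ({x0}, {y0}) exceeds the {H}x{W} field")
    frames = seq.frames[:, y0:y0 + side_px, x0:x0 + side_px].copy()
    return ImageSequence(frames, pixel_pitch_nm=pitch,
                         frame_time_s=seq.frame_time_s)
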