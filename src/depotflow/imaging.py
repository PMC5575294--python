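"""Detector-level corrections and attenuation inversion for radiograph stacks.

Raw radiographs carry fixed-pattern detector structure: each pixel has its
own gain and dark offset.  Flat-field correction (FFC) normalizes an object
frame by a sample-free *gain* exposure and a beam-off *offset* exposure,

    FFC = (object - offset) / (gain - offset),

yielding transmission in [0, 1].  The Beer-Lambert law I = I0 exp(-mu x)
then inverts transmission to material path length x = -ln(T)/mu.

Invalid pixels (zero flat-field denominator, non-positive transmission)
propagate as numpy masked-array masks rather than infinities.

A parallel-projection geometry is assumed throughout; cone-beam
magnification of the acquisition geometry is ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from . import constants as C

__all__ = [
    "ImageStack",
    "FlatFieldSet",
    "average_gain",
    "flat_field_correct",
    "beer_lambert_thickness",
    "register_drift",
    "read_stack",
    "write_stack",
]


@dataclass
class ImageStack:
    """Time-ordered radiograph frames plus acquisition geometry.

    frames: (T, H, W) array of detector counts (or transmission once
    corrected); timestamps strictly increasing, seconds from injection start.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_size_um: float = C.DEFAULT_PIXEL_SIZE_UM
    field_of_view_mm: tuple[float, float] = C.DEFAULT_FIELD_OF_VIEW_MM
    exposure_s: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.timestamps.shape != (self.frames.shape[0],):
            raise ValueError("one timestamp per frame required")
        if self.frames.shape[0] > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class FlatFieldSet:
    """Gain (sample-free) and offset (beam-off) calibration images."""

    gain: np.ndarray
    offset: np.ndarray
    n_gain_averaged: int = 1

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        if self.gain.shape != self.offset.shape:
            raise ValueError("gain and offset shapes must match")


def average_gain(gain_frames: Sequence[np.ndarray]) -> np.ndarray:
    """Pixelwise arithmetic mean of repeated gain exposures.

    Averaging n frames reduces the residual gain noise by sqrt(n); the
    acquisition protocol averages 10.
    """
    frames = [np.asarray(f, dtype=float) for f in gain_frames]
    if len(frames) == 0:
        raise ValueError("need at least one gain frame")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all gain frames must share one shape")
    return np.mean(np.stack(frames, axis=0), axis=0)


def flat_field_correct(object_img: np.ndarray, flat: FlatFieldSet) -> np.ma.MaskedArray:
    """Flat-field correct one frame to transmission: (obj - off)/(gain - off).

    Pixels where gain equals offset are masked rather than divided through.
    """
    obj = np.asarray(object_img, dtype=float)
    if obj.shape != flat.gain.shape:
        raise ValueError("object and flat-field shapes must match")
    denom = flat.gain - flat.offset
    invalid = denom == 0
    safe = np.where(invalid, 1.0, denom)
    trans = (obj - flat.offset) / safe
    return np.ma.MaskedArray(trans, mask=invalid)


def beer_lambert_thickness(transmission: np.ndarray, mu_abs_per_mm: float) -> np.ma.MaskedArray:
    """Invert transmission to material path length x = -ln(T)/mu [mm].

    Non-positive transmission pixels are masked; existing masks propagate.
    """
    if mu_abs_per_mm <= 0:
        raise ValueError("absorption coefficient must be positive")
    t = np.ma.asarray(transmission).astype(float)
    invalid = np.ma.getmaskarray(t) | (t.filled(0.0) <= 0)
    safe = np.where(invalid, 1.0, t.filled(1.0))
    x = -np.log(safe) / mu_abs_per_mm
    return np.ma.MaskedArray(x, mask=invalid)


def register_drift(
    stack: ImageStack,
    reference_index: int = 0,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, ImageStack]:
    """Estimate and undo slow sample drift by integer-pixel translation.

    Each frame is aligned against ``stack.frames[reference_index]`` by the
    translation maximizing the cross-correlation (phase correlation,
    integer-pixel).  Returns the per-frame (drow, dcol) shifts of each frame
    relative to the reference and a corrected stack with those shifts undone.

    An optional boolean ``mask`` (True = exclude, e.g. the needle region)
    is zeroed out before correlation.  Featureless frames yield zero shift
    with a warning.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 frames to register")
    ref = stack.frames[reference_index].astype(float)
    if mask is not None:
        ref = np.where(mask, 0.0, ref)
    shifts = np.zeros((len(stack), 2))
    corrected = np.empty_like(stack.frames, dtype=float)
    ref_flat = np.ptp(ref) == 0
    for i, frame in enumerate(stack.frames):
        frm = frame.astype(float)
        work = np.where(mask, 0.0, frm) if mask is not None else frm
        if i == reference_index:
            corrected[i] = frm
            continue
        if ref_flat or np.ptp(work) == 0:
            warnings.warn(f"frame {i}: featureless image, assuming zero shift", stacklevel=2)
            corrected[i] = frm
            continue
        corr_shift, _, _ = phase_cross_correlation(ref, work, upsample_factor=1)
        corr_shift = np.round(corr_shift).astype(int)
        shifts[i] = -corr_shift  # drift of this frame relative to the reference
        corrected[i] = ndimage.shift(frm, corr_shift, order=0, mode="nearest")
    return shifts, ImageStack(
        frames=corrected,
        timestamps=stack.timestamps.copy(),
        pixel_size_um=stack.pixel_size_um,
        field_of_view_mm=stack.field_of_view_mm,
        exposure_s=stack.exposure_s,
    )


# --------------------------------------------------------------------------- #
# stack I/O: multi-page TIFF + plain-text metadata sidecar
# --------------------------------------------------------------------------- #

_SIDECAR_SUFFIX = ".meta.yaml"


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page float32 TIFF with a YAML sidecar.

    The sidecar holds pixel size, field of view, exposure and per-frame
    timestamps so a read round-trips losslessly.
    """
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "pixel_size_um": float(stack.pixel_size_um),
        "field_of_view_mm": [float(v) for v in stack.field_of_view_mm],
        "exposure_s": float(stack.exposure_s),
        "timestamps_s": [float(t) for t in stack.timestamps],
    }
    path.with_suffix(path.suffix + _SIDECAR_SUFFIX).write_text(yaml.safe_dump(meta))


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack`.

    A missing sidecar falls back to default geometry (9 um pixels, unit
    frame spacing) with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # malformed file
        raise ValueError(f"could not read TIFF stack {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(path.suffix + _SIDECAR_SUFFIX)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        return ImageStack(
            frames=frames,
            timestamps=np.asarray(meta["timestamps_s"], dtype=float),
            pixel_size_um=float(meta.get("pixel_size_um", C.DEFAULT_PIXEL_SIZE_UM)),
            field_of_view_mm=tuple(meta.get("field_of_view_mm", C.DEFAULT_FIELD_OF_VIEW_MM)),
            exposure_s=float(meta.get("exposure_s", 1.0)),
        )
    warnings.warn(f"no metadata sidecar for {path}; applying defaults", stacklevel=2)
    return ImageStack(frames=frames, timestamps=np.arange(frames.shape[0], dtype=float))
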