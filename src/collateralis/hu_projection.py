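"""Brightness adjustment, CBCT-to-Hounsfield conversion and sliding MIP.

Raw CBCT gray values are not calibrated CT numbers: scatter depresses them
relative to true attenuation.  The pipeline therefore first applies a linear
brightness regression Y = m + w*Q to each slice (defaults w=1.0236, m=200,
fitted on clinical CBCT data), then maps the adjusted values to Hounsfield
units with the DICOM rescale affine HU = Y*RS + RI.  A sliding-window
maximum intensity projection (default 20 slices, stride 1) then collapses
the HU volume into a stack of 2D projections in which contrast-filled
vessels stand out.

Brightness adjustment must happen *before* the HU conversion; with a nonzero
regression constant the two orders differ by m*RS and swapping them loses
vessel signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import CBCTVolume, Image2D

__all__ = [
    "BrightnessModel",
    "MIPStack",
    "adjust_brightness",
    "to_hounsfield",
    "convert_volume_to_hu",
    "sliding_mip",
]


@dataclass
class BrightnessModel:
    """Linear regression Y = m + w*Q mapping raw CBCT values to adjusted values."""

    w: float = 1.0236
    m: float = 200.0

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError("regression coefficient w must be positive")


@dataclass
class MIPStack:
    """Ordered sliding-window maximum intensity projections of an HU volume.

    ``windows[k]`` is the 0-based inclusive slice range [first, last] that
    produced ``images[k]``; user-facing logs print these 1-based.
    """

    images: list[Image2D]
    windows: list[tuple[int, int]]
    window: int
    stride: int

    def __post_init__(self) -> None:
        if len(self.images) != len(self.windows):
            raise ValueError("images and windows must align")
        for k, (lo, hi) in enumerate(self.windows):
            if hi - lo + 1 != self.window:
                raise ValueError(f"window {k} has length {hi - lo + 1}, expected {self.window}")
            if k > 0 and lo - self.windows[k - 1][0] != self.stride:
                raise ValueError("windows must advance by exactly the stride")

    def __len__(self) -> int:
        return len(self.images)


def _as2d(image: Image2D | np.ndarray) -> np.ndarray:
    arr = image.data if isinstance(image, Image2D) else np.asarray(image, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite input image")
    return arr


def adjust_brightness(q_image: Image2D | np.ndarray, model: BrightnessModel | None = None) -> Image2D:
    """Apply the linear brightness regression Y = m + w*Q elementwise."""
    model = model or BrightnessModel()
    q = _as2d(q_image)
    prov = q_image.provenance if isinstance(q_image, Image2D) else None
    return Image2D(model.m + model.w * q, value_range="raw", provenance=prov)


def to_hounsfield(y_image: Image2D | np.ndarray, rescale_slope: float, rescale_intercept: float) -> Image2D:
    """Convert a brightness-adjusted image to Hounsfield units, HU = Y*RS + RI."""
    if rescale_slope == 0:
        raise ValueError("rescale slope must be nonzero")
    y = _as2d(y_image)
    prov = y_image.provenance if isinstance(y_image, Image2D) else None
    return Image2D(y * rescale_slope + rescale_intercept, value_range="HU", provenance=prov)


def convert_volume_to_hu(volume: CBCTVolume, model: BrightnessModel | None = None) -> CBCTVolume:
    """Brightness-adjust then HU-convert every slice of a raw CBCT volume."""
    model = model or BrightnessModel()
    hu = (model.m + model.w * volume.data) * volume.rescale_slope + volume.rescale_intercept
    return CBCTVolume(
        data=hu,
        slice_thickness_mm=volume.slice_thickness_mm,
        pixel_spacing_mm=volume.pixel_spacing_mm,
        rescale_slope=volume.rescale_slope,
        rescale_intercept=volume.rescale_intercept,
        rescale_from_tags=volume.rescale_from_tags,
        provenance=volume.provenance + " | HU",
    )


def sliding_mip(volume: CBCTVolume | np.ndarray, window: int = 20, stride: int = 1) -> MIPStack:
    """Sliding-window maximum intensity projection along the slice axis.

    Image k is the elementwise maximum over slices
    [k*stride, k*stride + window - 1]; the stack holds
    floor((n_slices - window)/stride) + 1 projections.
    """
    data = volume.data if isinstance(volume, CBCTVolume) else np.asarray(volume, dtype=float)
    n = data.shape[0]
    if window < 1 or window > n:
        raise ValueError(f"window must be in [1, {n}], got {window}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    view = np.lib.stride_tricks.sliding_window_view(data, window, axis=0)
    mips = view[::stride].max(axis=-1)
    images, windows = [], []
    for k in range(mips.shape[0]):
        lo = k * stride
        windows.append((lo, lo + window - 1))
        images.append(
            Image2D(mips[k], value_range="HU", provenance=f"MIP slices {lo + 1}-{lo + window} (1-based)")
        )
    return MIPStack(images=images, windows=windows, window=window, stride=stride)
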