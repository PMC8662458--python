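"""Morphological skull stripping of MIP images.

Four steps: (1) binarize below the image mean, which marks air and brain
tissue but not the bright cranial shell; (2) clear every component touching
the image border (the air outside the skull); (3) flood-fill interior holes
and keep the largest remaining component - the brain region; (4) multiply
the MIP by that mask.  Component labeling uses 8-connectivity and hole
filling 4-connectivity, so thin diagonal gaps in the shell do not leak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops
from skimage.segmentation import clear_border

from .volume_io import Image2D

__all__ = [
    "BrainMask",
    "binarize_below_mean",
    "clear_border_components",
    "fill_and_keep_largest",
    "apply_mask",
    "strip_skull",
]


@dataclass
class BrainMask:
    """Binary brain region of interest produced by skull stripping."""

    mask: np.ndarray
    area: int
    threshold: float
    n_components_considered: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.area <= 0:
            raise ValueError("brain mask has zero area")
        if label(self.mask, connectivity=2).max() != 1:
            raise ValueError("brain mask must be a single connected component")


def _as2d(image: Image2D | np.ndarray) -> np.ndarray:
    arr = image.data if isinstance(image, Image2D) else np.asarray(image, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite input image")
    return arr


def binarize_below_mean(image: Image2D | np.ndarray) -> np.ndarray:
    """Threshold I < mean(I): true where the pixel is strictly below the image mean."""
    arr = _as2d(image)
    return arr < arr.mean()


def clear_border_components(mask: np.ndarray) -> np.ndarray:
    """Remove every 8-connected foreground component touching any image edge."""
    mask = np.asarray(mask, dtype=bool)
    labels = label(mask, connectivity=2)
    return clear_border(labels) > 0


def fill_and_keep_largest(mask: np.ndarray) -> BrainMask:
    """Fill interior holes (4-connected flood fill) and keep the largest component.

    Area ties are broken toward the component with the smallest top-left
    bounding-box coordinate, for determinism.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("skull stripping failed: empty mask before hole filling")
    filled = ndimage.binary_fill_holes(mask)  # default structure = 4-connectivity
    labels = label(filled, connectivity=2)
    regions = regionprops(labels)
    best = min(regions, key=lambda r: (-r.area, r.bbox[0], r.bbox[1]))
    return BrainMask(
        mask=labels == best.label,
        area=int(best.area),
        threshold=float("nan"),
        n_components_considered=len(regions),
    )


def apply_mask(image: Image2D | np.ndarray, mask: BrainMask | np.ndarray) -> Image2D:
    """Element-by-element multiplication of the MIP image with the brain mask."""
    arr = _as2d(image)
    m = mask.mask if isinstance(mask, BrainMask) else np.asarray(mask, dtype=bool)
    if arr.shape != m.shape:
        raise ValueError(f"shape mismatch: image {arr.shape} vs mask {m.shape}")
    vr = image.value_range if isinstance(image, Image2D) else "raw"
    prov = (image.provenance or "") + " | skull-stripped" if isinstance(image, Image2D) else "skull-stripped"
    return Image2D(arr * m, value_range=vr, provenance=prov)


def strip_skull(image: Image2D | np.ndarray) -> tuple[Image2D, BrainMask]:
    """Run the full four-step skull removal and return (masked MIP, mask)."""
    arr = _as2d(image)
    threshold = float(arr.mean())
    binary = binarize_below_mean(arr)
    interior = clear_border_components(binary)
    if not interior.any():
        raise ValueError("skull stripping failed: no interior component after border clearing")
    brain = fill_and_keep_largest(interior)
    brain.threshold = threshold
    masked = apply_mask(image, brain)
    return masked, brain
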