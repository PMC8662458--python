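"""Sliding-window patch extraction and the 40-feature bank.

Each overlapping patch (default 16x16, shift 1) is described by 40 features
in three groups:

* 22 gray-level co-occurrence (GLCM) texture statistics - the combined
  Haralick/Soh/Clausi battery.  Intensities are quantized to 8 equal-width
  levels over the patch's own range; co-occurrences are counted at the four
  distance-1 offsets, symmetrized and pooled into one normalized matrix.
  Entropy-type features use log2 with the 0*log0 := 0 convention.  Note the
  historical battery contains near-duplicates: Clausi's "inverse difference"
  is the same formula as the |i-j| homogeneity variant; both columns are
  kept so the canonical 22-name set is complete.
* 11 region-shape descriptors computed on the Otsu-binarized patch's
  largest connected component: six base properties (area, perimeter, major
  and minor axis length, eccentricity, solidity) and five shape factors
  (aspect ratio, circularity, compactness, roundness, extent).
* The 7 Hu moment invariants of the grayscale patch treated as a density -
  invariant to translation, scale and rotation (the seventh flips sign
  under reflection/90-degree rotation).

Only the total of 40 and the three groups are externally fixed; the exact
membership of the GLCM and shape groups is this module's documented
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "Patch",
    "extract_patches",
    "glcm",
    "glcm_features",
    "hu_moments",
    "shape_features",
    "build_feature_table",
    "GLCM_FEATURE_NAMES",
    "SHAPE_FEATURE_NAMES",
    "MOMENT_FEATURE_NAMES",
    "FEATURE_NAMES",
    "FEATURE_GROUPS",
    "DEFAULT_OFFSETS",
]

GLCM_FEATURE_NAMES = (
    "glcm_autocorrelation",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_dissimilarity",
    "glcm_energy",
    "glcm_entropy",
    "glcm_homogeneity",
    "glcm_homogeneity_moment",
    "glcm_max_probability",
    "glcm_variance",
    "glcm_sum_average",
    "glcm_sum_variance",
    "glcm_sum_entropy",
    "glcm_difference_variance",
    "glcm_difference_entropy",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_inverse_difference",
    "glcm_inverse_difference_norm",
    "glcm_inverse_difference_moment_norm",
)

SHAPE_FEATURE_NAMES = (
    "shape_area",
    "shape_perimeter",
    "shape_major_axis",
    "shape_minor_axis",
    "shape_eccentricity",
    "shape_solidity",
    "shape_aspect_ratio",
    "shape_circularity",
    "shape_compactness",
    "shape_roundness",
    "shape_extent",
)

MOMENT_FEATURE_NAMES = tuple(f"hu_moment_{i}" for i in range(1, 8))

FEATURE_NAMES = GLCM_FEATURE_NAMES + SHAPE_FEATURE_NAMES + MOMENT_FEATURE_NAMES
assert len(FEATURE_NAMES) == 40

FEATURE_GROUPS = {
    "glcm": GLCM_FEATURE_NAMES,
    "shape": SHAPE_FEATURE_NAMES,
    "moment": MOMENT_FEATURE_NAMES,
    "all": FEATURE_NAMES,
}

#: Distance-1 offsets (row, col): 0, 45, 90 and 135 degrees.
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class Patch:
    """A square intensity block cut from a source image.

    ``row``/``col`` are the 0-based top-left coordinates in the source;
    ``label`` is 0 for normal vessel, 1 for collateral, None if unlabeled.
    """

    data: np.ndarray
    row: int
    col: int
    label: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError(f"patch must be square 2D, got {self.data.shape}")
        if self.row < 0 or self.col < 0:
            raise ValueError("patch coordinates must be non-negative")


def extract_patches(image, block: int = 16, shift: int = 1) -> list[Patch]:
    """All overlapping block x block patches at offsets that are multiples of shift.

    The count is (floor((rows-block)/shift)+1) * (floor((cols-block)/shift)+1);
    e.g. a 256x256 image at block 16, shift 1 yields 241*241 = 58081 patches.
    """
    arr = np.asarray(getattr(image, "data", image), dtype=float)
    rows, cols = arr.shape
    if block > min(rows, cols):
        raise ValueError(f"block {block} exceeds image dims {arr.shape}")
    if shift < 1:
        raise ValueError("shift must be >= 1")
    patches = []
    for r in range(0, rows - block + 1, shift):
        for c in range(0, cols - block + 1, shift):
            patches.append(Patch(arr[r : r + block, c : c + block], r, c))
    return patches


# ---------------------------------------------------------------------------
# GLCM


def _quantize(patch: np.ndarray, levels: int) -> np.ndarray:
    lo = patch.min()
    span = patch.max() - lo
    if span == 0:
        return np.zeros(patch.shape, dtype=np.intp)
    q = ((patch - lo) / span * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def glcm(patch, levels: int = 8, offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix pooled over the offsets.

    The patch is quantized to ``levels`` equal-width bins over its own range;
    constant patches put all mass in one diagonal cell.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    arr = np.asarray(getattr(patch, "data", patch), dtype=float)
    q = _quantize(arr, levels)
    counts = np.zeros((levels, levels), dtype=float)
    rows, cols = q.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("patch too small for the requested offsets")
    return counts / total


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """The 22 combined Haralick/Soh/Clausi statistics of a normalized GLCM."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be square")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("GLCM must be normalized to sum 1")
    n = p.shape[0]
    i = np.arange(n)[:, None].astype(float)
    j = np.arange(n)[None, :].astype(float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((np.arange(n) * px).sum())
    mu_y = float((np.arange(n) * py).sum())
    var_x = float(((np.arange(n) - mu_x) ** 2 * px).sum())
    var_y = float(((np.arange(n) - mu_y) ** 2 * py).sum())

    # sum and difference distributions p_{x+y}, p_{|x-y|}
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (i + j).astype(int).ravel(), p.ravel())
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(i - j).astype(int).ravel(), p.ravel())

    contrast = float(((i - j) ** 2 * p).sum())
    dissim = float((np.abs(i - j) * p).sum())
    energy = float((p**2).sum())
    entropy = float(-_xlog2(p).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((i * j * p).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        correlation = 0.0

    k_sum = np.arange(2 * n - 1, dtype=float)
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = float(-_xlog2(p_sum).sum())
    k_diff = np.arange(n, dtype=float)
    diff_mean = float((k_diff * p_diff).sum())
    diff_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    diff_entropy = float(-_xlog2(p_diff).sum())

    # information measures of correlation; entropies in bits for imc1,
    # the exponential form of imc2 uses nats
    pxy = px[:, None] * py[None, :]
    mask = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[mask] * np.log2(pxy[mask])).sum())
    mask2 = pxy > 0
    hxy2 = float(-(pxy[mask2] * np.log2(pxy[mask2])).sum())
    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    ln2 = np.log(2.0)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * ln2 * (hxy2 - entropy)))))

    abs_ij = np.abs(i - j)
    return {
        "glcm_autocorrelation": float((i * j * p).sum()),
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_cluster_prominence": float(((i + j - mu_x - mu_y) ** 4 * p).sum()),
        "glcm_cluster_shade": float(((i + j - mu_x - mu_y) ** 3 * p).sum()),
        "glcm_dissimilarity": dissim,
        "glcm_energy": energy,
        "glcm_entropy": entropy,
        "glcm_homogeneity": float((p / (1.0 + abs_ij)).sum()),
        "glcm_homogeneity_moment": float((p / (1.0 + (i - j) ** 2)).sum()),
        "glcm_max_probability": float(p.max()),
        "glcm_variance": float(((i - mu_x) ** 2 * p).sum()),
        "glcm_sum_average": sum_average,
        "glcm_sum_variance": sum_variance,
        "glcm_sum_entropy": sum_entropy,
        "glcm_difference_variance": diff_variance,
        "glcm_difference_entropy": diff_entropy,
        "glcm_imc1": imc1,
        "glcm_imc2": imc2,
        "glcm_inverse_difference": float((p / (1.0 + abs_ij)).sum()),
        "glcm_inverse_difference_norm": float((p / (1.0 + abs_ij / n)).sum()),
        "glcm_inverse_difference_moment_norm": float((p / (1.0 + (i - j) ** 2 / n**2)).sum()),
    }


# ---------------------------------------------------------------------------
# Hu moment invariants


def hu_moments(patch) -> np.ndarray:
    """The seven Hu invariants of the grayscale patch treated as a density.

    The patch is first divided by its maximum, making the invariants exact
    under uniform intensity scaling as well as translation and rotation.
    Then raw moments m_pq -> central moments mu_pq -> scale-normalized
    eta_pq = mu_pq / mu_00^(1+(p+q)/2) -> Hu's polynomial combinations.
    Rejects an all-zero patch (the normalization is undefined).
    """
    a = np.asarray(getattr(patch, "data", patch), dtype=float)
    if a.ndim != 2:
        raise ValueError("patch must be 2D")
    if a.max() <= 0 or a.sum() <= 0:
        raise ValueError("all-zero patch: Hu moments undefined")
    a = a / a.max()
    m00 = a.sum()
    y = np.arange(a.shape[0], dtype=float)[:, None]
    x = np.arange(a.shape[1], dtype=float)[None, :]
    xbar = (x * a).sum() / m00
    ybar = (y * a).sum() / m00

    def eta(pq_p: int, pq_q: int) -> float:
        mu = (((x - xbar) ** pq_p) * ((y - ybar) ** pq_q) * a).sum()
        return float(mu / m00 ** (1 + (pq_p + pq_q) / 2.0))

    n20, n02, n11 = eta(2, 0), eta(0, 2), eta(1, 1)
    n30, n03 = eta(3, 0), eta(0, 3)
    n21, n12 = eta(2, 1), eta(1, 2)

    phi1 = n20 + n02
    phi2 = (n20 - n02) ** 2 + 4 * n11**2
    phi3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    phi4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    phi5 = (n30 - 3 * n12) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2) + (
        3 * n21 - n03
    ) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    phi6 = (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4 * n11 * (n30 + n12) * (n21 + n03)
    phi7 = (3 * n21 - n03) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2) - (
        n30 - 3 * n12
    ) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    return np.array([phi1, phi2, phi3, phi4, phi5, phi6, phi7])


# ---------------------------------------------------------------------------
# Shape features


def shape_features(patch) -> dict[str, float]:
    """Region descriptors of the Otsu-binarized patch's largest component.

    A constant patch is treated as all-foreground; an empty foreground after
    thresholding yields an all-zero vector (with a warning).
    """
    a = np.asarray(getattr(patch, "data", patch), dtype=float)
    if np.ptp(a) == 0:
        fg = np.ones(a.shape, dtype=bool)
    else:
        fg = a > threshold_otsu(a)
    labels = label(fg, connectivity=2)
    if labels.max() == 0:
        warnings.warn("empty foreground after thresholding; shape features set to 0")
        return {name: 0.0 for name in SHAPE_FEATURE_NAMES}
    region = max(regionprops(labels), key=lambda r: r.area)
    area = float(region.area)
    perimeter = float(region.perimeter)
    major = float(region.axis_major_length)
    minor = float(region.axis_minor_length)
    return {
        "shape_area": area,
        "shape_perimeter": perimeter,
        "shape_major_axis": major,
        "shape_minor_axis": minor,
        "shape_eccentricity": float(region.eccentricity),
        "shape_solidity": float(region.solidity),
        "shape_aspect_ratio": major / minor if minor > 0 else 0.0,
        "shape_circularity": 4 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0,
        "shape_compactness": perimeter**2 / area,
        "shape_roundness": 4 * area / (np.pi * major**2) if major > 0 else 0.0,
        "shape_extent": float(region.extent),
    }


# ---------------------------------------------------------------------------
# Feature table


def build_feature_table(patches: Iterable[Patch], levels: int = 8,
                        offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS) -> pd.DataFrame:
    """One row per patch: the 40 named features plus label, row, col.

    Unlabeled patches get label -1.  An all-zero patch (no vessel signal at
    all) receives zero Hu invariants rather than an error, so background
    patches do not abort a batch.
    """
    patches = list(patches)
    if not patches:
        raise ValueError("need at least one patch")
    rows = []
    for patch in patches:
        feats = glcm_features(glcm(patch.data, levels=levels, offsets=offsets))
        feats.update(shape_features(patch.data))
        if patch.data.sum() == 0:
            hu = np.zeros(7)
        else:
            hu = hu_moments(patch.data)
        feats.update({name: float(v) for name, v in zip(MOMENT_FEATURE_NAMES, hu)})
        feats["label"] = -1 if patch.label is None else int(patch.label)
        feats["row"] = patch.row
        feats["col"] = patch.col
        rows.append(feats)
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["label", "row", "col"])
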