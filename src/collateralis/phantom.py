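"""Synthetic head CBCT phantom with voxel-level ground truth.

The generator emulates the image content the detection pipeline must cope
with: a bright ellipsoidal skull shell around a darker brain interior, a
smooth illumination bias field, thick bright low-curvature "normal" vessel
tubes, thin dim tortuous collateral tubes with diameters of 0.4-0.6 mm
(below the 0.762841 mm voxel spacing, so they are rendered by
partial-volume weighting), plus additive noise (Gaussian, speckle or
Poisson) and concentric ring artifacts.  Intensities live on a raw CBCT
scale with rescale tags slope 1 / intercept -1024, so the
brightness-adjustment and HU-conversion stages have real work to do.

Geometry and corruption draw from independent seeded streams, so the clean
signal of a given seed is unchanged by the noise settings.  The ground
truth labels every voxel whose center falls inside a tube or the shell
(0 background, 1 skull, 2 normal vessel, 3 collateral) and records each
centerline polyline in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .features import Patch
from .volume_io import CBCTVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "add_ring_artifact",
    "labelled_patch_sampler",
    "project_truth",
    "easy_spec",
    "LABEL_BACKGROUND",
    "LABEL_SKULL",
    "LABEL_NORMAL",
    "LABEL_COLLATERAL",
]

LABEL_BACKGROUND = 0
LABEL_SKULL = 1
LABEL_NORMAL = 2
LABEL_COLLATERAL = 3


@dataclass
class PhantomSpec:
    """Parameters of the synthetic head volume; defaults are the study conditions."""

    shape: tuple[int, int, int] = (64, 128, 128)  # slices, rows, cols
    voxel_mm: tuple[float, float, float] = (0.762841, 0.762841, 0.762841)
    # z radius exceeds the axial field of view: a mid-head acquisition where
    # every slice shows a skull ring rather than a polar cap
    skull_radii_mm: tuple[float, float, float] = (60.0, 44.0, 40.0)  # (z, y, x)
    skull_thickness_mm: float = 3.0
    skull_intensity: float = 900.0
    brain_intensity: float = 60.0
    bias_amplitude: float = 10.0
    n_normal: int = 5
    normal_radius_mm: float = 1.0
    normal_intensity: float = 600.0
    n_collateral: int = 8
    collateral_radius_range_mm: tuple[float, float] = (0.2, 0.3)
    collateral_intensity_factor: float = 0.6
    tortuosity_std_rad: float = 0.35
    collateral_step_mm: float = 1.5
    noise_type: str = "gaussian"
    noise_level: float = 5.0
    ring_count: int = 2
    ring_amplitude: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.shape) < 32:
            raise ValueError("grid must be at least 32 voxels in every axis")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel spacing must be positive")
        for name in ("skull_thickness_mm", "skull_intensity", "brain_intensity",
                     "bias_amplitude", "normal_radius_mm", "normal_intensity",
                     "noise_level", "ring_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.collateral_radius_range_mm
        if not (0 < lo <= hi):
            raise ValueError("collateral radius range must be positive and ordered")
        if hi >= self.normal_radius_mm:
            raise ValueError("collateral radius must be strictly below the normal radius")
        if not 0 <= self.collateral_intensity_factor < 1:
            raise ValueError("collateral intensity factor must lie in [0, 1)")
        if self.noise_type not in ("gaussian", "speckle", "poisson"):
            raise ValueError(f"unknown noise type {self.noise_type!r}")


@dataclass
class GroundTruth:
    """Voxel labels, per-vessel centerlines (mm) and the clean signal volume."""

    labels: np.ndarray
    centerlines: list[tuple[str, np.ndarray]]
    clean: np.ndarray = field(repr=False, default=None)


def easy_spec(**overrides) -> PhantomSpec:
    """The low-noise high-contrast condition used for end-to-end recovery runs."""
    spec = PhantomSpec(noise_level=1.0, ring_amplitude=5.0, collateral_intensity_factor=0.5)
    return replace(spec, **overrides)


# ---------------------------------------------------------------------------
# Geometry helpers


def _voxel_centers(shape, voxel_mm):
    return [np.arange(n, dtype=float) * d for n, d in zip(shape, voxel_mm)]


def _inside_ellipsoid(point_mm, center, radii, margin=0.0) -> bool:
    r = [max(rad - margin, 1e-6) for rad in radii]
    return sum(((p - c) / rr) ** 2 for p, c, rr in zip(point_mm, center, r)) < 1.0


def _normal_centerline(rng: np.random.Generator, center, inner_radii, radius_mm) -> np.ndarray:
    """Low-curvature cubic spline crossing the brain roughly in-plane."""
    margin = radius_mm + 3.0
    ry, rx = inner_radii[1] - margin, inner_radii[2] - margin
    theta = rng.uniform(0, np.pi)
    z0 = center[0] + rng.uniform(-0.55, 0.55) * inner_radii[0]
    # chord endpoints at 90% of the in-plane inner ellipse along direction theta
    dy, dx = np.sin(theta), np.cos(theta)
    scale = 0.9 / np.sqrt((dy / ry) ** 2 + (dx / rx) ** 2)
    p0 = np.array([z0, center[1] - dy * scale, center[2] - dx * scale])
    p1 = np.array([z0, center[1] + dy * scale, center[2] + dx * scale])
    # two interior control points with small perpendicular and axial offsets
    perp = np.array([0.0, dx, -dy])
    ctrl = []
    for t in (0.33, 0.66):
        offset = rng.normal(0, 4.0) * perp + np.array([rng.normal(0, 3.0), 0, 0])
        ctrl.append(p0 + t * (p1 - p0) + offset)
    knots = np.stack([p0, ctrl[0], ctrl[1], p1])
    spline = CubicSpline(np.linspace(0, 1, 4), knots, axis=0)
    pts = spline(np.linspace(0, 1, 160))
    # clamp inside the brain interior
    for k in range(pts.shape[0]):
        while not _inside_ellipsoid(pts[k], center, inner_radii, margin=radius_mm + 1.0):
            pts[k] = center + 0.95 * (pts[k] - center)
    return pts


def _collateral_centerline(rng: np.random.Generator, center, inner_radii, radius_mm,
                           step_mm: float, angle_std: float, length_mm: float = 90.0) -> np.ndarray:
    """Bounded random walk: tortuous, mostly in-plane, steered back toward center."""
    margin = radius_mm + 2.0
    start = None
    while start is None or not _inside_ellipsoid(start, center, inner_radii, margin=margin + 4.0):
        start = center + rng.uniform(-0.6, 0.6) * np.asarray(inner_radii)
    phi = rng.uniform(0, 2 * np.pi)
    direction = np.array([rng.normal(0, 0.2), np.sin(phi), np.cos(phi)])
    direction /= np.linalg.norm(direction)
    pts = [np.asarray(start, dtype=float)]
    n_steps = max(int(length_mm / step_mm), 8)
    for _ in range(n_steps):
        direction = direction + rng.normal(0, angle_std, size=3) * np.array([0.4, 1.0, 1.0])
        direction /= np.linalg.norm(direction)
        candidate = pts[-1] + step_mm * direction
        if not _inside_ellipsoid(candidate, center, inner_radii, margin=margin):
            # steer back toward the brain center
            direction = center - pts[-1]
            direction /= np.linalg.norm(direction)
            candidate = pts[-1] + step_mm * direction
        pts.append(candidate)
    return np.stack(pts)


def _rasterize_tube(shape, voxel_mm, polyline_mm, radius_mm, supersample=3):
    """Partial-volume fraction and center-inside mask of a tube around a polyline.

    The fraction of each boundary voxel intersected by the tube is estimated
    by a supersample^3 subgrid; voxels deeper inside than half a diagonal get
    fraction 1.
    """
    frac = np.zeros(shape, dtype=float)
    inside = np.zeros(shape, dtype=bool)
    spacing = np.asarray(voxel_mm)
    half_diag = np.linalg.norm(spacing) / 2.0
    offsets_1d = (np.arange(supersample) - (supersample - 1) / 2.0) / supersample
    sub = np.stack(np.meshgrid(*[offsets_1d * s for s in spacing], indexing="ij"), axis=-1).reshape(-1, 3)

    for p, q in zip(polyline_mm[:-1], polyline_mm[1:]):
        d = q - p
        seg_len2 = float(d @ d)
        lo_mm = np.minimum(p, q) - radius_mm - half_diag
        hi_mm = np.maximum(p, q) + radius_mm + half_diag
        lo = np.maximum(np.floor(lo_mm / spacing).astype(int), 0)
        hi = np.minimum(np.ceil(hi_mm / spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        grids = [np.arange(lo[a], hi[a], dtype=float) * spacing[a] for a in range(3)]
        zz, yy, xx = np.meshgrid(*grids, indexing="ij")
        pts = np.stack([zz, yy, xx], axis=-1)
        rel = pts - p
        if seg_len2 > 0:
            t = np.clip((rel @ d) / seg_len2, 0.0, 1.0)
        else:
            t = np.zeros(rel.shape[:-1])
        closest = p + t[..., None] * d
        dist = np.linalg.norm(pts - closest, axis=-1)

        sl = tuple(slice(lo[a], hi[a]) for a in range(3))
        inside[sl] |= dist <= radius_mm
        sure = dist <= radius_mm - half_diag
        boundary = (~sure) & (dist < radius_mm + half_diag)
        block = np.where(sure, 1.0, 0.0)
        if boundary.any():
            bpts = pts[boundary]  # (M, 3)
            spts = bpts[:, None, :] + sub[None, :, :]  # (M, S, 3)
            rel_s = spts - p
            if seg_len2 > 0:
                t_s = np.clip((rel_s @ d) / seg_len2, 0.0, 1.0)
            else:
                t_s = np.zeros(rel_s.shape[:-1])
            closest_s = p + t_s[..., None] * d
            dist_s = np.linalg.norm(spts - closest_s, axis=-1)
            block[boundary] = (dist_s <= radius_mm).mean(axis=1)
        np.maximum(frac[sl], block, out=frac[sl])
    return frac, inside


# ---------------------------------------------------------------------------
# Ring artifacts


def add_ring_artifact(image2d: np.ndarray, center: tuple[float, float],
                      radii, amplitude: float) -> np.ndarray:
    """Add a constant perturbation on one-pixel-wide annuli around ``center``.

    The output differs from the input only on the annuli; the mean absolute
    perturbation on each annulus equals ``amplitude`` exactly.
    """
    arr = np.asarray(image2d, dtype=float).copy()
    if not np.isfinite(amplitude):
        raise ValueError("amplitude must be finite")
    cy, cx = center
    rows, cols = arr.shape
    max_fit = min(cy, cx, rows - 1 - cy, cols - 1 - cx)
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    for r in radii:
        if r < 0:
            raise ValueError(f"negative ring radius {r}")
        if r > max_fit:
            raise ValueError(f"ring radius {r} does not fit in the image")
    if amplitude == 0:
        return arr
    yy, xx = np.ogrid[:rows, :cols]
    dist = np.hypot(yy - cy, xx - cx)
    for r in radii:
        arr[np.abs(dist - r) <= 0.5] += amplitude
    return arr


# ---------------------------------------------------------------------------
# Main generator


def generate_phantom(spec: PhantomSpec) -> tuple[CBCTVolume, GroundTruth]:
    """Render the phantom volume and its ground truth.

    The clean signal is background + bias + skull + vessels; ring artifacts
    and then noise corrupt it.  Equal (spec, seed) pairs give bit-identical
    output.
    """
    spec.validate()
    min_radius = spec.collateral_radius_range_mm[0]
    if (spec.n_normal > 0 or spec.n_collateral > 0) and min_radius < min(spec.voxel_mm) / 2:
        warnings.warn("sub-voxel vessel radius: tubes rendered by partial-volume intensity")

    geom_ss, corrupt_ss = np.random.SeedSequence(spec.seed).spawn(2)
    geom_rng = np.random.default_rng(geom_ss)
    corrupt_rng = np.random.default_rng(corrupt_ss)

    nz, ny, nx = spec.shape
    dz, dy, dx = spec.voxel_mm
    center = np.array([(nz - 1) * dz / 2, (ny - 1) * dy / 2, (nx - 1) * dx / 2])
    z, y, x = _voxel_centers(spec.shape, spec.voxel_mm)
    zz = ((z - center[0]) / spec.skull_radii_mm[0]) ** 2
    yy = ((y - center[1]) / spec.skull_radii_mm[1]) ** 2
    xx = ((x - center[2]) / spec.skull_radii_mm[2]) ** 2
    q_outer = zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
    inner_radii = tuple(r - spec.skull_thickness_mm for r in spec.skull_radii_mm)
    zi = ((z - center[0]) / inner_radii[0]) ** 2
    yi = ((y - center[1]) / inner_radii[1]) ** 2
    xi = ((x - center[2]) / inner_radii[2]) ** 2
    q_inner = zi[:, None, None] + yi[None, :, None] + xi[None, None, :]
    shell = (q_outer <= 1.0) & (q_inner >= 1.0)
    brain = q_inner < 1.0

    # smooth in-plane illumination bias: broad Gaussian at a seeded offset
    by = center[1] + geom_rng.uniform(-20.0, 20.0)
    bx = center[2] + geom_rng.uniform(-20.0, 20.0)
    sigma_mm = 40.0
    bias2d = spec.bias_amplitude * np.exp(
        -((y[:, None] - by) ** 2 + (x[None, :] - bx) ** 2) / (2 * sigma_mm**2)
    )

    signal = np.zeros(spec.shape, dtype=float)
    signal[brain] = spec.brain_intensity + np.broadcast_to(bias2d, spec.shape)[brain]
    signal[shell] = spec.skull_intensity
    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[shell] = LABEL_SKULL

    # confine vessels to the axial field of view even when the brain extends past it
    z_half = (nz - 1) * dz / 2.0
    vessel_radii = (min(inner_radii[0], z_half - 4.0), inner_radii[1], inner_radii[2])
    centerlines: list[tuple[str, np.ndarray]] = []
    vessels: list[tuple[str, np.ndarray, float, float]] = []
    for _ in range(spec.n_normal):
        line = _normal_centerline(geom_rng, center, vessel_radii, spec.normal_radius_mm)
        vessels.append(("normal", line, spec.normal_radius_mm, spec.normal_intensity))
    for _ in range(spec.n_collateral):
        radius = geom_rng.uniform(*spec.collateral_radius_range_mm)
        line = _collateral_centerline(
            geom_rng, center, vessel_radii, radius, spec.collateral_step_mm, spec.tortuosity_std_rad
        )
        vessels.append(("collateral", line, radius, spec.collateral_intensity_factor * spec.normal_intensity))

    extent = (np.asarray(spec.shape) - 1) * np.asarray(spec.voxel_mm)
    for kind, line, radius, intensity in vessels:
        line = np.clip(line, 0.0, extent)  # centerline points stay inside the grid
        centerlines.append((kind, line))
        frac, inside = _rasterize_tube(spec.shape, spec.voxel_mm, line, radius)
        signal += frac * np.maximum(intensity - signal, 0.0)
        labels[inside] = LABEL_NORMAL if kind == "normal" else LABEL_COLLATERAL

    clean = signal.copy()

    corrupted = signal
    if spec.ring_count > 0 and spec.ring_amplitude > 0:
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        max_fit = min(cy, cx)
        radii = corrupt_rng.uniform(8.0, max_fit - 1.0, size=spec.ring_count)
        ring_slice = add_ring_artifact(np.zeros((ny, nx)), (cy, cx), radii, spec.ring_amplitude)
        corrupted = corrupted + ring_slice[None, :, :]

    if spec.noise_level > 0:
        if spec.noise_type == "gaussian":
            corrupted = corrupted + spec.noise_level * corrupt_rng.standard_normal(spec.shape)
        elif spec.noise_type == "speckle":
            corrupted = corrupted * (1.0 + spec.noise_level * corrupt_rng.standard_normal(spec.shape))
        else:  # poisson: variance proportional to intensity * level
            lam = np.maximum(corrupted, 0.0) / spec.noise_level
            corrupted = corrupt_rng.poisson(lam).astype(float) * spec.noise_level

    volume = CBCTVolume(
        data=corrupted,
        slice_thickness_mm=dz,
        pixel_spacing_mm=(dy, dx),
        # display-style rescale: brain background lands near soft-tissue values
        # after brightness adjustment, air slightly negative
        rescale_slope=1.0,
        rescale_intercept=-250.0,
        rescale_from_tags=True,
        provenance=f"phantom seed={spec.seed}",
    )
    return volume, GroundTruth(labels=labels, centerlines=centerlines, clean=clean)


# ---------------------------------------------------------------------------
# Truth projection and patch sampling


def project_truth(labels: np.ndarray, first: int, last: int) -> np.ndarray:
    """Maximum-priority label projection over slices [first, last] inclusive.

    The numeric label order (collateral 3 > normal 2 > skull 1 > background)
    is the projection priority, mirroring which projected voxel dominates
    the MIP.
    """
    return np.asarray(labels)[first : last + 1].max(axis=0)


def labelled_patch_sampler(mip_image, truth_projection: np.ndarray, n_per_class: int,
                           block: int = 16, seed: int = 0) -> list[Patch]:
    """Sample labeled patches centered on vessel pixels of a truth projection.

    Returns ``n_per_class`` patches centered on collateral-labeled pixels
    (class 1) and as many centered on normal-vessel pixels (class 0).  Patch
    centers within a class are at least one block apart (Chebyshev); the
    selection is deterministic under the seed.

    Centers whose surrounding block contains no pixel of the *other* vessel
    class are preferred, emulating expert-marked regions of interest that
    contain either a collateral or a normal vessel; mixed-neighbourhood
    centers are used only when pure ones run out.
    """
    from scipy.ndimage import maximum_filter

    arr = np.asarray(getattr(mip_image, "data", mip_image), dtype=float)
    truth = np.asarray(truth_projection)
    if arr.shape != truth.shape:
        raise ValueError("truth projection must align with the MIP image")
    rng = np.random.default_rng(seed)
    half = block // 2
    rows, cols = arr.shape
    patches: list[Patch] = []
    for cls, lbl, other, name in (
        (1, LABEL_COLLATERAL, LABEL_NORMAL, "collateral"),
        (0, LABEL_NORMAL, LABEL_COLLATERAL, "normal"),
    ):
        cand = np.argwhere(truth == lbl)
        cand = cand[
            (cand[:, 0] >= half) & (cand[:, 0] <= rows - block + half)
            & (cand[:, 1] >= half) & (cand[:, 1] <= cols - block + half)
        ]
        if len(cand) == 0:
            raise ValueError(f"no labeled pixels available for class {name!r}")
        near_other = maximum_filter((truth == other).astype(np.uint8), size=block) > 0
        pure = cand[~near_other[cand[:, 0], cand[:, 1]]]
        mixed = cand[near_other[cand[:, 0], cand[:, 1]]]
        cand = np.concatenate(
            [pure[rng.permutation(len(pure))], mixed[rng.permutation(len(mixed))]]
        )
        chosen: list[np.ndarray] = []
        for rc in cand:
            if all(np.max(np.abs(rc - prev)) >= block for prev in chosen):
                chosen.append(rc)
            if len(chosen) == n_per_class:
                break
        if len(chosen) < n_per_class:
            raise ValueError(
                f"insufficient labeled pixels for class {name!r}: "
                f"requested {n_per_class}, found {len(chosen)} separated centers"
            )
        for r, c in chosen:
            r0, c0 = r - half, c - half
            patches.append(Patch(arr[r0 : r0 + block, c0 : c0 + block], int(r0), int(c0), label=cls))
    return patches
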