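"""Input/output for the pipeline's standard formats.

Reads axial DICOM series into :class:`CBCTVolume` containers, writes phantom
volumes back out as one-file-per-slice DICOM, and persists 2D images (16-bit
PNG with an invertible affine sidecar), feature tables (CSV) and evaluation
reports (JSON) together with a hashed manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import pydicom
from PIL import Image
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

__all__ = [
    "CBCTVolume",
    "Image2D",
    "read_dicom_series",
    "write_dicom_series",
    "write_outputs",
    "load_png",
]


@dataclass
class Image2D:
    """A single 2D intensity image with a declared value-range convention.

    ``value_range`` is one of ``"raw"`` (scanner units), ``"HU"`` (Hounsfield)
    or ``"normalized"`` (unitless, typically [0, 1]).
    """

    data: np.ndarray
    value_range: str = "raw"
    provenance: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"Image2D expects a 2D array, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Image2D contains non-finite values")
        if self.value_range not in ("raw", "HU", "normalized"):
            raise ValueError(f"unknown value_range {self.value_range!r}")


@dataclass
class CBCTVolume:
    """A 3D CBCT intensity stack (slices x rows x cols) with rescale metadata.

    ``rescale_slope``/``rescale_intercept`` are the DICOM (0028,1053) and
    (0028,1052) values used to map stored values to Hounsfield units; when a
    series carries no rescale tags the stored values are already in the
    default HU unit and ``rescale_from_tags`` is False (slope 1, intercept 0).
    """

    data: np.ndarray
    slice_thickness_mm: float
    pixel_spacing_mm: tuple[float, float] = (0.762841, 0.762841)
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    rescale_from_tags: bool = True
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if not self.slice_thickness_mm > 0:
            raise ValueError("slice thickness must be positive")
        if self.rescale_slope == 0:
            raise ValueError("rescale slope must be nonzero")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


def read_dicom_series(directory: str | Path) -> CBCTVolume:
    """Read a directory of single-frame DICOM files as one sorted volume.

    Slices are ordered by the z component of ImagePositionPatient, falling
    back to InstanceNumber, so the result is independent of directory listing
    order.  Missing rescale tags mean the stored values are already HU
    (slope 1, intercept 0) and are flagged via ``rescale_from_tags=False``.
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ""))
    datasets = []
    for p in paths:
        try:
            ds = pydicom.dcmread(p)
        except Exception as exc:  # pragma: no cover - exercised via error path test
            raise ValueError(f"unreadable DICOM file: {p}") from exc
        if "PixelData" in ds:
            datasets.append(ds)
    if len(datasets) < 2:
        raise ValueError(f"need at least 2 DICOM slices in {directory}, found {len(datasets)}")

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise ValueError(f"mixed slice sizes in series: {sorted(shapes)}")

    def sort_key(ds: Dataset) -> float:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    stack = np.stack([ds.pixel_array.astype(float) for ds in datasets])

    first = datasets[0]
    has_tags = hasattr(first, "RescaleSlope") and hasattr(first, "RescaleIntercept")
    rs = float(getattr(first, "RescaleSlope", 1.0))
    ri = float(getattr(first, "RescaleIntercept", 0.0))
    thickness = float(getattr(first, "SliceThickness", 1.0))
    spacing = getattr(first, "PixelSpacing", [1.0, 1.0])
    return CBCTVolume(
        data=stack,
        slice_thickness_mm=thickness,
        pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
        rescale_slope=rs,
        rescale_intercept=ri,
        rescale_from_tags=has_tags,
        provenance=str(directory),
    )


def write_dicom_series(volume: CBCTVolume, directory: str | Path) -> list[Path]:
    """Write a volume as a DICOM series, one int16 file per axial slice.

    Pixel data is rounded to signed 16-bit integers; the rescale tags carry
    the volume's slope/intercept.  Returns the written paths in slice order.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = np.rint(volume.data).astype(np.int16)
    series_uid = generate_uid()
    study_uid = generate_uid()
    paths = []
    for i in range(volume.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientName = "PHANTOM"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * volume.slice_thickness_mm]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceThickness = volume.slice_thickness_mm
        ds.PixelSpacing = [volume.pixel_spacing_mm[0], volume.pixel_spacing_mm[1]]
        ds.RescaleSlope = volume.rescale_slope
        ds.RescaleIntercept = volume.rescale_intercept
        ds.Rows, ds.Columns = data.shape[1:]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.PixelData = data[i].tobytes()
        path = directory / f"slice_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def _write_png16(image: Image2D | np.ndarray, path: Path) -> None:
    """Store an image as min-max scaled 16-bit PNG + JSON sidecar with the affine map."""
    arr = image.data if isinstance(image, Image2D) else np.asarray(image, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    scale = hi - lo
    if scale == 0:
        scaled = np.zeros(arr.shape, dtype=np.uint16)
    else:
        scaled = np.rint((arr - lo) / scale * 65535.0).astype(np.uint16)
    Image.fromarray(scaled).save(path)
    sidecar = {
        "min": lo,
        "max": hi,
        "value_range": image.value_range if isinstance(image, Image2D) else "raw",
        "provenance": image.provenance if isinstance(image, Image2D) else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_png(path: str | Path) -> Image2D:
    """Invert :func:`_write_png16` using its sidecar, restoring the affine scale."""
    path = Path(path)
    arr = np.asarray(Image.open(path), dtype=float)
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sc = json.loads(sidecar_path.read_text())
        lo, hi = sc["min"], sc["max"]
        arr = arr / 65535.0 * (hi - lo) + lo
        return Image2D(arr, value_range=sc.get("value_range", "raw"), provenance=sc.get("provenance"))
    return Image2D(arr, value_range="raw", provenance=str(path))


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def write_outputs(objects: Mapping[str, Any], directory: str | Path, overwrite: bool = False) -> dict:
    """Persist a mapping of named pipeline artifacts and return a hashed manifest.

    Dispatch by type: :class:`Image2D`/2D arrays become 16-bit PNGs with
    sidecars, DataFrames become CSV (RFC-4180 quoting), everything else is
    serialized as JSON.  Refuses to clobber an existing manifest unless
    ``overwrite`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"manifest already present at {manifest_path}; pass overwrite=True")

    files: list[Path] = []
    for name, obj in objects.items():
        if isinstance(obj, Image2D) or (isinstance(obj, np.ndarray) and obj.ndim == 2):
            path = directory / f"{name}.png"
            _write_png16(obj, path)
            files.extend([path, path.with_suffix(".json")])
        elif isinstance(obj, pd.DataFrame):
            path = directory / f"{name}.csv"
            obj.to_csv(path, index=False)
            files.append(path)
        else:
            path = directory / f"{name}.json"
            path.write_text(json.dumps(_jsonable(obj), indent=1))
            files.append(path)

    manifest = {
        "files": [
            {"name": p.name, "sha256": hashlib.sha256(p.read_bytes()).hexdigest()}
            for p in sorted(files)
        ]
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
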