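"""Read and write CT volumes: DICOM CT series and an internal format.

HU normalization is always applied on read (``slope · stored + intercept``);
the analyzers never see stored pixel values.  Only the DICOM tags needed for
geometry and rescaling are handled — this is not a conformance layer.

The internal format is a single ``.npz`` holding the HU array, spacing,
origin and a JSON metadata sidecar entry; the round trip is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .volume import HU_MIN, VolumeGrid

#: Allowed wobble in inter-slice spacing before a series is rejected (mm).
SLICE_SPACING_TOLERANCE = 0.01


class SeriesError(RuntimeError):
    """Raised for unreadable, mixed or geometrically inconsistent series."""


@dataclass
class SeriesMeta:
    spacing: tuple[float, float, float]
    slice_positions: list[float]
    rescale_slope: float
    rescale_intercept: float
    kvp: Optional[float] = None
    exposure_mas: Optional[float] = None
    source_id: str = ""
    extra: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------


def read_ct_series(path: str | Path) -> tuple[VolumeGrid, SeriesMeta]:
    """Read a directory of axial CT slices belonging to one series.

    Slices are sorted by position along z; stored values are mapped to HU.

    Raises
    ------
    SeriesError
        On mixed series identifiers, non-uniform slice spacing beyond
        tolerance, or missing rescale tags.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".ima"})
    if not files:
        raise SeriesError(f"no DICOM slice files in {path}")
    datasets = [pydicom.dcmread(f) for f in files]

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) != 1:
        raise SeriesError(f"mixed series identifiers: {sorted(uids)}")
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise SeriesError("missing rescale slope/intercept tags")

    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(zs) > 1:
        steps = np.diff(zs)
        if steps.max() - steps.min() > SLICE_SPACING_TOLERANCE or steps.min() <= 0:
            raise SeriesError(f"non-uniform slice spacing: steps {np.unique(steps)}")
        dz = float(steps.mean())
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))

    first = datasets[0]
    dy, dx = (float(v) for v in first.PixelSpacing)
    hu = np.stack(
        [
            ds.pixel_array.astype(np.float32) * float(ds.RescaleSlope)
            + float(ds.RescaleIntercept)
            for ds in datasets
        ]
    )
    origin = (
        float(first.ImagePositionPatient[2]),
        float(first.ImagePositionPatient[1]),
        float(first.ImagePositionPatient[0]),
    )
    meta = SeriesMeta(
        spacing=(dz, dy, dx),
        slice_positions=[float(z) for z in zs],
        rescale_slope=float(first.RescaleSlope),
        rescale_intercept=float(first.RescaleIntercept),
        kvp=float(first.KVP) if "KVP" in first else None,
        exposure_mas=float(first.Exposure) if "Exposure" in first else None,
        source_id=str(uids.pop()),
    )
    volume = VolumeGrid(hu, meta.spacing, origin, {"series": meta.source_id})
    return volume, meta


def write_dicom_series(
    volume: VolumeGrid,
    path: str | Path,
    *,
    kvp: Optional[float] = None,
    exposure_mas: Optional[float] = None,
) -> list[Path]:
    """Write a volume as a DICOM CT series, one file per axial slice.

    Stored values are ``HU − intercept`` with rescale slope 1 and intercept
    −1024 (values are rounded to integers; the internal format is the
    lossless path).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dz, dy, dx = volume.spacing
    series_uid = generate_uid()
    intercept = HU_MIN
    written = []
    for k in range(volume.shape[0]):
        stored = np.round(volume.values[k] - intercept).astype(np.uint16)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            volume.origin[2],
            volume.origin[1],
            volume.origin[0] + k * dz,
        ]
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = dz
        ds.Rows, ds.Columns = stored.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = int(intercept)
        if kvp is not None:
            ds.KVP = kvp
        if exposure_mas is not None:
            ds.Exposure = exposure_mas
        ds.PixelData = stored.tobytes()
        out = path / f"slice_{k:04d}.dcm"
        ds.save_as(out, enforce_file_format=True)
        written.append(out)
    return written


# ---------------------------------------------------------------------------
# internal format
# ---------------------------------------------------------------------------


def write_volume(volume: VolumeGrid, path: str | Path) -> Path:
    """Lossless array-on-disk dump (``.npz`` with a JSON metadata entry)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    meta = {k: v for k, v in volume.meta.items() if _json_safe(v)}
    np.savez(
        path,
        values=volume.values,
        spacing=np.asarray(volume.spacing),
        origin=np.asarray(volume.origin),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )
    return path


def read_volume(path: str | Path) -> VolumeGrid:
    path = Path(path)
    try:
        with np.load(path) as npz:
            values = npz["values"]
            spacing = tuple(npz["spacing"])
            origin = tuple(npz["origin"])
            meta = json.loads(npz["meta"].tobytes().decode()) if "meta" in npz else {}
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as err:
        raise SeriesError(f"cannot read volume {path}: {err}") from err
    return VolumeGrid(values, spacing, origin, meta)


def _json_safe(v: Any) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
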