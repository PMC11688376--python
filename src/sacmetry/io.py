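"""Readers/writers for the formats the pipeline touches, the preprocessing
crop, and the end-to-end record pipeline (segmentation -> biometry -> report).

Masks and images travel as PNG/TIFF (any nonzero pixel is foreground) or
``.npy`` grids; spacing comes from the DICOM PixelSpacing tag (0028,0030),
stored in mm and converted to cm/px at ingestion, or from a JSON sidecar
``{"row_spacing_mm": x, "col_spacing_mm": y}``.

DICOM stores row spacing first; the literal assignment in the reference
algorithm reads the first entry as the column spacing.  ``spacing_order``
selects between the DICOM standard (default) and that literal reading --
they coincide whenever spacing is isotropic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .biometry import PixelSpacing, run_biometry
from .metrics import AgreementStats, agreement

logger = logging.getLogger("sacmetry")

__all__ = ["StudyRecord", "read_mask", "read_study", "write_dicom",
           "crop_to_input", "run_pipeline", "CROP_SIZE"]

CROP_SIZE = 512


@dataclass
class StudyRecord:
    """One case: image and/or mask, spacing, and optional clinical fields."""

    case_id: str
    spacing: PixelSpacing | None = None
    image: np.ndarray | None = None
    mask: np.ndarray | None = None
    clinician_gw: float | None = None
    label: str | None = None


def _read_image_file(path: Path) -> np.ndarray:
    if path.suffix.lower() == ".npy":
        return np.load(path)
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) to grayscale
        arr = arr[..., :3].mean(axis=-1)
    return arr


def read_mask(path) -> np.ndarray:
    """Load a binary mask; any nonzero pixel counts as foreground."""
    arr = _read_image_file(Path(path))
    return (arr != 0).astype(np.uint8)


def _spacing_from_pair(first_mm: float, second_mm: float,
                       spacing_order: str) -> PixelSpacing:
    if spacing_order == "dicom":
        row_mm, col_mm = first_mm, second_mm
    elif spacing_order == "paper":
        col_mm, row_mm = first_mm, second_mm
    else:
        raise ValueError("spacing_order must be 'dicom' or 'paper'")
    return PixelSpacing.from_mm(row_mm, col_mm)


def read_study(path, sidecar=None, spacing_order: str = "dicom") -> StudyRecord:
    """Load one study: grayscale pixel grid plus pixel spacing in cm/px.

    ``path`` is either a DICOM file (PixelSpacing tag required) or an
    image/``.npy`` file accompanied by a JSON sidecar.  A missing tag or
    sidecar raises with the missing element named.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom") or _looks_like_dicom(path):
        import pydicom

        ds = pydicom.dcmread(path)
        if "PixelSpacing" not in ds:
            raise ValueError(
                f"{path.name}: DICOM is missing PixelSpacing (0028,0030) "
                "and no sidecar was given")
        ps = [float(v) for v in ds.PixelSpacing]
        spacing = _spacing_from_pair(ps[0], ps[1], spacing_order)
        image = ds.pixel_array.astype(np.float64)
        return StudyRecord(case_id=path.stem, spacing=spacing, image=image)

    if sidecar is None:
        sidecar = path.with_suffix(".json")
    sidecar = Path(sidecar)
    if not sidecar.exists():
        raise ValueError(f"{path.name}: no spacing sidecar found at {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        spacing = PixelSpacing.from_mm(meta["row_spacing_mm"],
                                       meta["col_spacing_mm"])
    except KeyError as exc:
        raise ValueError(f"{sidecar.name}: sidecar missing key {exc}") from exc
    record = StudyRecord(case_id=path.stem, spacing=spacing,
                         image=_read_image_file(path).astype(np.float64))
    if "clinician_gw" in meta:
        record.clinician_gw = float(meta["clinician_gw"])
    return record


def _looks_like_dicom(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def write_dicom(path, image: np.ndarray, row_spacing_mm: float,
                col_spacing_mm: float) -> None:
    """Write a minimal secondary-capture DICOM (fixture/round-trip use)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    arr = np.asarray(image)
    if arr.dtype != np.uint16:
        arr = arr.astype(np.uint16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.Rows, ds.Columns = arr.shape
    ds.PixelSpacing = [f"{row_spacing_mm:g}", f"{col_spacing_mm:g}"]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = arr.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def crop_to_input(image: np.ndarray, size: int = CROP_SIZE,
                  anchor: tuple[int, int] | None = None
                  ) -> tuple[np.ndarray, tuple[int, int]]:
    """Crop an acquisition frame (e.g. 720x960) to the network's size.

    Default anchor centers the window; an explicit ``anchor=(r0, c0)`` gives
    the top-left corner.  Returns the crop and the ``(r0, c0)`` actually
    used, so biometry corner coordinates can be mapped back:
    ``crop[0, 0] == image[r0, c0]``.  Images smaller than ``size`` in either
    dimension are rejected (no upscaling).
    """
    arr = np.asarray(image)
    H, W = arr.shape[:2]
    if H < size or W < size:
        raise ValueError(f"image {H}x{W} smaller than crop size {size}; "
                         "upscaling is not supported")
    if anchor is None:
        r0, c0 = (H - size) // 2, (W - size) // 2
    else:
        r0, c0 = int(anchor[0]), int(anchor[1])
        if not (0 <= r0 <= H - size and 0 <= c0 <= W - size):
            raise ValueError(f"anchor {(r0, c0)} puts the {size}x{size} window "
                             f"outside the {H}x{W} image")
    return arr[r0:r0 + size, c0:c0 + size], (r0, c0)


def run_pipeline(records, network=None, threshold: float = 0.5
                 ) -> tuple[pd.DataFrame, AgreementStats | None, list[str]]:
    """Chain segmentation (optional) and biometry over a cohort.

    Each record needs ``spacing`` plus either a precomputed ``mask`` or an
    ``image`` to be segmented by ``network``.  Per-case failures are logged
    and skipped; the failed case ids are returned so callers can signal
    partial success.  When >= 2 successful cases carry ``clinician_gw``,
    Bland-Altman agreement (automated - clinician) is computed over them.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to process")
    rows, failures, pairs = [], [], []
    for rec in records:
        try:
            if rec.spacing is None:
                raise ValueError("record has no pixel spacing")
            mask = rec.mask
            if mask is None:
                if network is None or rec.image is None:
                    raise ValueError("record has no mask and no "
                                     "network/image to produce one")
                from .models import predict_mask

                mask = predict_mask(network, rec.image, threshold=threshold)
            result = run_biometry(mask, rec.spacing)
            rows.append({"case_id": rec.case_id,
                         "DM_cm": result.DM_cm,
                         "Dm_cm": result.Dm_cm,
                         "GW_weeks": result.GW_weeks})
            if rec.clinician_gw is not None:
                pairs.append((rec.clinician_gw, result.GW_weeks))
            logger.info("case %s: DM=%.3f cm Dm=%.3f cm GW=%.2f wk",
                        rec.case_id, result.DM_cm, result.Dm_cm,
                        result.GW_weeks)
        except Exception as exc:  # noqa: BLE001 - per-case isolation
            failures.append(rec.case_id)
            logger.warning("case %s failed: %s", rec.case_id, exc)
    report = pd.DataFrame(rows, columns=["case_id", "DM_cm", "Dm_cm",
                                         "GW_weeks"])
    stats = agreement(pairs) if len(pairs) >= 2 else None
    return report, stats, failures
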