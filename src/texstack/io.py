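"""Dataset layout on disk: NIfTI volumes, PNG tiles, CSV manifest.

Layout under an output directory::

    manifest.csv                    patient roster + exclusion flags + labels
    provenance.json                 generator params, config, seeds
    mri/<pid>_<sequence>.nii.gz     one volume per sequence
    mri/<pid>_mask.nii.gz           ROI mask on the DWI grid
    pathology/<pid>.png             H&E tile (8-bit), plus _h.png / _e.png
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import RoiMask, Volume
from .synth import CohortRecord

__all__ = [
    "write_volume",
    "read_volume",
    "write_mask",
    "read_mask",
    "write_tile",
    "read_tile",
    "write_manifest",
    "read_manifest",
    "write_provenance",
]

MANIFEST_COLUMNS = [
    "patient_id",
    "has_complete_sequences",
    "has_egfr_result",
    "ihc_percent_positive",
    "egfr_status",
    "split",
]


def _affine(spacing, origin) -> np.ndarray:
    # Our (slice,row,col) axes map to a diagonal affine; orientation codes
    # are irrelevant for synthetic data as long as write/read round-trips.
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: Volume, path: Path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.spacing_mm, volume.origin_mm))
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def read_volume(path: Path, sequence: str | None = None) -> Volume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in np.asarray(img.affine)[:3, 3])
    return Volume(np.asarray(img.dataobj, dtype=float), spacing, origin, sequence)


def write_mask(mask: RoiMask, path: Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing_mm, mask.origin_mm))
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))


def read_mask(path: Path) -> RoiMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in np.asarray(img.affine)[:3, 3])
    return RoiMask(np.asarray(img.dataobj) != 0, spacing, origin)


def write_tile(tile: np.ndarray, path: Path) -> None:
    """Quantize a [0, 1] RGB tile to 8 bits and write a PNG."""
    quantized = np.clip(np.round(np.asarray(tile) * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(str(path), quantized)


def read_tile(path: Path) -> np.ndarray:
    """Read a PNG tile back onto the [0, 1] scale."""
    return iio.imread(str(path)).astype(float) / 255.0


def write_manifest(records: list[CohortRecord], path: Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "has_complete_sequences": r.has_complete_sequences,
                "has_egfr_result": r.has_egfr_result,
                "ihc_percent_positive": (
                    "" if r.ihc_percent_positive is None else f"{r.ihc_percent_positive:.6f}"
                ),
                "egfr_status": r.egfr_status or "",
                "split": r.split,
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path: Path) -> list[CohortRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        percent = row["ihc_percent_positive"]
        records.append(
            CohortRecord(
                patient_id=row["patient_id"],
                has_complete_sequences=str(row["has_complete_sequences"]) == "True",
                has_egfr_result=str(row["has_egfr_result"]) == "True",
                ihc_percent_positive=float(percent) if percent != "" else None,
                egfr_status=row["egfr_status"] or None,
                split=row["split"] or "unassigned",
            )
        )
    return records


def write_provenance(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
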