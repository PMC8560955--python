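"""NIfTI volume / mask I/O, bounding-box CSV, config echo and manifests.

Volumes travel as NIfTI with the voxel spacing carried in the header
zooms; masks are uint8 NIfTI on the same grid.  Feature tables are tidy
CSV (see :mod:`lesionsr.radiomics.table`).  Every pipeline output
directory receives a JSON manifest (config echo, seeds, input hashes)
sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CTVolume",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_bboxes",
    "write_bboxes",
    "write_manifest",
    "read_manifest",
    "file_sha256",
]


@dataclass(frozen=True)
class CTVolume:
    """HU-valued 3D array with voxel spacing (mm) and affine orientation."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")


def write_volume(vol: CTVolume | np.ndarray, path: str | Path,
                 spacing_mm: tuple[float, float, float] | None = None) -> None:
    if isinstance(vol, CTVolume):
        data, spacing, affine = vol.data, vol.spacing_mm, vol.affine
    else:
        data = np.asarray(vol)
        spacing = spacing_mm or (1.0, 1.0, 1.0)
        affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> CTVolume:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:  # malformed header or file
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    return CTVolume(
        data=data,
        spacing_mm=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine),
    )


def write_mask(mask: np.ndarray, path: str | Path,
               spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8),
                          np.diag(list(spacing_mm) + [1.0]))
    img.header.set_zooms(spacing_mm)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    vol = read_volume(path)
    data = vol.data
    uniques = np.unique(data)
    if not np.all(np.isin(uniques, (0, 1))):
        raise ValueError(f"mask {path} is not binary (values {uniques[:5]}...)")
    return data.astype(bool)


BBOX_COLUMNS = ["volume_id", "slice", "y_lo", "x_lo", "y_hi", "x_hi"]


def write_bboxes(rows: list[tuple], path: str | Path) -> None:
    pd.DataFrame(rows, columns=BBOX_COLUMNS).to_csv(path, index=False)


def read_bboxes(path: str | Path) -> list[tuple]:
    df = pd.read_csv(path)
    missing = set(BBOX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"bbox CSV missing columns: {sorted(missing)}")
    return [
        (str(r.volume_id), int(r.slice), int(r.y_lo), int(r.x_lo),
         int(r.y_hi), int(r.x_hi))
        for r in df.itertuples()
    ]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: dict, seeds: dict,
                   inputs: dict[str, str] | None = None) -> Path:
    """Write the reproducibility manifest for an output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "seeds": seeds,
        "input_hashes": inputs or {},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_manifest(out_dir: str | Path) -> dict:
    return json.loads((Path(out_dir) / "manifest.json").read_text())
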