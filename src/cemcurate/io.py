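"""Readers, writers, and the JSON-lines corpus manifest.

Supported inputs: single/multi-page TIFF, PNG, JPEG (2D); multi-page
TIFF, MRC (voxel size from the header cell), NIfTI (spacing from pixdim)
(3D). A sidecar ``<file>.json`` next to any input may supply
``spacing_nm`` and ``inverted`` when the container has no metadata.

MRC cell dimensions follow the crystallographic convention (Angstrom)
and are converted to nanometers on read; NIfTI pixdim values are taken
as nanometers as-is.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Optional

import gemmi
import nibabel as nib
import numpy as np
import tifffile
from PIL import Image

from .types import Patch, PatchRecord, SourceImage

IMAGE_2D_SUFFIXES = {".png", ".jpg", ".jpeg"}


def _sidecar(path: Path) -> dict:
    side = path.with_suffix(path.suffix + ".json")
    if side.exists():
        with open(side) as fh:
            return json.load(fh)
    return {}


def load_source(path, source_id: Optional[str] = None) -> SourceImage:
    """Read one 2D image or 3D volume with whatever spacing is available."""
    path = Path(path)
    sid = source_id or path.stem.replace(".nii", "")
    meta = _sidecar(path)
    spacing = meta.get("spacing_nm")
    inverted = bool(meta.get("inverted", False))
    suffix = path.suffix.lower()
    name = path.name.lower()

    if suffix in IMAGE_2D_SUFFIXES:
        pixels = np.asarray(Image.open(path).convert("L"))
    elif suffix in {".tif", ".tiff"}:
        pixels = tifffile.imread(path)
        if pixels.ndim == 3 and pixels.shape[-1] in (3, 4) and pixels.shape[0] > 4:
            pixels = pixels[..., 0]  # RGB page stored channel-last
    elif suffix == ".mrc":
        m = gemmi.read_ccp4_map(str(path))
        pixels = np.array(m.grid, copy=True).transpose(2, 1, 0)  # -> (z, y, x)
        sp = m.grid.spacing  # Angstrom per voxel along x, y, z
        if spacing is None and all(s > 0 for s in sp):
            spacing = (sp[2] / 10.0, sp[1] / 10.0, sp[0] / 10.0)
    elif name.endswith(".nii") or name.endswith(".nii.gz"):
        img = nib.load(str(path))
        pixels = np.asanyarray(img.dataobj).transpose(2, 1, 0)  # (x,y,z)->(z,y,x)
        zooms = img.header.get_zooms()[:3]
        if spacing is None and all(z > 0 for z in zooms):
            spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    else:
        raise ValueError(f"unsupported input format: {path.name}")

    return SourceImage(source_id=sid, pixels=pixels,
                       spacing_nm=spacing, inverted=inverted)


def discover_sources(input_dir) -> List[Path]:
    """All readable source files in a directory, sorted for determinism."""
    input_dir = Path(input_dir)
    exts = IMAGE_2D_SUFFIXES | {".tif", ".tiff", ".mrc"}
    files = [p for p in sorted(input_dir.iterdir())
             if p.suffix.lower() in exts
             or p.name.lower().endswith((".nii", ".nii.gz"))]
    return files


def write_mrc(volume: np.ndarray, path, spacing_nm=(10.0, 10.0, 10.0)):
    """Write a (z, y, x) volume as an MRC map with voxel size in nm."""
    volume = np.asarray(volume)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(
        np.ascontiguousarray(volume.transpose(2, 1, 0).astype(np.float32)))
    nz, ny, nx = volume.shape
    z, y, x = spacing_nm
    m.grid.unit_cell = gemmi.UnitCell(nx * x * 10.0, ny * y * 10.0,
                                      nz * z * 10.0, 90, 90, 90)
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def write_patch(patch: Patch, out_dir) -> Path:
    """Write one patch as TIFF named after its provenance id."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{patch.record.patch_id}.tiff"
    tifffile.imwrite(path, patch.image)
    return path


def load_patch_image(path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: patch images must be 2D")
    return np.asarray(img, dtype=np.uint8)


def record_loader(record: dict) -> np.ndarray:
    """Default manifest image loader: read the record's ``path`` field."""
    return load_patch_image(record["path"])


def write_manifest(records: Iterable[dict], path) -> None:
    """Write manifest records as JSON lines (one record per line)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")


def read_manifest(path) -> List[dict]:
    """Read a JSON-lines manifest; malformed lines raise with their number."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed manifest line {lineno}: "
                                 f"{exc}") from exc
            if not isinstance(rec, dict):
                raise ValueError(f"{path}: line {lineno} is not an object")
            records.append(rec)
    return records


def patch_to_record(patch: Patch, path: Optional[Path] = None,
                    stage: str = "raw") -> dict:
    rec = patch.record.to_dict()
    rec["stage"] = stage
    if path is not None:
        rec["path"] = str(path)
    return rec
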