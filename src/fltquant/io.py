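"""NIfTI / CSV / JSON input-output and the run manifest.

Volumes and masks travel as NIfTI (.nii/.nii.gz) sharing one affine; tables
as UTF-8 CSV with a header row; configuration and the manifest as JSON. All
writes are deterministic (gzip with zeroed mtime via nibabel, stable column
order, sorted JSON keys) so reruns with the same config produce
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .errors import AffineMismatchError, ShapeMismatchError, ValidationError
from .quant import PETStudy

__all__ = [
    "read_pet_study",
    "write_pet_study",
    "write_volume",
    "ResultWriter",
    "AFFINE_TOLERANCE",
]

AFFINE_TOLERANCE = 1e-4


def write_volume(
    data: np.ndarray, affine: np.ndarray, path: str | Path, dtype=np.float64
) -> Path:
    """Write one volume as NIfTI; boolean masks are stored as uint8."""
    path = Path(path)
    if data.dtype == bool:
        data = data.astype(np.uint8)
        dtype = np.uint8
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    nib.save(img, path)
    return path


def write_pet_study(study: PETStudy, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write SUV volume and both masks as NIfTI files sharing one affine."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "suv": write_volume(study.suv_volume, study.affine, out_dir / f"{stem}_suv.nii.gz"),
        "tumor_mask": write_volume(
            study.tumor_mask, study.affine, out_dir / f"{stem}_tumor_mask.nii.gz"
        ),
        "muscle_mask": write_volume(
            study.muscle_mask, study.affine, out_dir / f"{stem}_muscle_mask.nii.gz"
        ),
    }
    return paths


def _load_checked(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    img = nib.load(path)
    return np.asarray(img.dataobj), img.affine


def read_pet_study(
    suv_path: str | Path,
    tumor_mask_path: str | Path,
    muscle_mask_path: str | Path,
    subject_id: str = "",
    day: int = 0,
    injected_activity: Optional[float] = None,
    body_weight: Optional[float] = None,
) -> PETStudy:
    """Load and validate one study from three co-registered NIfTI files.

    Shapes must match exactly and affines within ``AFFINE_TOLERANCE``;
    resampling is out of scope, so mismatches are hard errors. Nonzero mask
    values are coerced to membership.
    """
    suv, suv_affine = _load_checked(suv_path)
    masks = {}
    for name, p in (("tumor", tumor_mask_path), ("muscle", muscle_mask_path)):
        data, affine = _load_checked(p)
        if data.shape != suv.shape:
            raise ShapeMismatchError(
                f"{name} mask shape {data.shape} != SUV shape {suv.shape} ({p})"
            )
        if not np.allclose(affine, suv_affine, atol=AFFINE_TOLERANCE):
            raise AffineMismatchError(
                f"{name} mask affine\n{affine}\ndoes not match SUV affine\n{suv_affine}"
            )
        masks[name] = data
    return PETStudy(
        suv_volume=np.asarray(suv, dtype=np.float64),
        tumor_mask=masks["tumor"],
        muscle_mask=masks["muscle"],
        subject_id=subject_id or Path(suv_path).name.split("_suv")[0],
        day=day,
        injected_activity=injected_activity,
        body_weight=body_weight,
        affine=suv_affine,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class ResultWriter:
    """Collects result artifacts under one output directory and writes a manifest.

    The manifest (JSON) records the config echo, seed, software version, and
    every written file exactly once with its SHA-256, which is sufficient to
    verify a bit-identical rerun.
    """

    def __init__(self, out_dir: str | Path, config: Optional[Mapping[str, Any]] = None,
                 seed: Optional[int] = None):
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.config = dict(config) if config else {}
        self.seed = seed
        self._entries: dict[str, str] = {}

    def _register(self, path: Path) -> Path:
        rel = str(path.relative_to(self.out_dir))
        if rel in self._entries:
            raise ValidationError(f"artifact {rel!r} written twice")
        self._entries[rel] = _sha256(path)
        return path

    def add_table(self, df: pd.DataFrame, name: str) -> Path:
        path = self.out_dir / f"{name}.csv"
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False, encoding="utf-8")
        return self._register(path)

    def add_volume(self, data: np.ndarray, affine: np.ndarray, name: str) -> Path:
        path = self.out_dir / f"{name}.nii.gz"
        path.parent.mkdir(parents=True, exist_ok=True)
        write_volume(data, affine, path)
        return self._register(path)

    def add_json(self, obj: Any, name: str) -> Path:
        path = self.out_dir / f"{name}.json"
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        return self._register(path)

    def add_file(self, path: str | Path) -> Path:
        """Register a file already written under the output directory."""
        return self._register(Path(path))

    def write_manifest(self) -> Path:
        manifest = {
            "version": __version__,
            "seed": self.seed,
            "config": self.config,
            "files": dict(sorted(self._entries.items())),
        }
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        return path
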