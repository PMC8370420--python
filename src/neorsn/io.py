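"""NIfTI volume and covariate-table I/O.

All cross-subject operations in this package assume that subject volumes
live on a common voxel grid (the study design registers every subject to a
weekly template before analysis; registration itself is out of scope here).
Affines are read and written but only voxel sizes are interpreted.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: inclusion window for postmenstrual age at scan, weeks
PMA_WINDOW = (37.0, 44.5)
#: gestational age at birth separating term from preterm, weeks
TERM_CUTOFF = 37.0

COVARIATE_COLUMNS = [
    "subject_id",
    "ga_birth",
    "pma_scan",
    "sex",
    "group",
    "postnatal_days",
]
_REQUIRED_COLUMNS = ["subject_id", "ga_birth", "pma_scan", "sex", "postnatal_days"]


@dataclass
class Bold4D:
    """A subject's 4D BOLD acquisition on a fixed voxel grid.

    Parameters
    ----------
    data
        X x Y x Z x T array of intensities (arbitrary units).
    voxel_size
        Voxel edge lengths in mm.
    tr
        Repetition time in seconds.
    subject_id
        Identifier used in file names and covariate tables.
    """

    data: np.ndarray
    voxel_size: tuple = (2.15, 2.15, 2.15)
    tr: float = 0.392
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"expected 4D volume, got {self.data.ndim}D for '{self.subject_id}'"
            )
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 volumes")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not np.isfinite(self.data).all():
            raise ValueError(f"non-finite voxels in data for '{self.subject_id}'")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.tr = float(self.tr)

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class MaskVolume:
    """Boolean brain mask matching a Bold4D spatial grid."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise ValueError("mask has no true voxels")


@dataclass
class SubjectMeta:
    """Per-subject covariates.

    ``motion_outliers`` is filled in by the motion-QC stage (count of DVARS
    outlier volumes in the retained window) and used as a nuisance covariate
    in every subsequent regression.
    """

    subject_id: str
    ga_birth: float
    pma_scan: float
    sex: str
    group: str = ""
    postnatal_days: float = 0.0
    motion_outliers: Optional[int] = None

    def __post_init__(self):
        self.ga_birth = float(self.ga_birth)
        self.pma_scan = float(self.pma_scan)
        if not self.group:
            self.group = "term" if self.ga_birth >= TERM_CUTOFF else "preterm"
        self.validate()

    def validate(self):
        if self.sex not in ("female", "male"):
            raise ValueError(
                f"subject '{self.subject_id}': sex must be 'female' or 'male', "
                f"got '{self.sex}'"
            )
        if self.group not in ("term", "preterm"):
            raise ValueError(
                f"subject '{self.subject_id}': group must be 'term' or 'preterm'"
            )
        if self.ga_birth > self.pma_scan:
            raise ValueError(
                f"subject '{self.subject_id}': ga_birth ({self.ga_birth}) exceeds "
                f"pma_scan ({self.pma_scan})"
            )
        expected = "term" if self.ga_birth >= TERM_CUTOFF else "preterm"
        if self.group != expected:
            raise ValueError(
                f"subject '{self.subject_id}': group '{self.group}' inconsistent "
                f"with ga_birth {self.ga_birth} (cutoff {TERM_CUTOFF} weeks)"
            )
        lo, hi = PMA_WINDOW
        if not (lo <= self.pma_scan <= hi):
            raise ValueError(
                f"subject '{self.subject_id}': pma_scan {self.pma_scan} outside "
                f"study window [{lo}, {hi}] weeks"
            )


def read_bold(path) -> Bold4D:
    """Load a 4D NIfTI-1 file.

    The repetition time is taken from the header time-step field; voxel
    sizes from the spatial zooms. Non-finite voxels are a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    if img.ndim < 4:
        raise ValueError(f"expected 4D volume in {path}, got {img.ndim}D")
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim > 4:
        data = data.reshape(data.shape[:4])
    if not np.isfinite(data).all():
        raise ValueError(f"non-finite voxels in {path}")
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    sid = path.name
    for suffix in (".gz", ".nii"):
        if sid.endswith(suffix):
            sid = sid[: -len(suffix)]
    return Bold4D(data=data, voxel_size=voxel_size, tr=tr, subject_id=sid)


def write_bold(b: Bold4D, path) -> Path:
    """Write a Bold4D to a NIfTI-1 file (voxel sizes and TR in the header)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    affine = np.diag(list(b.voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(b.data, dtype=np.float64), affine)
    img.header.set_zooms(tuple(b.voxel_size) + (b.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def write_mask(mask: MaskVolume, path, voxel_size=(2.15, 2.15, 2.15)) -> Path:
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    nib.save(img, str(path))
    return Path(path)


def read_mask(path) -> MaskVolume:
    img = nib.load(str(path))
    return MaskVolume(np.asarray(img.get_fdata()) > 0)


def read_covariates(path) -> list:
    """Parse a tab-separated covariate table into SubjectMeta records.

    The ``group`` column is optional; when absent it is derived from
    gestational age at birth (term iff >= 37 weeks). Row order is preserved
    and every malformed row raises an error naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"covariate table {path} missing columns: {missing}")
    metas = []
    for i, row in df.iterrows():
        try:
            meta = SubjectMeta(
                subject_id=str(row["subject_id"]),
                ga_birth=float(row["ga_birth"]),
                pma_scan=float(row["pma_scan"]),
                sex=str(row["sex"]),
                group=str(row["group"]) if "group" in df.columns else "",
                postnatal_days=float(row["postnatal_days"]),
                motion_outliers=(
                    int(row["motion_outliers"])
                    if "motion_outliers" in df.columns
                    and pd.notna(row["motion_outliers"])
                    else None
                ),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"covariate row {i} of {path}: {exc}") from exc
        metas.append(meta)
    return metas


def write_covariates(metas: Sequence[SubjectMeta], path) -> Path:
    rows = []
    for m in metas:
        d = dataclasses.asdict(m)
        if d["motion_outliers"] is None:
            d.pop("motion_outliers")
        rows.append(d)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return Path(path)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, stage: str, config: dict, seed, inputs=(), outputs=()):
    """Append a JSON run-manifest entry recording config, seed and I/O hashes."""
    entry = {
        "stage": stage,
        "seed": seed,
        "config": config,
        "inputs": {str(p): file_sha256(p) for p in inputs if Path(p).exists()},
        "outputs": {str(p): file_sha256(p) for p in outputs if Path(p).exists()},
    }
    path = Path(path)
    manifest = []
    if path.exists():
        manifest = json.loads(path.read_text())
    manifest.append(entry)
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
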