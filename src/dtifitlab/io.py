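"""Readers/writers for the standard on-disk formats and validated domain types.

Volumes are NIfTI-1, gradient tables are FSL-dialect whitespace text (one row
of b-values; three rows of x/y/z components), subject metadata is CSV with a
header, and label-atlas lookups are two-column TSV (``label<TAB>name``).

Grid convention: 0-based voxel indices, world coordinates via the NIfTI
affine.  All maps within a cohort must share an identical grid; registration
is enforced, never computed.  Maps are written as 32-bit floats.  b-vectors
are interpreted in the image coordinate frame as stored (no gradient-frame
rotation handling).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GradientScheme",
    "DWIVolume",
    "CohortTable",
    "LabelAtlas",
    "FormatError",
    "ValidationError",
    "read_dwi",
    "write_dwi",
    "read_map",
    "write_map",
    "read_cohort",
    "read_atlas",
    "write_atlas",
    "GROUPS",
]

GROUPS = ("HC", "MCI", "AD")

#: gender is stored as a 0/1 indicator for the design matrices; this is the
#: mapping applied to string-coded columns (recorded in run logs).
GENDER_CODES = {"M": 0, "MALE": 0, "F": 1, "FEMALE": 1, "0": 0, "1": 1}


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """Contents parsed but violate a domain invariant."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class GradientScheme:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    b=0 volumes may carry zero vectors; every b>0 vector must be unit length
    to within 1e-3 (and is re-normalized exactly on construction).  A valid
    scheme has at least one b=0 volume and at least seven b>0 volumes, the
    minimum for a 7-parameter tensor fit.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise FormatError(
                f"bvec table shape {self.bvecs.shape} does not match "
                f"{self.bvals.size} b-values"
            )
        if np.any(self.bvals < 0):
            raise ValidationError("negative b-value in gradient table")
        dwi = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) >= 1e-3):
            bad = np.flatnonzero(np.abs(norms - 1.0) >= 1e-3)
            raise ValidationError(
                f"non-unit b-vector(s) for b>0 volumes at DWI index {bad.tolist()}"
            )
        vecs = self.bvecs.copy()
        vecs[dwi] = vecs[dwi] / norms[:, None]
        self.bvecs = vecs
        if np.count_nonzero(~dwi) < 1:
            raise ValidationError("scheme has no b=0 volume")
        if np.count_nonzero(dwi) < 7:
            raise ValidationError(
                "scheme has fewer than 7 diffusion-weighted volumes; "
                "the tensor is unidentifiable"
            )

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.size)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0


@dataclass
class DWIVolume:
    """One subject's 4D diffusion-weighted acquisition on a voxel grid."""

    signal: np.ndarray  # (nx, ny, nz, nvol), non-negative scanner units
    voxel_size: np.ndarray  # (3,) mm
    scheme: GradientScheme
    subject_id: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).ravel()
        if self.signal.ndim != 4:
            raise ValidationError(f"signal must be 4D, got ndim={self.signal.ndim}")
        if self.signal.shape[3] != self.scheme.n_volumes:
            raise FormatError(
                f"volume count mismatch {self.signal.shape[3]} vs "
                f"{self.scheme.n_volumes}"
            )
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValidationError(f"invalid voxel size {self.voxel_size}")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid(self) -> tuple[int, int, int]:
        return tuple(self.signal.shape[:3])


@dataclass
class CohortTable:
    """Per-subject metadata: group, age, gender and cognitive scores.

    Backed by a DataFrame with columns ``id, group, age, gender, MoCA, MMSE,
    ADAS``; cognitive scores may be missing (NaN).
    """

    table: pd.DataFrame

    SCORES = ("MoCA", "MMSE", "ADAS")

    def __post_init__(self) -> None:
        df = self.table.copy()
        required = ["id", "group", "age", "gender"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"cohort table missing column(s) {missing}")
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValidationError(f"duplicate subject id(s) {dup}")
        bad = ~df["group"].isin(GROUPS)
        if bad.any():
            rows = df.index[bad].tolist()
            labels = df.loc[bad, "group"].tolist()
            raise ValidationError(
                f"unknown group label(s) {labels} in row(s) {rows}; "
                f"expected one of {list(GROUPS)}"
            )
        df["age"] = df["age"].astype(float)
        if np.any(df["age"] <= 0):
            raise ValidationError("non-positive age")
        as_num = pd.to_numeric(df["gender"], errors="coerce")
        as_str = (
            df["gender"].astype(str).str.strip().str.upper().map(GENDER_CODES)
        )
        gender = as_num.where(as_num.isin([0, 1]), as_str)
        if gender.isna().any():
            raise ValidationError("gender column not codable as 0/1 indicator")
        df["gender"] = gender.astype(int)
        for score in self.SCORES:
            if score not in df.columns:
                df[score] = np.nan
            df[score] = pd.to_numeric(df[score], errors="coerce")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def group_indices(self, group: str) -> np.ndarray:
        return np.flatnonzero((self.table["group"] == group).to_numpy())


@dataclass
class LabelAtlas:
    """Integer label volume on the cohort grid plus label -> name lookup."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.rint(self.labels).astype(int)
            if not np.allclose(lab, self.labels):
                raise ValidationError("label volume is not integer valued")
            self.labels = lab
        present = set(np.unique(self.labels).tolist()) - {0}
        unnamed = sorted(present - set(self.names))
        if unnamed:
            raise ValidationError(f"label(s) {unnamed} have no name entry")

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------


def _load_table(path: str | os.PathLike) -> np.ndarray:
    """Whitespace-delimited numeric table; tolerant of tabs and CRLF."""
    text = Path(path).read_text().replace("\r\n", "\n").replace("\r", "\n")
    rows = [
        [float(tok) for tok in line.split()]
        for line in text.split("\n")
        if line.strip()
    ]
    if not rows:
        raise FormatError(f"empty gradient table {path}")
    width = {len(r) for r in rows}
    if len(width) != 1:
        raise FormatError(f"ragged gradient table {path}")
    return np.asarray(rows, dtype=float)


def read_dwi(
    image_path: str | os.PathLike,
    bval_path: str | os.PathLike,
    bvec_path: str | os.PathLike,
    subject_id: str | None = None,
) -> DWIVolume:
    """Read a 4D NIfTI plus FSL-dialect bval/bvec tables into a DWIVolume.

    b-vectors for b>0 volumes are re-normalized to unit length (they must
    already be within 1e-3 of unit norm).  Voxel size comes from the NIfTI
    header zooms; the affine is preserved.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected a 3D+volumes image")
    bvals = _load_table(bval_path).ravel()
    bvecs = _load_table(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        pass  # ambiguous but row-per-volume either way
    if data.shape[3] != bvals.size:
        raise FormatError(
            f"volume count mismatch {data.shape[3]} vs {bvals.size}"
        )
    if bvecs.shape[0] != bvals.size:
        raise FormatError(
            f"volume count mismatch {bvals.size} vs {bvecs.shape[0]} "
            f"between bval and bvec tables"
        )
    if np.any(bvals < 0):
        raise ValidationError("negative b-value in bval table")
    scheme = GradientScheme(bvals=bvals, bvecs=bvecs)
    sid = subject_id if subject_id is not None else Path(image_path).name.split(".")[0]
    return DWIVolume(
        signal=data,
        voxel_size=np.asarray(img.header.get_zooms()[:3], dtype=float),
        scheme=scheme,
        subject_id=sid,
        affine=np.asarray(img.affine, dtype=float),
    )


def write_dwi(
    volume: DWIVolume,
    image_path: str | os.PathLike,
    bval_path: str | os.PathLike,
    bvec_path: str | os.PathLike,
) -> None:
    """Write a DWIVolume as NIfTI + FSL-dialect bval/bvec text files."""
    img = nib.Nifti1Image(volume.signal.astype(np.float32), volume.affine)
    img.header.set_zooms((*volume.voxel_size, 1.0))
    nib.save(img, str(image_path))
    np.savetxt(bval_path, volume.scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, volume.scheme.bvecs.T, fmt="%.8f")


def write_map(
    map_or_array,
    reference: DWIVolume,
    out_path: str | os.PathLike,
) -> Path:
    """Write a 3D statistic map with the reference volume's grid metadata.

    Accepts a bare 3D array or any object exposing a 3D ``.data`` attribute.
    Data are cast to float32 on disk; the write/read round trip is exact at
    that precision.
    """
    data = getattr(map_or_array, "data", map_or_array)
    data = np.asarray(data, dtype=float)
    if data.shape != reference.grid:
        raise ValidationError(
            f"grid mismatch: map {data.shape} vs reference {reference.grid}"
        )
    img = nib.Nifti1Image(data.astype(np.float32), reference.affine)
    img.header.set_zooms(tuple(reference.voxel_size))
    nib.save(img, str(out_path))
    return Path(out_path)


def read_map(path: str | os.PathLike) -> np.ndarray:
    """Read a 3D NIfTI map as a float array."""
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3D map, got ndim={arr.ndim}")
    return arr


def read_cohort(csv_path: str | os.PathLike) -> CohortTable:
    """Read and validate a subject covariate CSV (id, group, age, gender, ...)."""
    return CohortTable(pd.read_csv(csv_path))


def read_atlas(
    label_path: str | os.PathLike, names_path: str | os.PathLike
) -> LabelAtlas:
    """Read a label NIfTI plus a ``label<TAB>name`` TSV lookup."""
    labels = np.asarray(nib.load(str(label_path)).dataobj)
    names: dict[int, str] = {}
    text = Path(names_path).read_text().replace("\r\n", "\n")
    for line in text.split("\n"):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{names_path}: expected 'label<TAB>name' rows")
        names[int(parts[0])] = parts[1].strip()
    return LabelAtlas(labels=labels, names=names)


def write_atlas(
    atlas: LabelAtlas,
    reference: DWIVolume,
    label_path: str | os.PathLike,
    names_path: str | os.PathLike,
) -> None:
    if atlas.labels.shape != reference.grid:
        raise ValidationError(
            f"grid mismatch: atlas {atlas.labels.shape} vs reference {reference.grid}"
        )
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), reference.affine)
    nib.save(img, str(label_path))
    with open(names_path, "w") as fh:
        for label in sorted(atlas.names):
            fh.write(f"{label}\t{atlas.names[label]}\n")
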