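"""Reading and writing CT volumes and lung-function tables.

Volumes are held as plain 3-D numpy arrays indexed ``(slice, row, column)``,
with the slice index increasing inferior -> superior, so that "apical"
always means the high-index end of axis 0.  Grey levels are whatever the
source format stores after its own slope/intercept rescale; no further unit
conversion is applied, because absolute density values are scanner- and
export-convention dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

__all__ = [
    "CTVolume",
    "PhaseSeries",
    "read_volume",
    "write_volume",
    "average_phases",
    "read_lung_function",
    "write_lung_function",
]

LUNG_FUNCTION_COLUMNS = ("patient_id", "fev1_pct", "tlco_pct")


@dataclass
class CTVolume:
    """A 3-D scalar CT grid with physical spacing.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Grey-level values (the density signal).
    spacing : tuple of float
        ``(dx, dy, dz)`` voxel spacing in mm: dx along columns, dy along
        rows, dz between slices.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"CTVolume requires a 3-D array, got {self.voxels.ndim} dimensions"
            )
        if min(self.voxels.shape) < 1:
            raise ValueError("CTVolume axes must all have length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        self.origin = tuple(float(s) for s in self.origin)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def slice_thickness_mm(self) -> float:
        return self.spacing[2]


@dataclass
class PhaseSeries:
    """An ordered set of breathing-phase volumes sharing one grid."""

    phases: list[CTVolume] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.phases) < 1:
            raise ValueError("PhaseSeries requires at least one phase")
        ref = self.phases[0]
        for i, ph in enumerate(self.phases[1:], start=1):
            if ph.shape != ref.shape:
                raise ValueError(f"phase {i} shape {ph.shape} != phase 0 {ref.shape}")
            if ph.spacing != ref.spacing:
                raise ValueError(
                    f"phase {i} spacing {ph.spacing} != phase 0 {ref.spacing}"
                )


def average_phases(series: PhaseSeries) -> CTVolume:
    """Collapse a phase series to its voxel-wise arithmetic mean (AVIP).

    The average-intensity projection over breathing phases is the single
    volume the rest of the pipeline consumes; spacing and origin are copied
    from the first phase.
    """
    stack = np.stack([ph.voxels for ph in series.phases], axis=0)
    ref = series.phases[0]
    return CTVolume(stack.mean(axis=0), ref.spacing, ref.origin)


# ---------------------------------------------------------------------------
# volume file I/O
# ---------------------------------------------------------------------------


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI file or a single-series DICOM directory.

    Scale slopes/intercepts declared by the format are applied; nothing
    else is rescaled.  The returned array is (slice, row, column).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if path.is_dir():
        return _read_dicom_series(path)
    return _read_nifti(path)


def write_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii or .nii.gz), losslessly (float64)."""
    affine = np.diag(list(volume.spacing) + [1.0]).astype(float)
    affine[:3, 3] = volume.origin
    # nibabel stores (i, j, k) = (x, y, z); our array is (z, y, x)
    img = nib.Nifti1Image(np.asarray(volume.voxels.T, dtype=np.float64), affine)
    nib.save(img, str(path))


def _read_nifti(path: Path) -> CTVolume:
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(
            f"{path}: expected a 3-D image, got shape {img.shape}; "
            "average 4-D phase data first (average_phases)"
        )
    data = img.get_fdata(dtype=np.float64)  # applies scl_slope / scl_inter
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTVolume(data.T, tuple(float(z) for z in zooms), origin)


def _read_dicom_series(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue  # non-DICOM clutter is ignored
    if not datasets:
        raise FileNotFoundError(f"{path}: no readable DICOM files")
    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"{path}: directory mixes {len(uids)} DICOM series")

    # sort inferior -> superior on the z component of the patient position
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(zs) > 1:
        steps = np.diff(zs)
        dz = float(steps.mean())
        if dz <= 0 or np.any(np.abs(steps - dz) > 1e-3 * abs(dz) + 1e-6):
            raise ValueError(f"{path}: inconsistent DICOM slice spacing {steps}")
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))

    dy, dx = (float(v) for v in datasets[0].PixelSpacing)  # row, col spacing
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    voxels = np.stack(slices, axis=0)
    ipp = datasets[0].ImagePositionPatient
    origin = (float(ipp[0]), float(ipp[1]), float(ipp[2]))
    return CTVolume(voxels, (dx, dy, dz), origin)


# ---------------------------------------------------------------------------
# lung-function tables
# ---------------------------------------------------------------------------


def read_lung_function(path: str | Path) -> pd.DataFrame:
    """Read and validate a ``patient_id,fev1_pct,tlco_pct`` CSV.

    Both lung-function columns are percentages of the predicted value for
    the patient's age, height and gender, so they must be strictly
    positive; patient ids must be unique.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in LUNG_FUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df = df.loc[:, list(LUNG_FUNCTION_COLUMNS)].copy()
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"{path}: duplicate patient_id(s) {dupes}")
    for col in ("fev1_pct", "tlco_pct"):
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals <= 0).any() or vals.isna().any():
            raise ValueError(f"{path}: {col} must be > 0 for every patient")
        df[col] = vals.astype(float)
    return df.reset_index(drop=True)


def write_lung_function(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in LUNG_FUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cannot write lung-function table: missing {missing}")
    df.loc[:, list(LUNG_FUNCTION_COLUMNS)].to_csv(path, index=False)
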