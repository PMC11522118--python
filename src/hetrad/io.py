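"""Volumetric image and tabular I/O, lesion splitting and size filtering.

Volumes are CT-like 3-D scalar grids on the Hounsfield-unit scale with
anisotropic voxel spacing in millimetres.  Label masks share the volume's
grid: 0 marks background, positive integers mark individual lesions.  A
binary mask (labels {0, 1} only) is interpreted as an undifferentiated
lesion layer and split into 26-connected components.

Arrays are indexed ``data[x, y, z]``; ``spacing = (sx, sy, sz)`` gives the
physical size of one voxel along each axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "LabelMask",
    "LesionRegion",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "split_lesions",
    "filter_by_size",
    "equivalent_sphere_diameter",
    "write_feature_table",
    "read_feature_table",
    "read_manifest",
]

#: 3x3x3 structuring element: 26-connectivity in 3-D.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D intensity grid with voxel spacing and origin in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError(f"volume data must be 3-D, got shape {data.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass(frozen=True)
class LabelMask:
    """Integer lesion labels on the grid of a paired :class:`ImageVolume`."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"label mask must be 3-D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            if np.issubdtype(labels.dtype, np.floating) and np.all(
                labels == np.round(labels)
            ):
                labels = labels.astype(np.int32)
            else:
                raise ValueError(
                    "label mask must contain integers (fractional/probabilistic "
                    "masks are not supported)"
                )
        if labels.min() < 0:
            raise ValueError("label mask must be non-negative")
        object.__setattr__(self, "labels", labels)

    @property
    def lesion_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(k) for k in ids if k > 0]


def equivalent_sphere_diameter(volume_mm3: float) -> float:
    """Diameter of the sphere whose volume equals ``volume_mm3``."""
    return (6.0 * volume_mm3 / math.pi) ** (1.0 / 3.0)


@dataclass(frozen=True)
class LesionRegion:
    """One lesion's voxels after splitting a multi-lesion mask.

    ``voxel_coordinates`` are 0-based integer (x, y, z) indices into the
    source grid; world coordinates are obtained via origin + spacing only.
    """

    lesion_id: int
    patient_id: str
    voxel_intensities: np.ndarray
    voxel_coordinates: np.ndarray
    voxel_volume_mm3: float

    def __post_init__(self) -> None:
        inten = np.asarray(self.voxel_intensities, dtype=float)
        coords = np.asarray(self.voxel_coordinates)
        if inten.size < 1:
            raise ValueError("a lesion region needs at least one voxel")
        if coords.shape != (inten.size, 3):
            raise ValueError("voxel_coordinates must have shape (n_voxels, 3)")
        if len(np.unique(coords, axis=0)) != len(coords):
            raise ValueError("voxel_coordinates must be unique")
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("voxel_volume_mm3 must be > 0")
        object.__setattr__(self, "voxel_intensities", inten)
        object.__setattr__(self, "voxel_coordinates", coords.astype(np.intp))

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_intensities.size)

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    @property
    def equivalent_diameter_mm(self) -> float:
        return equivalent_sphere_diameter(self.volume_mm3)


# ---------------------------------------------------------------------------
# volume / mask file I/O


def _format_from_path(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nrrd") or name.endswith(".nhdr"):
        return "nrrd"
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    raise ValueError(f"cannot infer volume format from {path.name!r}")


def read_volume(path: str | Path, format: str | None = None) -> ImageVolume:
    """Read an NRRD or NIfTI-1 volume, taking spacing from the file header."""
    path = Path(path)
    fmt = format or _format_from_path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if fmt == "nrrd":
        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:  # ITK wraps parse failures in RuntimeError
            raise IOError(f"could not read NRRD volume {path}: {exc}") from exc
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = tuple(img.GetSpacing())
        origin = tuple(img.GetOrigin())
    elif fmt == "nifti":
        try:
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj)
        except Exception as exc:
            raise IOError(f"could not read NIfTI volume {path}: {exc}") from exc
        if data.ndim != 3:
            raise IOError(f"{path}: expected a 3-D volume, got ndim={data.ndim}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'nrrd' or 'nifti')")
    if any(s <= 0 for s in spacing):
        raise IOError(f"{path}: header field 'spacing' missing or non-positive: {spacing}")
    return ImageVolume(data=np.asarray(data), spacing=spacing, origin=origin)


def write_volume(volume: ImageVolume, path: str | Path, format: str | None = None) -> None:
    """Write a volume as NRRD (via ITK) or NIfTI-1 (via nibabel)."""
    path = Path(path)
    fmt = format or _format_from_path(path)
    if fmt == "nrrd":
        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        sitk.WriteImage(img, str(path), useCompression=True)
    elif fmt == "nifti":
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_mask(path: str | Path, format: str | None = None) -> LabelMask:
    """Read a label mask; rejects fractional (probabilistic) masks."""
    vol = read_volume(path, format)
    return LabelMask(labels=vol.data)


def write_mask(mask: LabelMask, spacing: Sequence[float], path: str | Path,
               origin: Sequence[float] = (0.0, 0.0, 0.0)) -> None:
    vol = ImageVolume(
        data=mask.labels.astype(np.int16),
        spacing=tuple(spacing),
        origin=tuple(origin),
    )
    write_volume(vol, path)


# ---------------------------------------------------------------------------
# lesion splitting and filtering


def split_lesions(mask: LabelMask, volume: ImageVolume, patient_id: str) -> list[LesionRegion]:
    """Split a multi-lesion mask into per-lesion regions.

    Distinct positive labels define lesions.  A purely binary mask (only
    label 1) is first partitioned into 26-connected components, mirroring
    the splitting of a single metastasis layer into individual lesions.
    """
    labels = mask.labels
    if labels.shape != volume.data.shape:
        raise ValueError(
            f"mask shape {labels.shape} does not match volume shape {volume.data.shape}"
        )
    ids = mask.lesion_ids
    if not ids:
        return []
    if ids == [1]:
        labels, n_found = ndimage.label(labels > 0, structure=STRUCT_26)
        ids = list(range(1, n_found + 1))
    voxel_volume = volume.voxel_volume_mm3
    regions: list[LesionRegion] = []
    objects = ndimage.find_objects(labels)
    for lesion_id in ids:
        sl = objects[lesion_id - 1]
        if sl is None:
            continue
        local = labels[sl] == lesion_id
        coords = np.argwhere(local)
        coords += [s.start for s in sl]
        regions.append(
            LesionRegion(
                lesion_id=int(lesion_id),
                patient_id=patient_id,
                voxel_intensities=volume.data[tuple(coords.T)],
                voxel_coordinates=coords,
                voxel_volume_mm3=voxel_volume,
            )
        )
    return regions


def filter_by_size(regions: Iterable[LesionRegion], min_diameter_mm: float = 5.0) -> list[LesionRegion]:
    """Keep lesions whose equivalent-sphere diameter is >= the threshold.

    The 5 mm default implements the exclusion of lesions smaller than
    0.5 cm; the boundary is inclusive.
    """
    if min_diameter_mm <= 0:
        raise ValueError("min_diameter_mm must be > 0")
    return [r for r in regions if r.equivalent_diameter_mm >= min_diameter_mm]


# ---------------------------------------------------------------------------
# tabular I/O

_FLOAT_FORMAT = "%.12g"  # 12 significant digits: lossless for feature values


def write_feature_table(rows: Sequence[tuple[str, int, "object"]], path: str | Path) -> None:
    """Write per-lesion feature vectors as CSV.

    ``rows`` holds ``(patient_id, lesion_id, feature_vector)`` triples whose
    feature vectors must all share the same ordered feature names.  Columns:
    patient_id, lesion_id, then the features in canonical order.
    """
    from .texture import FEATURE_NAMES  # canonical 75-name order

    records = []
    names: list[str] | None = None
    for patient_id, lesion_id, fv in rows:
        values = dict(fv.values) if hasattr(fv, "values") and not callable(fv.values) else dict(fv)
        row_names = list(values)
        if names is None:
            names = row_names
        elif row_names != names:
            raise ValueError(
                f"inconsistent feature names for lesion {lesion_id} of {patient_id}"
            )
        records.append({"patient_id": patient_id, "lesion_id": lesion_id, **values})
    columns = ["patient_id", "lesion_id"] + (names if names is not None else list(FEATURE_NAMES))
    df = pd.DataFrame.from_records(records, columns=columns)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a per-lesion feature CSV back into a DataFrame."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns or "lesion_id" not in df.columns:
        raise ValueError(f"{path}: not a feature table (missing patient_id/lesion_id)")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a patient manifest CSV (patient_id, cohort, optional extras)."""
    df = pd.read_csv(path, dtype=str)
    for col in ("patient_id", "cohort"):
        if col not in df.columns:
            raise ValueError(f"{path}: manifest is missing required column {col!r}")
    if df["patient_id"].duplicated().any():
        dupes = sorted(df.loc[df["patient_id"].duplicated(), "patient_id"])
        raise ValueError(f"{path}: duplicated patient ids {dupes}")
    return df
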