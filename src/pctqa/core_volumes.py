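"""Geometry-aware 3-D volumes, masks and rigid transforms.

Shared plumbing for the pseudo-CT QA pipeline: every downstream stage (HU
statistics, DVH, gamma, radiomics, radiobiology) consumes :class:`ImageVolume`
and :class:`StructureMask` objects defined here.

Conventions
-----------
* Arrays are indexed ``values[i, j, k]``; voxel ``(i, j, k)`` is a point
  sample at physical position ``origin + index * spacing`` (mm).  Axes are
  patient-LPS-like but only internal consistency is required — all
  comparisons are intra-case.
* Cross-grid comparisons resample the *evaluated* volume onto the
  *reference* geometry (reference = planning CT / its dose).
* Out-of-field voxels after a rigid transform are filled with 0 Gy for dose
  and -1000 HU (air) for CT-like volumes, and flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "Geometry",
    "ImageVolume",
    "StructureMask",
    "RigidTransform",
    "STRUCTURE_ROLES",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample",
    "resample_mask",
    "apply_rigid",
    "structure_volume_cc",
    "read_manifest",
]

#: structure roles understood by the reporting layers
STRUCTURE_ROLES = (
    "PTV",
    "GTV",
    "brain",
    "brain_minus_GTV",
    "brainstem",
    "lens_L",
    "lens_R",
    "opt_nerve_L",
    "opt_nerve_R",
    "opt_chiasm",
    "spinal_cord",
    "body",
)

#: fill values for voxels mapped from outside the source field of view
OUT_OF_FIELD_FILL = {"CT": -1000.0, "pCT": -1000.0, "dose": 0.0}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Geometry:
    """Axis-aligned sampling grid: spacing and origin in mm, shape in voxels."""

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.spacing) != 3 or len(self.origin) != 3 or len(self.shape) != 3:
            raise ValueError("geometry must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be >= 1 per axis, got {self.shape}")
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def indices_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (..., 3) to physical mm positions."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.array(self.spacing) + np.array(self.origin)

    def physical_to_indices(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        return (pos - np.array(self.origin)) / np.array(self.spacing)

    def extent_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounding box spanned by the voxel-centre lattice."""
        lo = np.array(self.origin)
        hi = lo + (np.array(self.shape) - 1) * np.array(self.spacing)
        return lo, hi

    def approx_equal(self, other: "Geometry", tol_mm: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol_mm)
            and np.allclose(self.origin, other.origin, atol=tol_mm)
        )


@dataclass
class ImageVolume:
    """A scalar 3-D grid: HU for CT/pCT, Gy for dose."""

    geometry: Geometry
    values: np.ndarray
    modality: str = "CT"  # one of {CT, pCT, dose}
    out_of_field: np.ndarray | None = None  # True where filled after transform

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("expected 3-D volume")
        if tuple(self.values.shape) != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if self.modality not in ("CT", "pCT", "dose"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.modality == "dose" and np.any(self.values < 0):
            raise ValueError("dose values must be >= 0")

    def copy(self) -> "ImageVolume":
        return ImageVolume(
            self.geometry,
            self.values.copy(),
            self.modality,
            None if self.out_of_field is None else self.out_of_field.copy(),
        )


@dataclass
class StructureMask:
    """Binary voxel mask with an anatomical role label."""

    geometry: Geometry
    voxels: np.ndarray
    role: str
    allow_empty: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("expected 3-D mask")
        if tuple(self.voxels.shape) != self.geometry.shape:
            raise ValueError("mask shape does not match geometry")
        if not self.allow_empty and not self.voxels.any():
            raise ValueError(f"empty structure {self.role!r}")

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion: intrinsic z-y-x Euler rotation (degrees) about a centre,
    then translation (mm).  ``centre_mm`` defaults to the grid centre of the
    volume the transform is applied to."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("zyx", self.rotation_deg, degrees=True).as_matrix()

    def apply_points(self, pts: np.ndarray, centre: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - centre) @ self.matrix().T + centre + np.asarray(self.translation_mm)

    def inverse(self) -> "RigidTransform":
        r = Rotation.from_euler("zyx", self.rotation_deg, degrees=True).inv()
        t = -r.apply(np.asarray(self.translation_mm))
        return RigidTransform(tuple(r.as_euler("zyx", degrees=True)), tuple(t))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        ra = Rotation.from_euler("zyx", self.rotation_deg, degrees=True)
        rb = Rotation.from_euler("zyx", other.rotation_deg, degrees=True)
        r = ra * rb
        t = ra.apply(np.asarray(other.translation_mm)) + np.asarray(self.translation_mm)
        return RigidTransform(tuple(r.as_euler("zyx", degrees=True)), tuple(t))

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(
            np.allclose(self.rotation_deg, 0, atol=tol)
            and np.allclose(self.translation_mm, 0, atol=tol)
        )


# ---------------------------------------------------------------------------
# I/O (SimpleITK backs both NRRD and NIfTI-1)
# ---------------------------------------------------------------------------

_FORMAT_EXT = {"NRRD": ".nrrd", "NIfTI": ".nii"}


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nrrd") or name.endswith(".nhdr"):
        return "NRRD"
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "NIfTI"
    raise ValueError(f"cannot infer volume format from {path.name!r}")


def read_volume(path: str | Path, format: str | None = None, modality: str = "CT") -> ImageVolume:
    """Read an NRRD or NIfTI-1 volume into an :class:`ImageVolume`.

    Geometry is populated from the header; values are used as stored (any
    slope/intercept scaling applied by the format reader is kept).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = _infer_format(path)
    if format not in _FORMAT_EXT:
        raise ValueError(f"unsupported format {format!r}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - passthrough of reader msg
        raise ValueError(f"unreadable {format} file {path.name}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"expected 3-D volume, got {img.GetDimension()}-D in {path.name}")
    # sitk arrays come back (z, y, x); transpose to our (x, y, z) indexing
    arr = sitk.GetArrayFromImage(img).T.astype(float)
    geom = Geometry(tuple(img.GetSpacing()), tuple(img.GetOrigin()), arr.shape)
    return ImageVolume(geom, arr, modality=modality)


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    path = Path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.T))
    img.SetSpacing(volume.geometry.spacing)
    img.SetOrigin(volume.geometry.origin)
    sitk.WriteImage(img, str(path))


def read_mask(path: str | Path, role: str) -> StructureMask:
    vol = read_volume(path)
    return StructureMask(vol.geometry, vol.values > 0.5, role=role, allow_empty=True)


def write_mask(mask: StructureMask, path: str | Path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(mask.voxels.T.astype(np.uint8)))
    img.SetSpacing(mask.geometry.spacing)
    img.SetOrigin(mask.geometry.origin)
    sitk.WriteImage(img, str(path))


def read_manifest(path: str | Path) -> dict:
    """Load a JSON case manifest ({case_id, prescription_Gy, fractions,
    volumes: {...}, structures: {role: path}})."""
    with open(path) as fh:
        manifest = json.load(fh)
    for key in ("case_id", "prescription_Gy", "fractions"):
        if key not in manifest:
            raise ValueError(f"manifest missing required field {key!r}")
    return manifest


# ---------------------------------------------------------------------------
# resampling and rigid transforms
# ---------------------------------------------------------------------------

_ORDER = {"nearest": 0, "trilinear": 1}


def _check_overlap(source: Geometry, target: Geometry) -> None:
    slo, shi = source.extent_mm()
    tlo, thi = target.extent_mm()
    if np.any(np.minimum(shi, thi) < np.maximum(slo, tlo)):
        raise ValueError("target geometry does not overlap the source extent")


def _sample(values: np.ndarray, idx: np.ndarray, order: int, cval: float) -> np.ndarray:
    """Interpolate ``values`` at fractional index coordinates ``idx`` (N, 3).

    Points inside the lattice clamp to edge behaviour only through genuine
    trilinear weights; points strictly outside receive ``cval``.
    """
    coords = idx.T
    out = ndimage.map_coordinates(values, coords, order=order, mode="nearest", prefilter=False)
    eps = 1e-9
    outside = np.any((idx < -eps) | (idx > np.array(values.shape) - 1 + eps), axis=-1)
    if outside.any():
        out = np.where(outside, cval, out)
    return out, outside


def _target_index_grid(target: Geometry) -> np.ndarray:
    axes = [np.arange(n, dtype=float) for n in target.shape]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return grid.reshape(-1, 3)


def resample(volume: ImageVolume, target: Geometry, interpolation: str = "trilinear") -> ImageVolume:
    """Resample a volume onto ``target``; trilinear output is bounded by the
    source min/max and exact for constant fields."""
    if interpolation not in _ORDER:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if volume.geometry.approx_equal(target):
        return volume.copy()
    _check_overlap(volume.geometry, target)
    pos = target.indices_to_physical(_target_index_grid(target))
    idx = volume.geometry.physical_to_indices(pos)
    cval = OUT_OF_FIELD_FILL[volume.modality]
    out, outside = _sample(volume.values, idx, _ORDER[interpolation], cval)
    return ImageVolume(
        target,
        out.reshape(target.shape),
        modality=volume.modality,
        out_of_field=outside.reshape(target.shape) if outside.any() else None,
    )


def resample_mask(mask: StructureMask, target: Geometry) -> StructureMask:
    """Nearest-neighbour mask resampling (stays binary)."""
    if mask.geometry.approx_equal(target):
        return StructureMask(target, mask.voxels.copy(), mask.role, allow_empty=True)
    _check_overlap(mask.geometry, target)
    pos = target.indices_to_physical(_target_index_grid(target))
    idx = mask.geometry.physical_to_indices(pos)
    out, _ = _sample(mask.voxels.astype(float), idx, 0, 0.0)
    return StructureMask(target, out.reshape(target.shape) > 0.5, mask.role, allow_empty=True)


def apply_rigid(
    volume: ImageVolume,
    t: RigidTransform,
    interpolation: str = "trilinear",
    centre_mm: np.ndarray | None = None,
) -> ImageVolume:
    """Resample ``volume`` under the rigid motion ``t`` (output voxel x takes
    the input value at ``t^{-1}(x)``).  Identity returns the input bit-exactly.
    """
    if interpolation not in _ORDER:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if not np.all(np.isfinite(t.rotation_deg)) or not np.all(np.isfinite(t.translation_mm)):
        raise ValueError("transform must be finite")
    if t.is_identity():
        return volume.copy()
    geom = volume.geometry
    if centre_mm is None:
        lo, hi = geom.extent_mm()
        centre_mm = (lo + hi) / 2.0
    pos = geom.indices_to_physical(_target_index_grid(geom))
    src_pos = t.inverse().apply_points(pos, np.asarray(centre_mm, dtype=float))
    idx = geom.physical_to_indices(src_pos)
    cval = OUT_OF_FIELD_FILL[volume.modality]
    out, outside = _sample(volume.values, idx, _ORDER[interpolation], cval)
    return ImageVolume(
        geom,
        out.reshape(geom.shape),
        modality=volume.modality,
        out_of_field=outside.reshape(geom.shape) if outside.any() else None,
    )


def structure_volume_cc(mask: StructureMask) -> float:
    """Structure volume in cm^3: voxel count x voxel volume (point-sample
    convention, voxel centres)."""
    n = mask.voxel_count
    if n == 0:
        raise ValueError("empty structure")
    return n * mask.geometry.voxel_volume_mm3 / 1000.0
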