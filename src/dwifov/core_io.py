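"""Data model and I/O for diffusion MRI studies.

A :class:`DWIStudy` bundles a 4-D intensity array (indexed ``(x, y, z, v)``
with ``z`` the superior–inferior axis), an FSL-style gradient table and the
voxel-to-world affine.  NIfTI reading/writing goes through nibabel; gradient
tables use the FSL ``.bval`` / ``.bvec`` text layout (bvec = 3 rows × V
columns).  :func:`resample_to_grid` moves volumes between subject space and
an isotropic, axis-aligned working grid (the "normalized space" in which
cutoffs are measured in mm), with a centered pad/crop fast path when the
geometries already agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import FormatError, GeometryError

log = logging.getLogger(__name__)

#: b-values at or below this (s/mm²) count as b0 volumes.
B0_THRESHOLD = 50.0


@dataclass
class GradientTable:
    """Per-volume b-values (s/mm²) and unit diffusion-gradient directions.

    Volumes with ``bval <= b0_threshold`` are b0 acquisitions and carry a
    zero b-vector; all other volumes carry a unit-norm b-vector (vectors off
    unit norm by more than 1e-3 are re-normalized with a warning).
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = B0_THRESHOLD

    def __post_init__(self):
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise FormatError("bvecs must be a (V, 3) array")
        if len(self.bvals) != len(self.bvecs):
            raise FormatError(
                f"{len(self.bvals)} b-values but {len(self.bvecs)} b-vectors")
        bvecs = self.bvecs.copy()
        weighted = self.bvals > self.b0_threshold
        norms = np.linalg.norm(bvecs, axis=1)
        if np.any(weighted & (norms == 0)):
            raise FormatError("zero b-vector on a diffusion-weighted volume")
        off = weighted & (np.abs(norms - 1.0) > 1e-3)
        if np.any(off):
            log.warning("re-normalizing %d b-vector(s) off unit norm",
                        int(off.sum()))
            bvecs[off] /= norms[off, None]
        bvecs[~weighted] = 0.0
        self.bvecs = bvecs

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bvals <= self.b0_threshold)

    @property
    def weighted_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bvals > self.b0_threshold)

    def group_indices(self, shell_group: str) -> np.ndarray:
        """Volume indices for a shell group, ``"b0"`` or ``"bweighted"``."""
        if shell_group == "b0":
            return self.b0_indices
        if shell_group == "bweighted":
            return self.weighted_indices
        raise ValueError(f"unknown shell group {shell_group!r}")


def _check_affine(affine) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GeometryError("affine must be an invertible 4x4 matrix")
    return affine


@dataclass
class DWIStudy:
    """A 4-D diffusion dataset: volumes, gradient table, geometry."""

    data: np.ndarray
    gradients: GradientTable
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise FormatError("DWI data must be 4-D (x, y, z, v)")
        if self.data.shape[3] != self.gradients.n_volumes:
            raise FormatError(
                f"image has {self.data.shape[3]} volumes but gradient "
                f"table has {self.gradients.n_volumes}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise GeometryError("voxel sizes must be positive")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def volume(self, v: int) -> np.ndarray:
        return self.data[..., v]

    def with_data(self, data: np.ndarray) -> "DWIStudy":
        return replace(self, data=data)


@dataclass
class StructuralImage:
    """A co-registered 3-D structural (T1w-like) image."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError("structural image must be 3-D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise GeometryError("voxel sizes must be positive")
        self.affine = _check_affine(self.affine)


@dataclass(frozen=True)
class NormalizedGrid:
    """Isotropic axis-aligned working grid (sagittal=x, coronal=y, axial=z).

    Defaults to the full-scale 256³ @ 1 mm grid; tests and phantoms use
    smaller cubes with the same conventions.
    """

    shape: tuple[int, int, int] = (256, 256, 256)
    voxel_size: float = 1.0

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise GeometryError("grid voxel size must be positive")
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise GeometryError("grid shape must be 3 positive integers")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    def affine_for(self, ref_shape, ref_affine) -> np.ndarray:
        """Grid voxel-to-world affine that centers the reference image."""
        ref_affine = _check_affine(ref_affine)
        c_ref = (np.asarray(ref_shape, dtype=float) - 1) / 2
        world_center = ref_affine[:3, :3] @ c_ref + ref_affine[:3, 3]
        c_grid = (np.asarray(self.shape, dtype=float) - 1) / 2
        A = np.eye(4)
        A[:3, :3] *= self.voxel_size
        A[:3, 3] = world_center - self.voxel_size * c_grid
        return A


# ---------------------------------------------------------------------------
# NIfTI + FSL gradient-table I/O
# ---------------------------------------------------------------------------

def _load_nifti(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    affine = _check_affine(img.affine)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, voxel_size, affine


def read_gradient_table(bval_path, bvec_path,
                        b0_threshold: float = B0_THRESHOLD) -> GradientTable:
    bvals = np.loadtxt(str(bval_path), ndmin=1)
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    if bvecs.shape[0] != 3:
        raise FormatError(f"bvec file must have 3 rows, got {bvecs.shape[0]}")
    return GradientTable(bvals, bvecs.T, b0_threshold=b0_threshold)


def write_gradient_table(gradients: GradientTable, bval_path, bvec_path):
    with open(bval_path, "w") as f:
        f.write(" ".join(_fmt(b) for b in gradients.bvals) + "\n")
    with open(bvec_path, "w") as f:
        for row in gradients.bvecs.T:
            f.write(" ".join(_fmt(x) for x in row) + "\n")


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def read_dwi(image_path, bval_path, bvec_path,
             b0_threshold: float = B0_THRESHOLD) -> DWIStudy:
    """Read a 4-D NIfTI plus its FSL gradient table into a DWIStudy."""
    data, voxel_size, affine = _load_nifti(image_path)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise FormatError(f"expected a 4-D image, got {data.ndim}-D")
    gradients = read_gradient_table(bval_path, bvec_path, b0_threshold)
    return DWIStudy(data, gradients, voxel_size, affine)


def write_dwi(study: DWIStudy, image_path, bval_path, bvec_path):
    """Write a DWIStudy as float32 NIfTI plus FSL bval/bvec files."""
    img = nib.Nifti1Image(study.data.astype(np.float32), study.affine)
    img.header.set_zooms(tuple(study.voxel_size) + (1.0,))
    nib.save(img, str(image_path))
    write_gradient_table(study.gradients, bval_path, bvec_path)


def read_structural(image_path) -> StructuralImage:
    data, voxel_size, affine = _load_nifti(image_path)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return StructuralImage(data, voxel_size, affine)


def write_volume(data: np.ndarray, affine, path, dtype=np.float32):
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=dtype), affine), str(path))


# ---------------------------------------------------------------------------
# Resampling between subject space and the normalized grid
# ---------------------------------------------------------------------------

_ORDERS = {"linear": 1, "nearest": 0}


def _voxel_map(src_affine, dst_affine):
    """Matrix/offset mapping destination voxel indices to source indices."""
    inv = np.linalg.inv(_check_affine(src_affine))
    dst = _check_affine(dst_affine)
    M = inv[:3, :3] @ dst[:3, :3]
    o = inv[:3, :3] @ dst[:3, 3] + inv[:3, 3]
    return M, o


def _integer_shift(volume, offset, out_shape):
    """Exact centered pad/crop: source index = dest index + offset."""
    out = np.zeros(out_shape, dtype=volume.dtype)
    src_sl, dst_sl = [], []
    for ax in range(3):
        k = int(round(offset[ax]))
        lo = max(0, -k)
        hi = min(out_shape[ax], volume.shape[ax] - k)
        if hi <= lo:
            return out
        dst_sl.append(slice(lo, hi))
        src_sl.append(slice(lo + k, hi + k))
    out[tuple(dst_sl)] = volume[tuple(src_sl)]
    return out


def _resample(volume, src_affine, dst_affine, out_shape, interpolation):
    if interpolation not in _ORDERS:
        raise ValueError(f"unknown interpolation {interpolation!r}; "
                         f"choose from {sorted(_ORDERS)}")
    M, o = _voxel_map(src_affine, dst_affine)
    if (np.allclose(M, np.eye(3), atol=1e-9)
            and np.allclose(o, np.round(o), atol=1e-6)):
        return _integer_shift(volume, o, tuple(out_shape))
    return ndimage.affine_transform(
        volume, M, offset=o, output_shape=tuple(out_shape),
        order=_ORDERS[interpolation], mode="constant", cval=0.0,
        prefilter=False)


def resample_to_grid(volume, affine, grid: NormalizedGrid,
                     interpolation: str = "linear", grid_affine=None):
    """Resample a 3-D volume onto the normalized grid.

    Returns ``(grid_volume, grid_affine)``.  When ``grid_affine`` is not
    given, it is derived so that the center of the input image lands on the
    center of the grid (centered pad/crop).  Out-of-field voxels are 0.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise GeometryError("resample_to_grid expects a 3-D volume")
    if grid_affine is None:
        grid_affine = grid.affine_for(volume.shape, affine)
    out = _resample(volume, affine, grid_affine, grid.shape, interpolation)
    return out, grid_affine


def resample_from_grid(grid_volume, grid_affine, target_shape, target_affine,
                       interpolation: str = "linear"):
    """Inverse of :func:`resample_to_grid`: grid array back to subject space."""
    return _resample(np.asarray(grid_volume), grid_affine, target_affine,
                     target_shape, interpolation)
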