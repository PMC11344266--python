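"""Intensity normalization, brain masking, and FOV-cutoff handling.

Normalization follows the convention of mapping the 99.9th-percentile
intensity of a whole DWI study (all volumes jointly) to 1 and the minimum
to 0; the structural image gets its own parameters.  FOV truncation is
simulated by zeroing a contiguous block of axial slices adjacent to the
superior or inferior brain boundary, recorded in an :class:`FOVMask`
(1 = acquired, 0 = missing).  The final recombination of an imputed
volume with the acquired data is ``m ⊙ x + (1 − m) ⊙ y``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core_io import DWIStudy
from .errors import MaskingError


@dataclass(frozen=True)
class NormalizationParams:
    """Affine intensity map: ``normalized = clip(x / scale, 0, 1)``."""

    scale: float
    floor: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError(f"normalization scale must be > 0, got {self.scale}")


@dataclass
class FOVMask:
    """Binary acquired-region mask; the missing region (0) is a contiguous
    block of complete axial slices at one z-extreme of the brain."""

    mask: np.ndarray
    cut_side: str = "none"       # {"top", "bottom", "none"}
    cut_mm: float = 0.0

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(np.uint8)
        if self.mask.ndim != 3:
            raise ValueError("FOV mask must be 3-D")
        if self.cut_side not in ("top", "bottom", "none"):
            raise ValueError(f"invalid cut side {self.cut_side!r}")

    @property
    def missing(self) -> np.ndarray:
        return 1 - self.mask

    def missing_z_slices(self) -> np.ndarray:
        """Indices of axial slices that are entirely missing."""
        full = self.mask.reshape(-1, self.mask.shape[2]).max(axis=0)
        return np.flatnonzero(full == 0)

    @classmethod
    def all_acquired(cls, shape) -> "FOVMask":
        return cls(np.ones(shape, dtype=np.uint8), "none", 0.0)


@dataclass
class BrainMask:
    """Binary brain mask used to restrict metrics and locate the z-extent."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(np.uint8)
        if self.mask.ndim != 3:
            raise ValueError("brain mask must be 3-D")
        if not self.mask.any():
            raise MaskingError("brain mask is empty")

    def z_extent(self) -> tuple[int, int]:
        """Inclusive (z_min, z_max) of brain voxels along the axial axis."""
        zs = np.flatnonzero(self.mask.any(axis=(0, 1)))
        return int(zs[0]), int(zs[-1])


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def compute_normalization(study, percentile: float = 99.9,
                          exclude_background: bool = False) -> NormalizationParams:
    """Normalization parameters shared by all volumes of one DWI study.

    ``scale`` is the given percentile of all voxels across all volumes
    jointly (default 99.9).  ``exclude_background`` restricts the
    percentile to strictly positive voxels.
    """
    data = study.data if isinstance(study, DWIStudy) else np.asarray(study)
    if data.size == 0:
        raise ValueError("empty study")
    values = data[data > 0] if exclude_background else data
    if values.size == 0:
        raise ValueError("study has no positive voxels to normalize against")
    scale = float(np.percentile(values, percentile))
    if scale <= 0:
        raise ValueError("degenerate normalization scale (all-zero study?)")
    return NormalizationParams(scale=scale, floor=0.0)


def apply_normalization(volume, params: NormalizationParams) -> np.ndarray:
    """Map intensities into [0, 1]: ``clip(volume / scale, 0, 1)``."""
    return np.clip(np.asarray(volume, dtype=np.float32) / params.scale, 0.0, 1.0)


def undo_normalization(volume, params: NormalizationParams) -> np.ndarray:
    return np.asarray(volume, dtype=np.float32) * params.scale


# ---------------------------------------------------------------------------
# Brain masking (median filter + Otsu + largest component)
# ---------------------------------------------------------------------------

def compute_brain_mask(volume, median_size: int = 3) -> BrainMask:
    """Simple median-Otsu brain mask from a 3-D volume (typically mean b0)."""
    volume = np.asarray(volume, dtype=np.float32)
    if volume.ndim != 3:
        raise ValueError("compute_brain_mask expects a 3-D volume")
    if np.ptp(volume) == 0:
        raise MaskingError("constant volume: no threshold separates brain")
    filtered = ndimage.median_filter(volume, size=median_size)
    try:
        thr = threshold_otsu(filtered)
    except ValueError as exc:  # pragma: no cover - skimage degenerate input
        raise MaskingError(str(exc)) from exc
    binary = filtered > thr
    if not binary.any():
        raise MaskingError("empty mask after Otsu thresholding")
    labels, n = ndimage.label(binary)
    largest = np.argmax(ndimage.sum_labels(binary, labels, range(1, n + 1))) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    return BrainMask(mask.astype(np.uint8))


# ---------------------------------------------------------------------------
# FOV cutoff simulation and recombination
# ---------------------------------------------------------------------------

def slices_for_cut(cut_mm: float, voxel_size: float) -> int:
    """Number of axial slices removed by a cut of ``cut_mm`` millimetres.

    Rounds half away from zero, so a 2.5 mm cut on a 1 mm grid removes 3
    slices.
    """
    if cut_mm < 0:
        raise ValueError("cut_mm must be non-negative")
    x = cut_mm / voxel_size
    return int(np.floor(x + 0.5))


def simulate_cutoff(study, brain: BrainMask, cut_mm: float, cut_side: str,
                    rng: np.random.Generator | None = None,
                    voxel_size: float | None = None):
    """Zero a block of axial slices at one end of the brain.

    The ``k = round(cut_mm / voxel_size)`` slices adjacent to the brain's
    superior (``cut_side="top"``) or inferior (``"bottom"``) boundary are
    set to 0 in every volume; the returned :class:`FOVMask` marks exactly
    those slices missing.  ``cut_side="random"`` draws top/bottom with
    equal probability from ``rng``.

    Returns ``(truncated_study, fov_mask)``; accepts either a
    :class:`DWIStudy` or a bare 3-D/4-D array plus ``voxel_size``.
    """
    if isinstance(study, DWIStudy):
        data, vs = study.data, study.voxel_size[2]
    else:
        data = np.asarray(study)
        if voxel_size is None:
            raise ValueError("voxel_size required for bare-array input")
        vs = float(voxel_size)

    if cut_side == "random":
        if rng is None:
            raise ValueError("rng required for cut_side='random'")
        cut_side = "top" if rng.random() < 0.5 else "bottom"
    if cut_side not in ("top", "bottom"):
        raise ValueError(f"cut_side must be 'top' or 'bottom', got {cut_side!r}")

    shape3 = data.shape[:3]
    k = slices_for_cut(cut_mm, vs)
    z_lo, z_hi = brain.z_extent()
    if k > (z_hi - z_lo + 1):
        raise ValueError(
            f"cut of {cut_mm} mm ({k} slices) exceeds brain extent "
            f"[{z_lo}, {z_hi}]")

    mask = np.ones(shape3, dtype=np.uint8)
    if k > 0:
        if cut_side == "top":
            z_sl = slice(z_hi - k + 1, z_hi + 1)
        else:
            z_sl = slice(z_lo, z_lo + k)
        mask[:, :, z_sl] = 0

    truncated = data.copy()
    if k > 0:
        if truncated.ndim == 4:
            truncated[:, :, z_sl, :] = 0
        else:
            truncated[:, :, z_sl] = 0

    fov = FOVMask(mask, cut_side if k > 0 else "none", float(cut_mm))
    if isinstance(study, DWIStudy):
        return study.with_data(truncated), fov
    return truncated, fov


def draw_cutoff(rng: np.random.Generator, max_mm: float = 50.0):
    """Training augmentation draw: cut_mm ~ U[0, max_mm], side ~ {top, bottom}."""
    return float(rng.uniform(0.0, max_mm)), ("top" if rng.random() < 0.5 else "bottom")


def recombine(acquired, imputed, fov: FOVMask) -> np.ndarray:
    """``m ⊙ acquired + (1 − m) ⊙ imputed`` — acquired voxels are untouched.

    Works on 3-D volumes or 4-D studies (mask broadcast over volumes).
    """
    acquired = np.asarray(acquired)
    imputed = np.asarray(imputed)
    if acquired.shape != imputed.shape:
        raise ValueError(f"shape mismatch: {acquired.shape} vs {imputed.shape}")
    m = fov.mask
    if acquired.ndim == 4:
        m = m[..., None]
    if m.shape[:3] != acquired.shape[:3]:
        raise ValueError(
            f"mask shape {fov.mask.shape} does not match data {acquired.shape}")
    return np.where(m.astype(bool), acquired, imputed)
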