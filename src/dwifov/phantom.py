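"""Synthetic DWI + structural phantoms with tensor-model diffusion contrast.

Each phantom is a set of nested superellipsoids on an isotropic grid —
background, a thin CSF rim, a gray-matter shell and a white-matter core
(flat-topped, as a real head is) — with per-compartment unattenuated
signal ``S0`` and diffusion tensor ``D``.  The DWI signal for gradient
direction ``g`` at b-value ``b`` follows the single-tensor forward model
``S = S0 · exp(−b · gᵀ D g)``; white matter carries a smooth swirl of
prolate-tensor orientations so the contrast is genuinely
direction-dependent, and the S0/tensor maps are lightly smoothed before
synthesis to emulate partial-volume mixing.  DWI magnitudes receive
Rician noise.

Two features decouple the DWI from the structural channel the way real
acquisitions are decoupled: a DWI-only smooth multiplicative S0 field
(bias-field / physiology stand-in, invisible in the structural image and
cancelling exactly in ADC ratios), and a residual sub-voxel T1w→DWI
misregistration.  Both make imputation difficulty grow with distance
from the acquired region.  The structural channel encodes the same
compartments with a distinct (T1w-like) contrast ordering plus its own
noise: informative about tissue boundaries without duplicating the
diffusion contrast.

Defaults are desk scale: 48³ voxels @ 1 mm, one b0 plus six directions on
a b = 1300 s/mm² shell, σ = 0.02·max(S0).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core_io import (DWIStudy, GradientTable, StructuralImage, write_dwi,
                      write_volume, read_dwi, read_structural)
from .normalization import BrainMask


@dataclass(frozen=True)
class Compartment:
    s0: float
    eigenvalues: tuple[float, float, float]   # mm²/s, descending


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: float = 1.0
    n_b0: int = 1
    n_weighted: int = 6
    bval: float = 1300.0
    sigma: float = 0.02          # Rician noise level, relative to max S0
    structural_sigma: float = 0.02
    # smooth multiplicative S0 field on the DWI only (bias-field /
    # physiology stand-in, invisible in the structural channel); cancels
    # in ADC ratios
    bias_field_amplitude: float = 0.25
    # partial-volume mixing: Gaussian smoothing (voxels) applied to the
    # S0 map and the tensor field before signal synthesis, so compartment
    # boundaries are gradual as in real tissue
    partial_volume_sigma: float = 0.5
    # residual T1w->DWI co-registration error: the structural channel is
    # shifted by a random sub-voxel offset of up to this many mm per axis
    t1_misregistration_mm: float = 1.5
    seed: int = 0
    # brain ellipsoid semi-axes as a fraction of the grid half-extent
    semi_axes: tuple[float, float, float] = (0.80, 0.88, 0.74)
    rotation_deg: float = 0.0    # rotation of the ellipsoid about z
    # superellipsoid exponent: 2 is a plain ellipsoid; higher values
    # flatten the top/bottom as in a real head, keeping axial
    # cross-sections large until just below the apex
    shape_exponent: float = 3.0
    # nested compartment boundaries as fractions of the brain radius;
    # the CSF rim is thin, as in a real head, so brain tissue reaches
    # close to the apex
    gray_radius: float = 0.95
    white_radius: float = 0.85
    csf: Compartment = Compartment(1.0, (3.0e-3, 3.0e-3, 3.0e-3))
    gray: Compartment = Compartment(0.75, (0.8e-3, 0.8e-3, 0.8e-3))
    white: Compartment = Compartment(0.65, (0.9e-3, 0.5e-3, 0.5e-3))
    structural_contrast: dict = field(default_factory=lambda: {
        "csf": 0.12, "gray": 0.55, "white": 0.90})

    def __post_init__(self):
        if not (0 < self.white_radius < self.gray_radius < 1.0):
            raise ValueError("compartments must be strictly nested: "
                             "0 < white_radius < gray_radius < 1")
        if self.n_b0 < 1:
            raise ValueError("at least one b0 volume is required")


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` well-spread unit vectors on the sphere (golden-spiral layout)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5 ** 0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def _rotation_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _compartment_labels(spec: PhantomSpec):
    """0 = background, 1 = CSF rim, 2 = gray shell, 3 = white core."""
    shape = np.asarray(spec.shape)
    center = (shape - 1) / 2.0
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in spec.shape],
                               indexing="ij"), axis=-1).astype(float)
    rel = (idx - center) @ _rotation_z(spec.rotation_deg)
    half = (shape / 2.0) * np.asarray(spec.semi_axes)
    p = spec.shape_exponent
    r = ((np.abs(rel) / half) ** p).sum(axis=-1) ** (1.0 / p)
    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[r <= 1.0] = 1
    labels[r <= spec.gray_radius] = 2
    labels[r <= spec.white_radius] = 3
    return labels, rel


def _tensor_field(spec: PhantomSpec, labels, rel) -> np.ndarray:
    """Per-voxel 3×3 diffusion tensor (mm²/s)."""
    D = np.zeros(spec.shape + (3, 3), dtype=np.float64)
    eye = np.eye(3)
    for lab, comp in ((1, spec.csf), (2, spec.gray)):
        D[labels == lab] = comp.eigenvalues[0] * eye
    # white matter: prolate tensor along a smooth swirl (tangential) field
    lam1, lam2, _ = spec.white.eigenvalues
    white = labels == 3
    if white.any():
        p = rel[white]
        e1 = np.stack([-p[:, 1], p[:, 0], 0.35 * p[:, 2]], axis=1)
        norms = np.linalg.norm(e1, axis=1, keepdims=True)
        # voxels on the swirl axis get an x-oriented fiber
        fallback = np.tile([1.0, 0.0, 0.0], (len(e1), 1))
        e1 = np.where(norms > 1e-9, e1 / np.maximum(norms, 1e-9), fallback)
        outer = np.einsum("ni,nj->nij", e1, e1)
        D[white] = lam2 * eye + (lam1 - lam2) * outer
    return D


def tensor_signal(s0: np.ndarray, tensors: np.ndarray, bvals: np.ndarray,
                  bvecs: np.ndarray) -> np.ndarray:
    """Noiseless forward model ``S_v = S0 · exp(−b_v · g_vᵀ D g_v)``."""
    quad = np.einsum("...ij,vi,vj->...v", tensors, bvecs, bvecs)
    return s0[..., None] * np.exp(-bvals[None, None, None, :] * quad)


def add_rician_noise(signal: np.ndarray, sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the complex signal with i.i.d. Gaussian noise σ added
    to the real and imaginary channels."""
    if sigma == 0:
        return signal.copy()
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative intensity field, 1 ± amplitude."""
    if spec.bias_field_amplitude == 0:
        return np.ones(spec.shape)
    from scipy import ndimage
    noise = rng.normal(size=spec.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=min(spec.shape) / 12.0)
    smooth /= smooth.std()      # unit rms: amplitude is the rms deviation
    return np.maximum(1.0 + spec.bias_field_amplitude * smooth, 0.1)


def generate_phantom(spec: PhantomSpec):
    """Simulate one phantom case.

    Returns ``(study, structural, brain_mask, tensor_field)`` where the
    study and structural image live on the phantom grid with a world
    origin at the grid center (so the normalized working grid of equal
    shape coincides with the subject grid).
    """
    rng = np.random.default_rng(spec.seed)
    labels, rel = _compartment_labels(spec)
    if not (labels == 3).any():
        raise ValueError("degenerate spec: white-matter core is empty")

    s0 = np.zeros(spec.shape, dtype=np.float64)
    for lab, comp in ((1, spec.csf), (2, spec.gray), (3, spec.white)):
        s0[labels == lab] = comp.s0
    tensors = _tensor_field(spec, labels, rel)
    if spec.partial_volume_sigma > 0:
        # mix compartments at boundaries *before* signal synthesis: the
        # signal model stays exactly S0·exp(−b·gᵀDg) for the returned
        # (smoothed) S0 and tensor field
        from scipy import ndimage
        s0 = ndimage.gaussian_filter(s0, spec.partial_volume_sigma)
        tensors = ndimage.gaussian_filter(
            tensors, (spec.partial_volume_sigma,) * 3 + (0.0, 0.0))
    # the DWI-only smooth field makes imputation difficulty grow with
    # distance from acquired data: unlike compartment identity, it cannot
    # be read off the structural channel
    s0_dwi = s0 * _bias_field(spec, rng)

    bvals = np.concatenate([np.zeros(spec.n_b0),
                            np.full(spec.n_weighted, spec.bval)])
    bvecs = np.concatenate([np.zeros((spec.n_b0, 3)),
                            fibonacci_directions(spec.n_weighted)])
    clean = tensor_signal(s0_dwi, tensors, bvals, bvecs)
    noisy = add_rician_noise(clean, spec.sigma * s0.max(), rng)

    vs = spec.voxel_size
    affine = np.eye(4)
    affine[:3, :3] *= vs
    affine[:3, 3] = -vs * (np.asarray(spec.shape) - 1) / 2.0

    study = DWIStudy(noisy.astype(np.float32), GradientTable(bvals, bvecs),
                     (vs, vs, vs), affine)

    t1 = np.zeros(spec.shape, dtype=np.float64)
    for lab, name in ((1, "csf"), (2, "gray"), (3, "white")):
        t1[labels == lab] = spec.structural_contrast[name]
    if spec.partial_volume_sigma > 0:
        from scipy import ndimage
        t1 = ndimage.gaussian_filter(t1, spec.partial_volume_sigma)
    if spec.t1_misregistration_mm > 0:
        from scipy import ndimage
        offset = rng.uniform(-spec.t1_misregistration_mm,
                             spec.t1_misregistration_mm, 3) / spec.voxel_size
        t1 = ndimage.shift(t1, offset, order=1, mode="constant", cval=0.0)
    t1 += rng.normal(0.0, spec.structural_sigma, spec.shape) * (labels > 0)
    structural = StructuralImage(np.clip(t1, 0, None).astype(np.float32),
                                 (vs, vs, vs), affine)

    brain = BrainMask((labels > 0).astype(np.uint8))
    return study, structural, brain, tensors


def case_spec(base: PhantomSpec, seed: int, rng: np.random.Generator) -> PhantomSpec:
    """Geometric jitter for one dataset case: ±8% semi-axes, ±15° rotation."""
    jitter = rng.uniform(0.92, 1.08, 3)
    axes = tuple(float(np.clip(a * j, 0.4, 0.95))
                 for a, j in zip(base.semi_axes, jitter))
    return replace(base, seed=seed, semi_axes=axes,
                   rotation_deg=float(rng.uniform(-15.0, 15.0)))


def _case_seed(master_seed: int, index: int) -> int:
    h = hashlib.sha256(f"{master_seed}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def make_cases(spec: PhantomSpec, count: int, master_seed: int, offset: int = 0):
    """Generate ``count`` jittered phantom cases in memory."""
    cases = []
    for i in range(count):
        seed = _case_seed(master_seed, offset + i)
        rng = np.random.default_rng(seed)
        cases.append(generate_phantom(case_spec(spec, seed, rng)))
    return cases


def make_dataset(spec: PhantomSpec, n_train: int, n_val: int, n_test: int,
                 out_dir, seed: int, overwrite: bool = False) -> dict:
    """Write train/val/test phantom splits to disk.

    Each case directory holds ``dwi.nii.gz`` + ``dwi.bval``/``dwi.bvec``,
    ``t1.nii.gz``, ``brain_mask.nii.gz`` and the ground-truth tensor field
    ``tensors.npz``; a ``manifest.json`` at the root records the split and
    per-case seeds.  Fully determined by ``seed``.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty")
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "splits": {}}
    offset = 0
    for split, count in (("train", n_train), ("val", n_val), ("test", n_test)):
        entries = []
        for i in range(count):
            case_seed = _case_seed(seed, offset + i)
            rng = np.random.default_rng(case_seed)
            cspec = case_spec(spec, case_seed, rng)
            study, structural, brain, tensors = generate_phantom(cspec)
            case_dir = out_dir / f"{split}_{i:03d}"
            case_dir.mkdir(exist_ok=True)
            write_dwi(study, case_dir / "dwi.nii.gz", case_dir / "dwi.bval",
                      case_dir / "dwi.bvec")
            write_volume(structural.data, structural.affine,
                         case_dir / "t1.nii.gz")
            write_volume(brain.mask, structural.affine,
                         case_dir / "brain_mask.nii.gz", dtype=np.uint8)
            np.savez_compressed(case_dir / "tensors.npz", tensors=tensors)
            entries.append({"dir": case_dir.name, "seed": case_seed})
        manifest["splits"][split] = entries
        offset += count
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_case(case_dir):
    """Read one on-disk phantom case back into memory."""
    case_dir = Path(case_dir)
    study = read_dwi(case_dir / "dwi.nii.gz", case_dir / "dwi.bval",
                     case_dir / "dwi.bvec")
    structural = read_structural(case_dir / "t1.nii.gz")
    brain = BrainMask(np.asarray(
        read_structural(case_dir / "brain_mask.nii.gz").data) > 0.5)
    tensors = None
    tpath = case_dir / "tensors.npz"
    if tpath.exists():
        with np.load(tpath) as f:
            tensors = f["tensors"]
    return study, structural, brain, tensors
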