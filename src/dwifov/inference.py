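"""Full-FOV imputation: per-view slice generation, view merging, and
recombination of the imputed missing region with the acquired data.

For each volume of a truncated study the pipeline routes to the b0 or
diffusion-weighted generator pair, predicts every sagittal and every
coronal slice on the normalized grid, averages the two predicted volumes
voxel-wise, keeps only the missing-region slices, resamples them back to
subject space, and recombines ``m ⊙ x_v + (1 − m) ⊙ ỹ_v`` so that every
acquired voxel of the input survives bit-identically.
"""

from __future__ import annotations

import numpy as np

from .core_io import (DWIStudy, NormalizedGrid, resample_from_grid,
                      resample_to_grid)
from .errors import ConfigurationError
from .gan import ModelBundle, forward_generate
from .normalization import (BrainMask, FOVMask, apply_normalization,
                            compute_brain_mask, compute_normalization,
                            recombine, undo_normalization)
from .patches import brain_slice_range, extract_patch, view_axis


def predict_volume_view(generator, dwi_volume, structural, view: str, n: int,
                        brain: BrainMask | None = None,
                        batch_size: int = 32) -> np.ndarray:
    """Predict every slice along the view axis and stack them into a volume.

    Inputs are [0, 1]-normalized grid volumes.  When a brain mask is given,
    prediction is restricted to the brain's bounding-box slice range (the
    rest of the volume stays 0).
    """
    dwi_volume = np.asarray(dwi_volume, dtype=np.float32)
    structural = np.asarray(structural, dtype=np.float32)
    axis = view_axis(view)
    expected = 2 * (2 * n + 1)
    if generator.in_channels != expected:
        raise ValueError(
            f"generator expects {generator.in_channels} channels but the "
            f"requested n={n} stack has {expected}")
    extent = dwi_volume.shape[axis]
    lo, hi = brain_slice_range(brain, view, extent)
    out = np.zeros_like(dwi_volume)
    indices = list(range(lo, hi + 1))
    for start in range(0, len(indices), batch_size):
        chunk = indices[start:start + batch_size]
        stacks = np.stack([
            extract_patch(dwi_volume, structural, view, i, n).input_stack
            for i in chunk])
        preds = forward_generate(generator, stacks)
        for i, pred in zip(chunk, preds):
            if axis == 0:
                out[i] = pred
            else:
                out[:, i] = pred
    return out


def merge_views(pred_sagittal, pred_coronal) -> np.ndarray:
    """Voxel-wise arithmetic mean of the two per-view predictions."""
    a = np.asarray(pred_sagittal)
    b = np.asarray(pred_coronal)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return (a + b) / 2.0


def derive_fov_mask(data_4d, brain: BrainMask) -> FOVMask:
    """Heuristic FOV mask: all-zero axial slice runs adjacent to the
    brain's z-extremes (brain extent taken from a complete-FOV mask,
    typically structural-derived)."""
    data_4d = np.asarray(data_4d)
    z_lo, z_hi = brain.z_extent()
    nonzero = data_4d.reshape(-1, data_4d.shape[2],
                              data_4d.shape[3]).any(axis=(0, 2))
    mask = np.ones(data_4d.shape[:3], dtype=np.uint8)
    side, n_missing = "none", 0
    z = z_hi
    while z >= z_lo and not nonzero[z]:
        mask[:, :, z] = 0
        z -= 1
        n_missing += 1
        side = "top"
    if n_missing == 0:
        z = z_lo
        while z <= z_hi and not nonzero[z]:
            mask[:, :, z] = 0
            z += 1
            n_missing += 1
            side = "bottom"
    return FOVMask(mask, side, float(n_missing))


def _is_on_grid(study: DWIStudy, grid: NormalizedGrid) -> bool:
    if study.shape != grid.shape:
        return False
    if not np.allclose(study.voxel_size, grid.voxel_size):
        return False
    return np.allclose(study.affine[:3, :3],
                       np.eye(3) * grid.voxel_size, atol=1e-9)


def impute_study(bundle: ModelBundle, study: DWIStudy, structural,
                 fov: FOVMask | None = None, brain: BrainMask | None = None,
                 grid: NormalizedGrid | None = None, n: int | None = None,
                 mask_imputed_to_brain: bool = True,
                 ablate_structural: bool = False) -> tuple[DWIStudy, FOVMask]:
    """Impute the missing FOV of a truncated study.

    Returns ``(imputed_study, fov_mask)``.  The gradient table and affine
    are copied unchanged; voxels acquired in the input are bit-identical
    in the output.  ``structural`` must be co-registered with the study.
    """
    bundle.require_complete()
    grid = grid or NormalizedGrid(shape=study.shape,
                                  voxel_size=float(study.voxel_size[2]))
    t1_data = structural.data if hasattr(structural, "data") else structural
    t1_affine = getattr(structural, "affine", study.affine)

    dwi_params = compute_normalization(study)
    t1_params = compute_normalization(np.asarray(t1_data))

    on_grid = _is_on_grid(study, grid)
    if on_grid:
        grid_affine = study.affine
        dwi_grid = apply_normalization(study.data, dwi_params)
        t1_grid = apply_normalization(np.asarray(t1_data), t1_params)
    else:
        grid_affine = grid.affine_for(study.shape, study.affine)
        vols = [resample_to_grid(study.data[..., v], study.affine, grid,
                                 "linear", grid_affine)[0]
                for v in range(study.n_volumes)]
        dwi_grid = apply_normalization(np.stack(vols, axis=-1), dwi_params)
        t1_grid = apply_normalization(
            resample_to_grid(np.asarray(t1_data), t1_affine, grid, "linear",
                             grid_affine)[0], t1_params)

    if brain is not None:
        brain_grid = brain if on_grid else BrainMask(
            resample_to_grid(brain.mask, t1_affine, grid, "nearest",
                             grid_affine)[0] > 0.5)
    else:
        # estimate on the grid from the structural image, then carry a
        # subject-space copy for FOV derivation
        brain_grid = compute_brain_mask(t1_grid)
        brain = brain_grid if on_grid else BrainMask(
            resample_from_grid(brain_grid.mask.astype(np.float32),
                               grid_affine, study.shape, study.affine,
                               "nearest") > 0.5)

    if fov is None:
        fov = derive_fov_mask(study.data, brain)
    fov_grid = fov if on_grid else FOVMask(
        resample_to_grid(fov.mask.astype(np.float32), study.affine, grid,
                         "nearest", grid_affine)[0] > 0.5,
        fov.cut_side, fov.cut_mm)

    missing_grid = ~fov_grid.mask.astype(bool)
    structural_for_net = (np.zeros_like(t1_grid) if ablate_structural
                          else t1_grid)

    out_data = study.data.copy()
    if missing_grid.any():
        for group in ("b0", "bweighted"):
            idx = study.gradients.group_indices(group)
            if idx.size == 0:
                continue
            gs = bundle.get(group, "sagittal")
            gc = bundle.get(group, "coronal")
            n_eff = n if n is not None else (gs.spec.in_channels // 2 - 1) // 2
            if gs.in_channels != 2 * (2 * n_eff + 1):
                raise ConfigurationError("bundle n does not match request")
            for v in idx:
                vol = dwi_grid[..., v]
                merged = merge_views(
                    predict_volume_view(gs, vol, structural_for_net,
                                        "sagittal", n_eff, brain=brain_grid),
                    predict_volume_view(gc, vol, structural_for_net,
                                        "coronal", n_eff, brain=brain_grid))
                if mask_imputed_to_brain:
                    merged = merged * brain_grid.mask
                pred = undo_normalization(merged, dwi_params)
                if on_grid:
                    pred_subject = pred
                else:
                    pred_subject = resample_from_grid(
                        pred, grid_affine, study.shape, study.affine, "linear")
                out_data[..., v] = recombine(study.data[..., v],
                                             pred_subject.astype(
                                                 study.data.dtype), fov)
    imputed = DWIStudy(out_data, study.gradients,
                       study.voxel_size, study.affine.copy())
    return imputed, fov
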