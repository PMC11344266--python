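"""Quantitative evaluation of FOV imputation.

All metrics are computed within an evaluation region (typically brain
mask ∩ missing region) on normalized intensities with ``data_range = 1``:
masked MSE, PSNR ``10·log10(range²/MSE)`` (``+inf`` when MSE is 0) and a
3-D SSIM with a uniform cubic window of side 7.  Beyond the aggregate
numbers, the module stratifies performance by the distance of each
missing axial slice from the nearest acquired slice, computes per-direction
apparent-diffusion-coefficient (ADC) maps ``−ln(S/S0)/b`` to probe for
gradient-direction bias, and tests that bias with a Kruskal–Wallis rank
test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core_io import DWIStudy
from .normalization import BrainMask, FOVMask, compute_normalization, apply_normalization


def _as_bool_mask(mask) -> np.ndarray:
    m = mask.mask if isinstance(mask, (BrainMask, FOVMask)) else mask
    return np.asarray(m).astype(bool)


def masked_mse(reference, test, mask) -> float:
    """Mean squared difference over mask voxels only."""
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    m = _as_bool_mask(mask)
    if m.shape != reference.shape:
        raise ValueError("mask shape does not match data")
    if not m.any():
        raise ValueError("empty evaluation mask")
    d = reference[m] - test[m]
    return float(np.mean(d * d))


def masked_psnr(reference, test, mask, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; ``+inf`` for identical inputs."""
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = masked_mse(reference, test, mask)
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range ** 2 / mse))


def _ssim_map(reference, test, window: int, data_range: float):
    """Pointwise SSIM map over every voxel (reflect-padded windows).

    Uniform (box) window; covariances use the unbiased N/(N−1)
    normalization.  Window centers closer than ``window // 2`` to the
    volume boundary use reflected data; the inner region is identical to
    the valid-window map.  Returns the full-size map and the pad width.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("SSIM window must be odd and >= 3")
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError("shape mismatch")
    if any(s < window for s in reference.shape):
        raise ValueError(f"volume smaller than the {window}³ SSIM window")

    def f(a):
        return ndimage.uniform_filter(a, size=window, mode="reflect")

    npix = window ** reference.ndim
    cov_norm = npix / (npix - 1)
    ux, uy = f(reference), f(test)
    uxx, uyy, uxy = f(reference * reference), f(test * test), f(reference * test)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    ssim = ((2 * ux * uy + c1) * (2 * vxy + c2)
            / ((ux * ux + uy * uy + c1) * (vx + vy + c2)))
    return ssim, window // 2


def ssim_3d(reference, test, mask=None, window: int = 7,
            data_range: float = 1.0) -> float:
    """Mean structural similarity within the mask.

    Without a mask the average runs over valid (fully inside) window
    centers only — the usual whole-image convention; with a mask every
    masked voxel contributes, using reflect-padded windows near the
    volume boundary so thin regions at the edge of the grid remain
    scoreable.
    """
    smap, pad = _ssim_map(reference, test, window, data_range)
    if mask is None:
        inner = tuple(slice(pad, s - pad) for s in smap.shape)
        return float(smap[inner].mean())
    m = _as_bool_mask(mask)
    if m.shape != np.asarray(reference).shape:
        raise ValueError("mask shape does not match data")
    if not m.any():
        raise ValueError("empty evaluation mask")
    return float(smap[m].mean())


# ---------------------------------------------------------------------------
# Distance-stratified performance
# ---------------------------------------------------------------------------

def slice_distances_mm(fov: FOVMask, voxel_size: float,
                       brain: BrainMask | None = None) -> dict[int, float]:
    """Distance (mm) of each fully missing axial slice to the nearest
    informative acquired slice, measured along the axial axis.

    When a brain mask is given, only acquired slices containing brain
    count as reference: empty grid slices beyond the brain's apex are
    outside the scanner's field of view and carry no signal, so a
    missing slice near the apex is far from — not adjacent to — the
    acquired data.
    """
    missing = fov.missing_z_slices()
    if missing.size == 0:
        raise ValueError("FOV mask has no missing slices")
    acquired = np.setdiff1d(np.arange(fov.mask.shape[2]), missing)
    if brain is not None:
        has_brain = np.flatnonzero(brain.mask.any(axis=(0, 1)))
        acquired = np.intersect1d(acquired, has_brain)
    if acquired.size == 0:
        raise ValueError("FOV mask has no (brain-bearing) acquired slices")
    return {int(z): float(np.abs(acquired - z).min() * voxel_size)
            for z in missing}


def distance_stratified_metrics(reference, test, fov: FOVMask,
                                brain: BrainMask, voxel_size: float = 1.0,
                                bin_mm: float = 1.0,
                                data_range: float = 1.0,
                                window: int = 7) -> pd.DataFrame:
    """Per-distance-bin PSNR and SSIM for the missing axial slices.

    ``reference``/``test`` may be 3-D volumes or 4-D studies (metrics pool
    all volumes).  SSIM values come from the 3-D SSIM map averaged over
    each bin's brain voxels.
    """
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    dists = slice_distances_mm(fov, voxel_size, brain=brain)
    bmask = _as_bool_mask(brain)

    vols_r = reference[..., None] if reference.ndim == 3 else reference
    vols_t = test[..., None] if test.ndim == 3 else test
    smaps = [_ssim_map(vols_r[..., v], vols_t[..., v], window, data_range)[0]
             for v in range(vols_r.shape[3])]

    bins: dict[float, list[int]] = {}
    for z, d in dists.items():
        key = float(np.ceil(d / bin_mm) * bin_mm)
        bins.setdefault(key, []).append(z)

    rows = []
    for d in sorted(bins):
        zs = bins[d]
        sel = np.zeros(bmask.shape, dtype=bool)
        sel[:, :, zs] = True
        sel &= bmask
        if not sel.any():
            continue
        err = [masked_mse(vols_r[..., v], vols_t[..., v], sel)
               for v in range(vols_r.shape[3])]
        mse = float(np.mean(err))
        psnr = float("inf") if mse == 0 else 10.0 * np.log10(data_range ** 2 / mse)
        ssim = float(np.mean([s[sel].mean() for s in smaps]))
        rows.append({"distance_mm": d, "n_slices": len(zs),
                     "n_voxels": int(sel.sum()), "mse": mse, "psnr": psnr,
                     "ssim": ssim})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ADC and gradient-direction bias
# ---------------------------------------------------------------------------

def adc_map(study: DWIStudy, direction_index: int) -> np.ndarray:
    """Per-voxel apparent diffusion coefficient for one gradient direction.

    ``ADC = −ln(S/S0)/b`` (mm²/s) with ``S0`` the mean b0 volume; voxels
    with non-positive ``S`` or ``S0`` are NaN and excluded downstream.
    """
    b0_idx = study.gradients.b0_indices
    if b0_idx.size == 0:
        raise ValueError("study has no b0 volume")
    weighted = study.gradients.weighted_indices
    if not 0 <= direction_index < weighted.size:
        raise ValueError(f"direction index {direction_index} out of range "
                         f"[0, {weighted.size})")
    v = weighted[direction_index]
    b = float(study.gradients.bvals[v])
    s0 = study.data[..., b0_idx].mean(axis=3).astype(np.float64)
    s = study.data[..., v].astype(np.float64)
    valid = (s > 0) & (s0 > 0)
    adc = np.full(s.shape, np.nan)
    adc[valid] = -np.log(s[valid] / s0[valid]) / b
    return adc


def adc_psnr_by_direction(reference: DWIStudy, test: DWIStudy, mask,
                          adc_range: float = 3.0e-3) -> list[float]:
    """PSNR of the ADC map per gradient direction, within the mask."""
    m = _as_bool_mask(mask)
    out = []
    for d in range(reference.gradients.weighted_indices.size):
        ar = adc_map(reference, d)
        at = adc_map(test, d)
        valid = m & np.isfinite(ar) & np.isfinite(at)
        if not valid.any():
            out.append(np.nan)
            continue
        mse = float(np.mean((ar[valid] - at[valid]) ** 2))
        out.append(float("inf") if mse == 0
                   else float(10.0 * np.log10(adc_range ** 2 / mse)))
    return out


def direction_bias_test(per_direction_values) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and p-value across direction groups.

    Groups whose pooled observations are all identical are the degenerate
    no-variance case and return ``(0.0, 1.0)``.
    """
    groups = [np.asarray(g, dtype=float) for g in per_direction_values]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Study-level reports
# ---------------------------------------------------------------------------

def evaluate_imputation(reference: DWIStudy, test: DWIStudy, fov: FOVMask,
                        brain: BrainMask, data_range: float = 1.0,
                        window: int = 7) -> dict:
    """Imputed-region MSE/PSNR/SSIM per shell group for one study.

    Both studies are normalized with the reference study's shared
    parameters before comparison; the evaluation region is
    brain ∩ missing.
    """
    params = compute_normalization(reference)
    region = _as_bool_mask(brain) & ~_as_bool_mask(fov)
    if not region.any():
        raise ValueError("empty evaluation region (brain ∩ missing)")
    out = {}
    for group in ("b0", "bweighted"):
        idx = reference.gradients.group_indices(group)
        if idx.size == 0:
            continue
        mses, ssims = [], []
        for v in idx:
            ref_v = apply_normalization(reference.data[..., v], params)
            test_v = apply_normalization(test.data[..., v], params)
            mses.append(masked_mse(ref_v, test_v, region))
            ssims.append(ssim_3d(ref_v, test_v, region, window, data_range))
        mse = float(np.mean(mses))
        out[group] = {
            "mse": mse,
            "psnr": float("inf") if mse == 0
            else float(10.0 * np.log10(data_range ** 2 / mse)),
            "ssim": float(np.mean(ssims)),
        }
    return out


def compare_methods(reference_studies: dict, method_outputs: dict,
                    fovs: dict, brains: dict, data_range: float = 1.0) -> pd.DataFrame:
    """Aggregate imputed-region metrics per method and shell group.

    ``reference_studies`` maps study key → ground-truth study;
    ``method_outputs`` maps method name → {study key → imputed study}.
    Rows report mean ± sd across studies (the per-study metric is computed
    first, then aggregated).
    """
    keys = sorted(reference_studies)
    rows = []
    for method, outputs in method_outputs.items():
        if sorted(outputs) != keys:
            raise ValueError(f"method {method!r} study keys do not match "
                             "the reference set")
        per_group: dict[str, dict[str, list]] = {}
        for k in keys:
            res = evaluate_imputation(reference_studies[k], outputs[k],
                                      fovs[k], brains[k], data_range)
            for group, metrics in res.items():
                slot = per_group.setdefault(group,
                                            {"mse": [], "psnr": [], "ssim": []})
                for name, value in metrics.items():
                    slot[name].append(value)
        for group, slot in sorted(per_group.items()):
            row = {"method": method, "shell_group": group,
                   "n_studies": len(keys)}
            for name, values in slot.items():
                arr = np.asarray(values, dtype=float)
                row[f"{name}_mean"] = float(arr.mean())
                row[f"{name}_sd"] = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, csv_path=None, json_path=None):
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if json_path is not None:
        df.to_json(json_path, orient="records", indent=2)
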