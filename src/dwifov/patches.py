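"""2.5D patch construction for sagittal/coronal slice imputation.

A training or inference unit pairs a stack of ``2n+1`` neighboring DWI
slices with the ``2n+1`` structural slices at the same indices, giving a
``2·(2n+1)``-channel input whose target is the single central DWI slice.
Only the sagittal and coronal views are valid: axial slices lie entirely
inside the missing region when the FOV is truncated and carry no signal
to learn from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .core_io import DWIStudy
from .normalization import BrainMask, FOVMask

log = logging.getLogger(__name__)

VIEW_AXES = {"sagittal": 0, "coronal": 1}


def view_axis(view: str) -> int:
    if view == "axial":
        raise ValueError("the axial view is not a supported prediction view")
    try:
        return VIEW_AXES[view]
    except KeyError:
        raise ValueError(f"unknown view {view!r}; choose sagittal or coronal")


def take_slice(volume: np.ndarray, view: str, index: int) -> np.ndarray:
    """The 2-D slice of a 3-D volume at ``index`` along the view axis."""
    return np.take(volume, index, axis=view_axis(view))


@dataclass
class PatchSample:
    """One 2.5D sample: ``(2·(2n+1), H, W)`` input stack + (1, H, W) target."""

    input_stack: np.ndarray
    target_slice: np.ndarray
    view: str
    slice_index: int
    shell_group: str | None = None
    volume_index: int | None = None

    @property
    def n(self) -> int:
        return (self.input_stack.shape[0] // 2 - 1) // 2


def extract_patch(dwi_volume: np.ndarray, structural: np.ndarray, view: str,
                  slice_index: int, n: int,
                  target_volume: np.ndarray | None = None) -> PatchSample:
    """Build the slice-stack sample centered at ``slice_index``.

    The first ``2n+1`` channels are DWI slices ``i−n .. i+n`` in the chosen
    view, the next ``2n+1`` the structural slices at identical indices;
    out-of-range neighbors are zero-filled.  The target is the slice at
    ``slice_index`` of ``target_volume`` (defaults to ``dwi_volume``), i.e.
    pass the truncated volume as input and the ground truth as target when
    building training pairs.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    dwi_volume = np.asarray(dwi_volume)
    structural = np.asarray(structural)
    if dwi_volume.shape != structural.shape:
        raise ValueError("DWI volume and structural image must share a shape")
    axis = view_axis(view)
    extent = dwi_volume.shape[axis]
    if not 0 <= slice_index < extent:
        raise ValueError(f"slice index {slice_index} out of range [0, {extent})")

    def stack(vol):
        planes = []
        zero = None
        for j in range(slice_index - n, slice_index + n + 1):
            if 0 <= j < extent:
                planes.append(np.take(vol, j, axis=axis))
            else:
                if zero is None:
                    zero = np.zeros_like(np.take(vol, slice_index, axis=axis))
                planes.append(zero)
        return np.stack(planes, axis=0)

    target_src = dwi_volume if target_volume is None else np.asarray(target_volume)
    target = np.take(target_src, slice_index, axis=axis)[None]
    return PatchSample(
        input_stack=np.concatenate([stack(dwi_volume), stack(structural)], axis=0),
        target_slice=target, view=view, slice_index=slice_index)


def brain_slice_range(brain: BrainMask | None, view: str, extent: int,
                      margin: int = 0) -> tuple[int, int]:
    """Inclusive index range of brain-intersecting slices along a view axis."""
    if brain is None:
        return 0, extent - 1
    axis = view_axis(view)
    other = tuple(a for a in range(3) if a != axis)
    hits = np.flatnonzero(brain.mask.any(axis=other))
    if hits.size == 0:
        return 0, -1
    lo = max(0, int(hits[0]) - margin)
    hi = min(extent - 1, int(hits[-1]) + margin)
    return lo, hi


def enumerate_training_samples(study: DWIStudy, structural: np.ndarray,
                               fov: FOVMask, view: str, shell_group: str,
                               n: int, brain: BrainMask | None = None,
                               margin: int = 0) -> Iterator[PatchSample]:
    """All training samples for one study, view and shell group.

    Inputs are extracted from the cutoff data (the study masked by ``fov``)
    while targets come from the untruncated ground truth, for every slice
    index intersecting the brain's bounding box along the view axis — the
    model learns to reproduce both missing and acquired regions.
    """
    axis = view_axis(view)
    extent = study.shape[axis]
    lo, hi = brain_slice_range(brain, view, extent, margin)
    if hi < lo:
        log.warning("empty brain bounding box: no training samples")
        return
    structural = np.asarray(structural)
    truncated = study.data * fov.mask[..., None]
    for v in study.gradients.group_indices(shell_group):
        truth_vol = study.data[..., v]
        input_vol = truncated[..., v]
        for i in range(lo, hi + 1):
            sample = extract_patch(input_vol, structural, view, i, n,
                                   target_volume=truth_vol)
            sample.shell_group = shell_group
            sample.volume_index = int(v)
            yield sample
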