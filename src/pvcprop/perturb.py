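"""Deliberate error injection into PVC inputs.

Three error sources are modelled, mirroring what goes wrong in clinical
processing pipelines:

* **FWHM mismatch** — the correction assumes a PSF width different from the
  true one (a parameter pass-through: the perturbation carries the wrong
  FWHM to the correction algorithms);
* **misregistration** — a rigid translation between the PET image and the
  anatomical parcellation. The anatomical side is translated (nearest-
  neighbour for labels) while the PET volume stays fixed, so labels are
  resampled exactly once and PET intensities are never interpolated;
* **mis-segmentation** — regional label volumes rescaled by a factor via
  deterministic morphological growth/shrinkage against neighbouring labels.

All perturbations are deterministic: identical inputs give identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import GridSpec
from .phantom import Parcellation

__all__ = [
    "PerturbationSpec",
    "translate_volume",
    "translate_parcellation",
    "rescale_region_volume",
    "FWHM_MISMATCH_GRID_MM",
    "X_TRANSLATION_GRID_MM",
    "Z_TRANSLATION_GRID_MM",
    "HIPPOCAMPUS_FACTOR_GRID",
    "CORTEX_FACTOR_GRID",
]

# canonical error magnitudes of the study design (all overridable)
FWHM_MISMATCH_GRID_MM = (-2.0, -1.0, 1.0, 2.0)  # relative to the true FWHM
X_TRANSLATION_GRID_MM = (-5.4, -2.7, 2.7, 5.4)  # two / one voxel pitches
Z_TRANSLATION_GRID_MM = (-4.9, -2.4, 2.4, 4.9)
HIPPOCAMPUS_FACTOR_GRID = (0.5, 0.7, 1.4, 1.6)
CORTEX_FACTOR_GRID = (0.6, 0.8, 1.3, 1.5)


@dataclass(frozen=True)
class PerturbationSpec:
    """One injected error: kind plus the field(s) that kind requires."""

    kind: str  # none | fwhm_mismatch | translation | volume_scale
    fwhm_used_mm: float | None = None
    offset_mm: tuple | None = None
    target_regions: tuple = ()  # base names, e.g. ("hippocampus",)
    factor: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "fwhm_mismatch", "translation", "volume_scale"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "fwhm_mismatch" and (self.fwhm_used_mm is None or self.fwhm_used_mm <= 0):
            raise ValueError("fwhm_mismatch requires a positive fwhm_used_mm")
        if self.kind == "translation" and (self.offset_mm is None or len(self.offset_mm) != 3):
            raise ValueError("translation requires a 3-vector offset_mm")
        if self.kind == "volume_scale" and (
            not self.target_regions or self.factor is None or self.factor <= 0
        ):
            raise ValueError("volume_scale requires target_regions and a positive factor")

    @property
    def magnitude(self) -> float:
        """Scalar summary of the error size (0 for the ideal case)."""
        if self.kind == "fwhm_mismatch":
            return float(self.fwhm_used_mm)
        if self.kind == "translation":
            return float(self.offset_mm[0] or self.offset_mm[1] or self.offset_mm[2])
        if self.kind == "volume_scale":
            return float(self.factor)
        return 0.0

    def label(self) -> str:
        if self.kind == "none":
            return "ideal"
        if self.kind == "fwhm_mismatch":
            return f"fwhm_{self.fwhm_used_mm:g}mm"
        if self.kind == "translation":
            ax = "xyz"[int(np.argmax(np.abs(self.offset_mm)))]
            return f"shift_{ax}_{self.magnitude:+g}mm"
        return f"scale_{'+'.join(self.target_regions)}_{self.factor:g}"


def translate_volume(
    volume: np.ndarray, offset_mm, grid: GridSpec, mode: str = "linear"
) -> np.ndarray:
    """Rigid translation by a world-mm offset, resampled onto the same grid.

    ``mode="nearest"`` (mandatory for label volumes) uses nearest-neighbour
    resampling; ``mode="linear"`` trilinear. Voxels shifted in from outside
    the field of view are filled with 0 (the background label).
    """
    volume = np.asarray(volume)
    if mode == "linear":
        if np.issubdtype(volume.dtype, np.integer):
            raise ValueError("linear interpolation is invalid for integer label volumes")
        order = 1
    elif mode == "nearest":
        order = 0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    shift_vox = [o / v for o, v in zip(offset_mm, grid.voxel_size_mm)]
    if all(s == 0 for s in shift_vox):
        return volume.copy()
    return ndimage.shift(
        volume.astype(float) if order else volume,
        shift=shift_vox,
        order=order,
        mode="constant",
        cval=0,
        prefilter=False,
    )


def translate_parcellation(parc: Parcellation, offset_mm) -> Parcellation:
    """Misregistered parcellation: labels rigidly shifted by ``offset_mm``."""
    labels = translate_volume(parc.labels, offset_mm, parc.grid, mode="nearest")
    return Parcellation(parc.grid, labels.astype(parc.labels.dtype), list(parc.regions))


def _grow_once(parc_labels, region_mask, centroid, spacing, n_add, protected_counts):
    """Add up to n_add shell voxels to the region, nearest-to-centroid first."""
    struct = ndimage.generate_binary_structure(3, 1)
    shell = ndimage.binary_dilation(region_mask, structure=struct) & ~region_mask
    shell &= parc_labels > 0  # only take from labelled tissue
    idx = np.argwhere(shell)
    if idx.size == 0:
        return 0
    d = np.linalg.norm((idx - centroid) * spacing, axis=1)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d))
    added = 0
    for k in order:
        if added >= n_add:
            break
        i, j, l = idx[k]
        src = parc_labels[i, j, l]
        if protected_counts[src] <= 1:
            continue  # never erase another region's last voxel
        protected_counts[src] -= 1
        region_mask[i, j, l] = True
        added += 1
    return added


def _shrink_once(region_mask, centroid, spacing, n_remove, min_keep=1):
    """Remove up to n_remove boundary voxels, farthest-from-centroid first."""
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(region_mask, structure=struct)
    boundary = region_mask & ~interior
    idx = np.argwhere(boundary)
    if idx.size == 0:
        return 0
    d = np.linalg.norm((idx - centroid) * spacing, axis=1)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -d))
    current = int(region_mask.sum())
    removed = 0
    for k in order:
        if removed >= n_remove or current - removed <= min_keep:
            break
        i, j, l = idx[k]
        region_mask[i, j, l] = False
        removed += 1
    return removed


def rescale_region_volume(
    parc: Parcellation,
    region_ids,
    factor: float,
    tolerance: float = 0.05,
) -> Parcellation:
    """Shrink or dilate regions to ``factor`` times their voxel count.

    Growth proceeds one 6-connected shell at a time with deterministic
    partial-shell selection (distance from the region centroid, ties broken
    by voxel index); grown voxels are taken from adjacent labels, and voxels
    removed by shrinking are reassigned to the nearest surviving label. The
    brain-mask voxel count is conserved and no other region is ever reduced
    below one voxel.

    Raises if the target count cannot be reached within ``tolerance``
    (relative to the factor), reporting the achieved ratio.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if np.isscalar(region_ids):
        region_ids = [region_ids]
    region_ids = [int(r) for r in region_ids]
    out = parc.labels.copy()
    spacing = np.asarray(parc.grid.voxel_size_mm)
    counts = np.bincount(out.ravel(), minlength=int(out.max()) + 2)

    for rid in region_ids:
        mask = out == rid
        n0 = int(mask.sum())
        if n0 == 0:
            raise ValueError(f"region id {rid} is empty; cannot rescale")
        target = max(1, int(round(factor * n0)))
        centroid = np.argwhere(mask).mean(axis=0)

        if target > n0:
            while mask.sum() < target:
                need = target - int(mask.sum())
                added = _grow_once(out, mask, centroid, spacing, need, counts)
                if added == 0:
                    break
                out[mask & (out != rid)] = rid
        elif target < n0:
            removed_total = np.zeros_like(mask)
            while mask.sum() > target:
                need = int(mask.sum()) - target
                before = mask.copy()
                removed = _shrink_once(mask, centroid, spacing, need)
                if removed == 0:
                    break
                removed_total |= before & ~mask
            if removed_total.any():
                # hand removed voxels to the nearest surviving label
                other = (out > 0) & ~removed_total & ~(mask)
                _, (ix, iy, iz) = ndimage.distance_transform_edt(
                    ~other, sampling=spacing, return_indices=True
                )
                out[removed_total] = out[ix[removed_total], iy[removed_total], iz[removed_total]]
                out[mask] = rid
        counts = np.bincount(out.ravel(), minlength=int(out.max()) + 2)

        achieved = int((out == rid).sum()) / n0
        if abs(achieved - factor) > tolerance * factor:
            raise RuntimeError(
                f"region id {rid}: achieved volume ratio {achieved:.3f} outside "
                f"tolerance of target {factor:.3f} (region too constrained to rescale)"
            )
    return Parcellation(parc.grid, out, list(parc.regions))
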