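"""Region spread functions — the shared substrate of every PVC algorithm.

The RSF of region *j* is the PSF-blurred indicator of its voxel set: the
fraction of region *j*'s signal that the scanner deposits at each voxel.
Where the regions (including background) partition the field of view the
RSFs form a partition of unity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..grids import GridSpec
from ..phantom import Parcellation
from ..simulate import PSFModel, gaussian_blur

__all__ = ["RSFStack", "region_spread_functions", "region_means"]

BACKGROUND_ID = 0


@dataclass
class RSFStack:
    """Stack of region spread functions, one volume per region.

    ``region_ids`` orders the stack; id 0 denotes the background region when
    present. Values lie in [0, 1] voxelwise up to floating-point round-off.
    """

    region_ids: list[int]
    data: np.ndarray  # (n_regions, nx, ny, nz)
    psf: PSFModel
    grid: GridSpec

    def __getitem__(self, region_id: int) -> np.ndarray:
        return self.data[self.region_ids.index(region_id)]

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def sum_map(self) -> np.ndarray:
        return self.data.sum(axis=0)


def region_spread_functions(
    parc: Parcellation,
    psf: PSFModel,
    include_background: bool = False,
    region_ids=None,
) -> RSFStack:
    """Blur each region indicator with the PSF.

    A zero-FWHM PSF returns the indicators themselves. Raises if any listed
    region is empty (its spread function would be identically zero).
    """
    if region_ids is None:
        region_ids = list(parc.region_ids)
        if include_background:
            region_ids = [BACKGROUND_ID] + region_ids
    data = np.empty((len(region_ids),) + parc.grid.shape, dtype=np.float64)
    for k, rid in enumerate(region_ids):
        ind = (parc.labels == rid).astype(np.float64)
        if not ind.any():
            name = "background" if rid == BACKGROUND_ID else parc.region(rid).name
            raise ValueError(f"region {name!r} (id {rid}) is empty; cannot build its RSF")
        data[k] = gaussian_blur(ind, psf.fwhm_mm, parc.grid) if psf.fwhm_mm > 0 else ind
    return RSFStack(region_ids=list(region_ids), data=data, psf=psf, grid=parc.grid)


def region_means(image: np.ndarray, parc: Parcellation, region_ids=None) -> pd.Series:
    """NaN-aware mean of ``image`` over each region's voxels.

    Returns a Series indexed by region id (SUVR units for SUVR inputs).
    """
    if region_ids is None:
        region_ids = parc.region_ids
    vals = {}
    for rid in region_ids:
        v = image[parc.labels == rid]
        with np.errstate(invalid="ignore"):
            vals[rid] = float(np.nanmean(v)) if v.size else np.nan
    s = pd.Series(vals)
    s.index.name = "region_id"
    return s
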