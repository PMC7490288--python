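"""NIfTI and CSV persistence for phantoms, images and result tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import GridSpec
from .phantom import AttenuationMap, Parcellation, RegionSpec, TruthImage

__all__ = [
    "save_volume",
    "load_volume",
    "save_parcellation",
    "load_parcellation",
    "save_truth",
    "save_attenuation",
]


def save_volume(values: np.ndarray, grid: GridSpec, path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(values).astype(dtype), affine=grid.affine())
    img.header.set_zooms(grid.voxel_size_mm)
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, GridSpec(shape=data.shape, voxel_size_mm=zooms)


def save_parcellation(parc: Parcellation, out_dir) -> None:
    """Write the label map (int16 NIfTI) and the region table (CSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_volume(parc.labels, parc.grid, out_dir / "parcellation.nii.gz", dtype=np.int16)
    parc.region_table().to_csv(out_dir / "regions.csv", index=False)


def load_parcellation(label_path, region_csv_path) -> Parcellation:
    labels, grid = load_volume(label_path)
    table = pd.read_csv(region_csv_path)
    regions = []
    for _, row in table.iterrows():
        truth = {
            col.removeprefix("suvr_"): float(row[col])
            for col in table.columns
            if col.startswith("suvr_") and np.isfinite(row[col])
        }
        regions.append(
            RegionSpec(
                int(row["region_id"]), str(row["name"]), str(row["tissue_class"]),
                str(row["laterality"]), truth,
            )
        )
    return Parcellation(grid, labels.astype(np.int16), regions)


def save_truth(truth: TruthImage, path) -> None:
    save_volume(truth.values, truth.grid, path)


def save_attenuation(mu: AttenuationMap, path) -> None:
    save_volume(mu.mu, mu.grid, path)
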