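"""Voxel grid geometry shared by every volume in the pipeline.

All volumes live on a regular axis-aligned grid. Voxel indices are 0-based;
world coordinates are measured in mm from the volume corner, so the centre of
voxel ``(i, j, k)`` sits at ``((i + 0.5) * dx, (j + 0.5) * dy, (k + 0.5) * dz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "DEFAULT_GRID"]


@dataclass(frozen=True)
class GridSpec:
    """Shape and voxel size of a 3-D volume.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z). Each dimension must be >= 8.
    voxel_size_mm : tuple of float
        Voxel pitch in mm along (x, y, z). Strictly positive.
    """

    shape: tuple[int, int, int] = (128, 128, 63)
    voxel_size_mm: tuple[float, float, float] = (2.682, 2.682, 2.425)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.voxel_size_mm) != 3:
            raise ValueError("GridSpec is three-dimensional")
        if any(int(n) < 8 for n in self.shape):
            raise ValueError(f"all grid dimensions must be >= 8, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        """Physical extent of the volume along each axis in mm."""
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size_mm))

    @property
    def center_mm(self) -> tuple[float, float, float]:
        return tuple(f / 2.0 for f in self.fov_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable arrays of voxel-centre world coordinates (mm)."""
        ax = [
            (np.arange(n, dtype=float) + 0.5) * v
            for n, v in zip(self.shape, self.voxel_size_mm)
        ]
        return (
            ax[0][:, None, None],
            ax[1][None, :, None],
            ax[2][None, None, :],
        )

    def mm_to_voxel(self, point_mm) -> tuple[float, float, float]:
        """World mm -> fractional voxel index (centre-of-voxel convention)."""
        return tuple(
            p / v - 0.5 for p, v in zip(point_mm, self.voxel_size_mm)
        )

    def contains_mm(self, point_mm) -> bool:
        return all(0.0 <= p <= f for p, f in zip(point_mm, self.fov_mm))

    def affine(self) -> np.ndarray:
        """NIfTI affine mapping voxel indices to world mm (corner origin)."""
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        aff[:3, 3] = [v / 2.0 for v in self.voxel_size_mm]
        return aff


DEFAULT_GRID = GridSpec()
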