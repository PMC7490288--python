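"""Synthetic parcellated brain phantom with known ground-truth uptake.

The phantom is a geometric surrogate for an MRI-derived parcellation: nested
ellipsoids provide the spill-over topology that drives the partial volume
effect in brain PET — a thin cortical grey-matter ribbon sandwiched between
white matter and CSF, small subcortical grey structures (hippocampus,
parahippocampal gyrus, fusiform) embedded in white matter, and a separate
cerebellar compartment whose grey matter serves as the SUVR reference region.

Two presets emulate the study conditions:

* ``HC`` — healthy-control anatomy and tracer uptake;
* ``AD`` — Alzheimer-like: thinner cortical ribbon, smaller hippocampus,
  higher uptake in temporal/hippocampal target regions and elevated
  white-matter non-specific binding (tau tracers such as THK-5351 bind
  non-specifically in white matter).

True-uptake images are exactly piecewise constant over the parcellation and
are never filtered; they are the ground truth all corrections are scored
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GridSpec, DEFAULT_GRID

__all__ = [
    "RegionSpec",
    "Parcellation",
    "TruthImage",
    "AttenuationMap",
    "PhantomGeometry",
    "PhantomBuildError",
    "ANALYSIS_ROIS",
    "DEFAULT_TRUTH_TABLE",
    "MU_SOFT_TISSUE",
    "MU_BONE",
    "build_phantom",
    "assign_truth",
    "build_attenuation",
    "make_point_source",
]

#: the six analysis ROIs, present bilaterally
ANALYSIS_ROIS = (
    "mid_inf_temporal",
    "parietal",
    "occipital",
    "parahippocampal",
    "hippocampus",
    "fusiform",
)

#: regions every brain phantom must contain (base names; bilateral ROIs are
#: required on both sides)
MANDATORY_REGIONS = ANALYSIS_ROIS + (
    "cerebral_wm",
    "csf",
    "cerebellar_gm",
    "cerebellar_wm",
)

MU_SOFT_TISSUE = 0.096  # cm^-1 at 511 keV
MU_BONE = 0.144  # cm^-1 at 511 keV


class PhantomBuildError(RuntimeError):
    """Raised when the requested grid cannot realize every mandatory region."""


@dataclass(frozen=True)
class RegionSpec:
    """One parcellation region: label id, tissue class and true uptake.

    ``truth_suvr`` maps condition name ("HC"/"AD") to the region's true SUVR.
    """

    region_id: int
    name: str
    tissue_class: str  # GM | WM | CSF | background
    laterality: str  # left | right | midline
    truth_suvr: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.region_id < 0:
            raise ValueError("region_id must be nonnegative")
        if self.tissue_class not in ("GM", "WM", "CSF", "background"):
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")
        if self.laterality not in ("left", "right", "midline"):
            raise ValueError(f"unknown laterality {self.laterality!r}")
        for v in self.truth_suvr.values():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"truth SUVR for {self.name} must be finite and >= 0")


@dataclass
class Parcellation:
    """Integer label volume plus the table of regions it contains."""

    grid: GridSpec
    labels: np.ndarray
    regions: list[RegionSpec]

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("label volume does not match grid shape")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer volume")
        known = {r.region_id for r in self.regions}
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - known
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from region table")

    # -- lookups ------------------------------------------------------------
    @property
    def region_ids(self) -> list[int]:
        return [r.region_id for r in self.regions]

    def region(self, region_id: int) -> RegionSpec:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(f"no region with id {region_id}")

    def ids_for(self, base_name: str) -> list[int]:
        """All region ids whose name equals ``base_name`` (both sides)."""
        ids = [r.region_id for r in self.regions if r.name == base_name]
        if not ids:
            raise KeyError(f"no region named {base_name!r}")
        return ids

    def mask(self, region_ids) -> np.ndarray:
        if np.isscalar(region_ids):
            region_ids = [region_ids]
        return np.isin(self.labels, list(region_ids))

    def tissue_mask(self, tissue_class: str) -> np.ndarray:
        ids = [r.region_id for r in self.regions if r.tissue_class == tissue_class]
        return self.mask(ids)

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def voxel_count(self, region_ids) -> int:
        return int(self.mask(region_ids).sum())

    def region_table(self) -> pd.DataFrame:
        rows = []
        for r in self.regions:
            row = {
                "region_id": r.region_id,
                "name": r.name,
                "tissue_class": r.tissue_class,
                "laterality": r.laterality,
                "n_voxels": self.voxel_count(r.region_id),
            }
            for cond, v in sorted(r.truth_suvr.items()):
                row[f"suvr_{cond}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def validate(self, require_standard_rois: bool = True) -> None:
        """Check structural invariants; raise naming the first violation."""
        for r in self.regions:
            if self.voxel_count(r.region_id) == 0:
                raise PhantomBuildError(f"region {r.name!r} (id {r.region_id}) is empty")
        if require_standard_rois:
            names = {(r.name, r.laterality) for r in self.regions}
            for roi in ANALYSIS_ROIS:
                for side in ("left", "right"):
                    if (roi, side) not in names:
                        raise PhantomBuildError(f"missing mandatory region {roi} ({side})")
            base = {r.name for r in self.regions}
            for name in ("cerebral_wm", "csf", "cerebellar_gm", "cerebellar_wm"):
                if name not in base:
                    raise PhantomBuildError(f"missing mandatory region {name!r}")

    def copy(self) -> "Parcellation":
        return Parcellation(self.grid, self.labels.copy(), list(self.regions))


@dataclass(frozen=True)
class TruthImage:
    """Piecewise-constant true SUVR volume for one condition."""

    grid: GridSpec
    values: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("truth volume does not match grid shape")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("truth values must be finite and nonnegative")


@dataclass(frozen=True)
class AttenuationMap:
    """511 keV linear attenuation coefficients (cm^-1) on the phantom grid."""

    grid: GridSpec
    mu: np.ndarray

    def __post_init__(self) -> None:
        if self.mu.shape != self.grid.shape:
            raise ValueError("mu volume does not match grid shape")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomGeometry:
    """Ellipsoid geometry of the phantom, in mm.

    Centres are offsets from the grid centre; blob offsets are from the
    cerebrum centre, specified for the right hemisphere and mirrored about the
    mid-sagittal (x) plane for the left. Defaults are sized for the default
    343 x 343 x 153 mm field of view.
    """

    cerebrum_offset_mm: tuple = (0.0, 12.0, 12.0)
    cerebrum_axes_mm: tuple = (68.0, 82.0, 58.0)
    csf_thickness_mm: float = 3.0
    cortex_thickness_mm: float = 6.0  # preset-dependent; AD thinner
    ventricle_offset_mm: tuple = (0.0, 8.0, 0.0)
    ventricle_axes_mm: tuple = (12.0, 28.0, 10.0)
    cerebellum_offset_mm: tuple = (0.0, -95.0, -52.0)
    cerebellum_axes_mm: tuple = (40.0, 32.0, 20.0)
    cerebellum_cortex_mm: float = 7.0
    hippocampus_offset_mm: tuple = (26.0, -12.0, -30.0)
    hippocampus_axes_mm: tuple = (9.0, 19.0, 8.0)
    parahippocampal_offset_mm: tuple = (38.0, -12.0, -34.0)
    parahippocampal_axes_mm: tuple = (8.0, 18.0, 7.0)
    fusiform_offset_mm: tuple = (46.0, -16.0, -24.0)
    fusiform_axes_mm: tuple = (8.0, 20.0, 7.0)
    blob_jitter_mm: float = 1.0  # seeded, mirror-symmetric placement jitter
    # lobe partition angles (degrees) on the cortical ribbon
    parietal_elevation_deg: float = 42.0
    anterior_half_width_deg: float = 40.0


#: true SUVR per region base name and condition; invented defaults with the
#: tau-tracer signature (high WM non-specific binding, AD-elevated temporal
#: and hippocampal uptake). Override via ``build_phantom(truth_table=...)``.
DEFAULT_TRUTH_TABLE: dict[str, dict[str, float]] = {
    "csf": {"HC": 0.05, "AD": 0.05},
    "cerebral_wm": {"HC": 1.8, "AD": 2.0},
    "frontal": {"HC": 1.0, "AD": 1.1},
    "parietal": {"HC": 1.05, "AD": 1.4},
    "occipital": {"HC": 1.1, "AD": 1.2},
    "mid_inf_temporal": {"HC": 1.15, "AD": 2.0},
    "parahippocampal": {"HC": 1.2, "AD": 2.4},
    "hippocampus": {"HC": 1.1, "AD": 1.8},
    "fusiform": {"HC": 1.15, "AD": 2.0},
    "cerebellar_gm": {"HC": 1.0, "AD": 1.0},
    "cerebellar_wm": {"HC": 1.6, "AD": 1.7},
}

# fixed label numbering: (base name, tissue class, bilateral?)
_REGION_LAYOUT = [
    ("csf", "CSF", False),
    ("cerebral_wm", "WM", False),
    ("frontal", "GM", True),
    ("parietal", "GM", True),
    ("occipital", "GM", True),
    ("mid_inf_temporal", "GM", True),
    ("parahippocampal", "GM", True),
    ("hippocampus", "GM", True),
    ("fusiform", "GM", True),
    ("cerebellar_gm", "GM", False),
    ("cerebellar_wm", "WM", False),
]


def _ellipsoid_r2(X, Y, Z, center, axes):
    """Squared normalized ellipsoid radius (<= 1 inside)."""
    return (
        ((X - center[0]) / axes[0]) ** 2
        + ((Y - center[1]) / axes[1]) ** 2
        + ((Z - center[2]) / axes[2]) ** 2
    )


def _shrunk(axes, t):
    out = tuple(max(a - t, 1e-3) for a in axes)
    return out


def build_phantom(
    preset: str,
    grid: GridSpec = DEFAULT_GRID,
    seed: int = 0,
    geometry: PhantomGeometry | None = None,
    truth_table: dict | None = None,
    ad_cortex_thickness_mm: float = 4.2,
    ad_hippocampus_scale: float = 0.75,
) -> Parcellation:
    """Build the parcellated phantom for one preset.

    Parameters
    ----------
    preset : {"HC", "AD"}
        HC uses the nominal geometry; AD thins the cortical ribbon to
        ``ad_cortex_thickness_mm`` and shrinks the hippocampus axes by
        ``ad_hippocampus_scale`` (cortical atrophy and hippocampal volume
        loss typical of Alzheimer anatomy).
    seed : int
        Drives a small (<= ``blob_jitter_mm``) mirror-symmetric jitter of the
        subcortical blob centres. The build is bit-reproducible for a fixed
        (preset, grid, seed).

    Raises
    ------
    PhantomBuildError
        If the grid is too small to realize every mandatory region; the
        message names the first unrealizable region.
    """
    preset = preset.upper()
    if preset not in ("HC", "AD"):
        raise ValueError(f"preset must be 'HC' or 'AD', got {preset!r}")
    geo = geometry or PhantomGeometry()
    if preset == "AD":
        geo = replace(
            geo,
            cortex_thickness_mm=ad_cortex_thickness_mm,
            hippocampus_axes_mm=tuple(a * ad_hippocampus_scale for a in geo.hippocampus_axes_mm),
        )
    table = truth_table or DEFAULT_TRUTH_TABLE

    X, Y, Z = grid.voxel_centers_mm()
    gc = grid.center_mm
    cer_c = tuple(c + o for c, o in zip(gc, geo.cerebrum_offset_mm))

    labels = np.zeros(grid.shape, dtype=np.int16)

    # region table with fixed ids
    regions: list[RegionSpec] = []
    name_to_ids: dict[str, dict[str, int]] = {}
    next_id = 1
    for name, tissue, bilateral in _REGION_LAYOUT:
        truth = dict(table.get(name, {"HC": 0.0, "AD": 0.0}))
        sides = ("left", "right") if bilateral else ("midline",)
        name_to_ids[name] = {}
        for side in sides:
            regions.append(RegionSpec(next_id, name, tissue, side, truth))
            name_to_ids[name][side] = next_id
            next_id += 1

    # -- cerebrum shells ----------------------------------------------------
    outer = _ellipsoid_r2(X, Y, Z, cer_c, geo.cerebrum_axes_mm) <= 1.0
    gm_axes = _shrunk(geo.cerebrum_axes_mm, geo.csf_thickness_mm)
    gm_outer = _ellipsoid_r2(X, Y, Z, cer_c, gm_axes) <= 1.0
    wm_axes = _shrunk(gm_axes, geo.cortex_thickness_mm)
    wm_core = _ellipsoid_r2(X, Y, Z, cer_c, wm_axes) <= 1.0

    csf_id = name_to_ids["csf"]["midline"]
    wm_id = name_to_ids["cerebral_wm"]["midline"]
    labels[outer & ~gm_outer] = csf_id
    labels[wm_core] = wm_id

    # ventricles (CSF inside white matter)
    vent_c = tuple(c + o for c, o in zip(cer_c, geo.ventricle_offset_mm))
    vent = _ellipsoid_r2(X, Y, Z, vent_c, geo.ventricle_axes_mm) <= 1.0
    labels[vent & wm_core] = csf_id

    # -- cortical ribbon, partitioned into lobes by angle --------------------
    ribbon = gm_outer & ~wm_core
    dx = X - cer_c[0]
    dy = Y - cer_c[1]
    dz = Z - cer_c[2]
    u = np.sqrt(
        (dx / gm_axes[0]) ** 2 + (dy / gm_axes[1]) ** 2
    )
    elev = np.degrees(np.arctan2(dz / gm_axes[2], u))
    azim = np.degrees(np.arctan2(dy, dx))  # 90 = anterior, -90 = posterior

    superior = elev > geo.parietal_elevation_deg
    anterior_band = np.abs(azim - 90.0) < geo.anterior_half_width_deg
    posterior_band = np.abs(azim + 90.0) < geo.anterior_half_width_deg

    lobe_masks = {
        "frontal": ribbon & (superior & (dy / gm_axes[1] > 0.25) | ~superior & anterior_band),
        "parietal": ribbon & superior & (dy / gm_axes[1] <= 0.25),
        "occipital": ribbon & ~superior & posterior_band,
        "mid_inf_temporal": ribbon & ~superior & ~anterior_band & ~posterior_band,
    }
    for name, m in lobe_masks.items():
        labels[m & (dx < 0)] = name_to_ids[name]["left"]
        labels[m & (dx >= 0)] = name_to_ids[name]["right"]

    # -- subcortical blobs (carved out of WM, mirror-symmetric jitter) -------
    rng = np.random.default_rng(seed)
    blob_defs = [
        ("hippocampus", geo.hippocampus_offset_mm, geo.hippocampus_axes_mm),
        ("parahippocampal", geo.parahippocampal_offset_mm, geo.parahippocampal_axes_mm),
        ("fusiform", geo.fusiform_offset_mm, geo.fusiform_axes_mm),
    ]
    for name, off, axes in blob_defs:
        jit = rng.uniform(-geo.blob_jitter_mm, geo.blob_jitter_mm, size=3)
        for side, sign in (("right", 1.0), ("left", -1.0)):
            c = (
                cer_c[0] + sign * (off[0] + jit[0]),
                cer_c[1] + off[1] + jit[1],
                cer_c[2] + off[2] + jit[2],
            )
            blob = _ellipsoid_r2(X, Y, Z, c, axes) <= 1.0
            labels[blob & (labels == wm_id)] = name_to_ids[name][side]

    # -- cerebellum ----------------------------------------------------------
    cb_c = tuple(c + o for c, o in zip(gc, geo.cerebellum_offset_mm))
    cb_outer = _ellipsoid_r2(X, Y, Z, cb_c, geo.cerebellum_axes_mm) <= 1.0
    cb_core = (
        _ellipsoid_r2(X, Y, Z, cb_c, _shrunk(geo.cerebellum_axes_mm, geo.cerebellum_cortex_mm))
        <= 1.0
    )
    free = labels == 0
    labels[cb_outer & ~cb_core & free] = name_to_ids["cerebellar_gm"]["midline"]
    labels[cb_core & free] = name_to_ids["cerebellar_wm"]["midline"]

    parc = Parcellation(grid=grid, labels=labels, regions=regions)
    parc.validate(require_standard_rois=True)
    return parc


def assign_truth(parcellation: Parcellation, condition: str) -> TruthImage:
    """Paint the true SUVR volume for one condition.

    The result is exactly piecewise constant over the parcellation and is
    normalized so the cerebellar grey matter — the SUVR reference region —
    has value exactly 1.0.
    """
    condition = condition.upper()
    values = np.zeros(parcellation.grid.shape, dtype=np.float64)
    lut_size = max(parcellation.region_ids) + 1
    lut = np.zeros(lut_size, dtype=np.float64)
    for r in parcellation.regions:
        if condition not in r.truth_suvr:
            raise KeyError(f"region {r.name!r} has no truth SUVR for condition {condition!r}")
        lut[r.region_id] = r.truth_suvr[condition]
    values = lut[parcellation.labels]

    ref_ids = parcellation.ids_for("cerebellar_gm")
    ref_val = lut[ref_ids[0]]
    if ref_val <= 0:
        raise ValueError("cerebellar grey matter truth value must be positive")
    values = values / ref_val
    return TruthImage(grid=parcellation.grid, values=values, condition=condition)


def build_attenuation(parcellation: Parcellation) -> AttenuationMap:
    """Two-tissue 511 keV attenuation map: soft tissue plus a skull shell.

    Brain voxels get mu = 0.096 cm^-1; a bone shell grown morphologically
    around the brain gets 0.144 cm^-1; everything else is 0.
    """
    brain = parcellation.brain_mask()
    struct = ndimage.generate_binary_structure(3, 1)
    skull = ndimage.binary_dilation(brain, structure=struct, iterations=2) & ~brain
    mu = np.zeros(parcellation.grid.shape, dtype=np.float64)
    mu[brain] = MU_SOFT_TISSUE
    mu[skull] = MU_BONE
    return AttenuationMap(grid=parcellation.grid, mu=mu)


def make_point_source(
    grid: GridSpec, center_mm, amplitude: float = 1.0
) -> TruthImage:
    """Single-voxel impulse for point-spread / FWHM measurements.

    The impulse is placed in the voxel nearest ``center_mm``; the volume sums
    to ``amplitude`` exactly.
    """
    if not grid.contains_mm(center_mm):
        raise ValueError(f"point source centre {center_mm} outside grid FOV {grid.fov_mm}")
    idx = tuple(
        int(np.clip(round(i), 0, n - 1))
        for i, n in zip(grid.mm_to_voxel(center_mm), grid.shape)
    )
    values = np.zeros(grid.shape, dtype=np.float64)
    values[idx] = amplitude
    return TruthImage(grid=grid, values=values, condition="POINT")
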