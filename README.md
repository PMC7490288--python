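# pvcprop

Error-propagation analysis of partial-volume correction (PVC) for brain PET,
on a fully synthetic digital phantom.

PET images are blurred by the scanner's finite resolution (the partial
volume effect, PVE): signal spills between neighbouring structures, biasing
regional quantification — severely so for thin cortex and small structures
like the hippocampus, and for tau tracers whose strong non-specific
white-matter binding spills into grey matter. Post-reconstruction PVC
algorithms undo this using an anatomical parcellation and a point-spread
model, but in practice their inputs carry errors: the assumed PSF width is
wrong, the anatomical image is misregistered to the PET, or regions are
mis-segmented. This package quantifies how such input errors propagate into
the corrected regional values, for seven algorithms:

* **MG** — Müller-Gärtner voxel-wise grey-matter correction,
* **GTM** — geometric transfer matrix (region-to-region spill-over inverse),
* **LABBE** — Labbé voxel-to-region spill-over least squares,
* **RBV** — region-based voxel-wise (GTM means + Yang voxel correction),
* **IY** — iterative Yang (ten iterations),
* **SFS-RR** — structural-functional synergy resolution recovery
  (wavelet-domain blending with a synthetic structural image), and
* **mod SFS-RR** — SFS-RR with GTM-corrected means in the structural image.

## The model

A parcellated ellipsoidal head phantom (cortical grey-matter ribbon between
white matter and CSF, subcortical grey blobs, cerebellum) carries a
piecewise-constant true SUVR image per condition ("HC" healthy,
"AD" Alzheimer-like: thinner cortex, smaller hippocampus, hotter target
regions). A pseudo-observed image is simulated analytically: slice-wise
parallel-beam projection with Beer-Lambert attenuation, scatter/randoms
surrogates added, scaled Poisson noise, precorrection, ramp-filter FBP and a
6 mm Gaussian post-filter. With the PSF modelled as an isotropic Gaussian of
FWHM *f* (sigma = f / (2 sqrt(2 ln 2))), each region's spread function is
RSF_j = PSF ⊗ 1_j and the GTM system is

    omega_ij = mean_{v in region i} RSF_j(v),      omega t = b,

with b the observed regional means and t the recovered true means. Error
propagation is scored per analysis ROI (middle+inferior temporal, parietal,
occipital, parahippocampal gyrus, hippocampus, fusiform; SUVR normalized to
cerebellar grey matter) as

    %difference = 100 (ROI_PVC − ROI_true) / ROI_true.

Injected errors follow the canonical grids: assumed FWHM off by ±1/±2 mm,
X translations ±2.7/±5.4 mm and Z translations ±2.4/±4.9 mm (one and two
voxel pitches), hippocampus volume × {0.5, 0.7, 1.4, 1.6} and global cortex
× {0.6, 0.8, 1.3, 1.5}, each evaluated with ROI templates drawn on the true
and on the erroneous anatomy.

## Worked example

```python
from pvcprop import (build_phantom, assign_truth, build_attenuation,
                     simulate_observed, measure_chain_fwhm)
from pvcprop.pvc import GTM, region_means

parc = build_phantom("HC", seed=1)
truth = assign_truth(parc, "HC")
mu = build_attenuation(parc)
observed = simulate_observed(truth, mu, seed=1)

fwhm = round(measure_chain_fwhm(parc.grid), 2)
print(f"effective resolution of the chain: {fwhm} mm FWHM")

gtm = GTM(fwhm_mm=fwhm).fit(parc)
corrected = gtm.transform(observed)
obs_means = region_means(observed, parc)
tv = region_means(truth.values, parc)
for name in ("hippocampus", "mid_inf_temporal", "cerebral_wm"):
    rid = parc.ids_for(name)[0]
    print(f"{name:18s} true {tv[rid]:.2f}  observed {obs_means[rid]:.2f}"
          f"  GTM {corrected[rid]:.2f}")
```

prints

```
effective resolution of the chain: 6.63 mm FWHM
hippocampus        true 1.10  observed 1.33  GTM 1.14
mid_inf_temporal   true 1.15  observed 1.02  GTM 1.14
cerebral_wm        true 1.80  observed 1.75  GTM 1.80
```

The observed hippocampus is inflated by spill-in from the hot white matter
(1.33 vs a true 1.10) while the thin temporal ribbon is underestimated
(1.02 vs 1.15); the GTM solve recovers both to within a few percent of
truth on this noisy realization. The correctors follow scikit-learn
conventions — `fit` on a parcellation, `transform` an observed volume,
`get_params`/`set_params`/`clone` — so they compose with sklearn tooling;
one-shot wrappers (`pvcprop.pvc.gtm_solve`, `rbv_correct`, ...) cover
script use.

The full factorial study is one call (or `pvcprop experiment` from a
shell):

```python
from pvcprop import ExperimentGrid, run_experiment_grid
table = run_experiment_grid(ExperimentGrid(seed=1), out_dir="results")
```

producing a tidy CSV with one row per (condition, algorithm, error source,
error magnitude, ROI, template variant) holding the corrected and true ROI
SUVRs and their %difference. A `click` CLI (`pvcprop phantom / simulate /
pvc / perturb / experiment`) exposes each stage on NIfTI volumes and CSV
region tables.

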