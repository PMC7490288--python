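"""Correction algorithms: exactness, oracle equivalence, algebraic identities."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from pvcprop.grids import GridSpec
from pvcprop.phantom import Parcellation, RegionSpec
from pvcprop.pvc import (
    GTM,
    SFSRR,
    RBV,
    IterativeYang,
    Labbe,
    MullerGartner,
    gtm_solve,
    iy_correct,
    labbe_solve,
    paint_regions,
    region_means,
    region_spread_functions,
    sfsrr_correct,
    synthetic_image,
    yang_ratio,
)
from pvcprop.simulate import PSFModel, gaussian_blur

from ._oracles import brute_blur, brute_gtm, brute_labbe
from .conftest import make_toy_parcellation

ANALYSIS = ("mid_inf_temporal", "parietal", "occipital", "parahippocampal",
            "hippocampus", "fusiform")


def analysis_ids(parc):
    ids = []
    for base in ANALYSIS + ("cerebellar_gm", "cerebral_wm"):
        ids.extend(parc.ids_for(base))
    return ids


# ---------------------------------------------------------------------------
# region spread functions
# ---------------------------------------------------------------------------


class TestRSF:
    def test_zero_fwhm_gives_indicators(self, hc_parc):
        stack = region_spread_functions(hc_parc, PSFModel(0.0))
        rid = hc_parc.ids_for("cerebral_wm")[0]
        assert np.array_equal(stack[rid], (hc_parc.labels == rid).astype(float))

    def test_interior_saturation(self, hc_parc):
        stack = region_spread_functions(hc_parc, PSFModel(6.0))
        wm = hc_parc.ids_for("cerebral_wm")[0]
        # a voxel deep inside white matter sees RSF ~ 1
        from scipy.ndimage import binary_erosion

        deep = binary_erosion(hc_parc.labels == wm, iterations=4)
        assert deep.any()
        assert stack[wm][deep].min() > 1 - 1e-3

    def test_partition_of_unity(self):
        parc, _ = make_toy_parcellation()
        stack = region_spread_functions(parc, PSFModel(5.0), include_background=True)
        total = stack.sum_map()
        inner = (slice(4, -4),) * 3
        assert np.allclose(total[inner], 1.0, atol=1e-6)
        assert stack.data.min() > -1e-6 and stack.data.max() < 1 + 1e-6

    def test_empty_region_raises(self, small_grid):
        labels = np.zeros(small_grid.shape, dtype=np.int16)
        labels[4:8, 4:8, 4:8] = 1
        parc = Parcellation(
            small_grid, labels,
            [RegionSpec(1, "blob", "GM", "midline"), RegionSpec(2, "ghost", "GM", "midline")],
        )
        with pytest.raises(ValueError, match="ghost"):
            region_spread_functions(parc, PSFModel(5.0))


# ---------------------------------------------------------------------------
# ROI-based solvers
# ---------------------------------------------------------------------------


class TestGTM:
    def test_exact_on_matched_blur(self, hc_parc, hc_truth, hc_blurred):
        t = GTM(7.0).fit(hc_parc).transform(hc_blurred)
        tv = region_means(hc_truth.values, hc_parc)
        assert np.abs((t - tv) / tv).max() < 1e-6

    def test_small_fwhm_returns_observed_means(self, hc_parc, hc_blurred):
        t = GTM(1e-6).fit(hc_parc).transform(hc_blurred)
        obs = region_means(hc_blurred, hc_parc)
        assert np.allclose(t, obs, rtol=1e-9)

    def test_matches_brute_force_oracle(self):
        parc, truth = make_toy_parcellation(values=(2.0, 1.0, 0.5))
        img = gaussian_blur(truth, 6.0, parc.grid)
        mine = GTM(6.0, include_background=False).fit(parc).transform(img)
        oracle = brute_gtm(img, parc.labels, parc.region_ids, 6.0, parc.grid.voxel_size_mm)
        assert np.allclose(mine.to_numpy(), oracle, atol=1e-8)

    def test_condition_number_guard(self, hc_parc):
        with pytest.raises(RuntimeError, match="condition number"):
            GTM(7.0, cond_threshold=1.0).fit(hc_parc)


class TestLabbe:
    def test_exact_on_matched_blur(self, hc_parc, hc_truth, hc_blurred):
        t = Labbe(7.0).fit(hc_parc).transform(hc_blurred)
        tv = region_means(hc_truth.values, hc_parc)
        assert np.abs((t - tv) / tv).max() < 1e-6

    def test_small_fwhm_returns_region_means(self, hc_parc, hc_blurred):
        t = Labbe(1e-6).fit(hc_parc).transform(hc_blurred)
        obs = region_means(hc_blurred, hc_parc)
        assert np.allclose(t, obs, rtol=1e-6, atol=1e-9)

    def test_matches_brute_force_oracle(self):
        parc, truth = make_toy_parcellation(values=(2.0, 1.0, 0.5))
        img = gaussian_blur(truth, 6.0, parc.grid)
        mine = Labbe(6.0, include_background=False).fit(parc).transform(img)
        oracle = brute_labbe(
            img, parc.labels, parc.region_ids, 6.0, parc.grid.voxel_size_mm,
            parc.brain_mask(),
        )
        assert np.allclose(mine.to_numpy(), oracle, atol=1e-8)


# ---------------------------------------------------------------------------
# Muller-Gartner
# ---------------------------------------------------------------------------


def three_compartment_phantom(g=1.5, w=0.8):
    """Thick GM shell around a WM core in CSF bath: the classical MG setup."""
    grid = GridSpec((48, 48, 32), (3.0, 3.0, 3.0))
    X, Y, Z = grid.voxel_centers_mm()
    c = grid.center_mm
    r2 = ((X - c[0]) / 55) ** 2 + ((Y - c[1]) / 55) ** 2 + ((Z - c[2]) / 40) ** 2
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[r2 <= 1.0] = 3  # CSF
    labels[r2 <= 0.8] = 1  # GM shell
    labels[r2 <= 0.45] = 2  # WM core
    regions = [
        RegionSpec(1, "gm", "GM", "midline", {"HC": g}),
        RegionSpec(2, "wm", "WM", "midline", {"HC": w}),
        RegionSpec(3, "csf", "CSF", "midline", {"HC": 0.0}),
    ]
    parc = Parcellation(grid, labels, regions)
    truth = np.select([labels == 1, labels == 2], [g, w], 0.0)
    return parc, truth


class TestMullerGartner:
    def test_uniform_brain_consistency(self, hc_parc):
        """GM, WM and CSF all at the same value: MG must return that value."""
        img = gaussian_blur(2.0 * hc_parc.brain_mask().astype(float), 7.0, hc_parc.grid)
        out = MullerGartner(7.0).fit(hc_parc).transform(img)
        gm = hc_parc.tissue_mask("GM")
        vals = out[gm]
        assert np.allclose(vals[np.isfinite(vals)], 2.0, atol=1e-6)

    def test_three_compartment_recovery(self):
        parc, truth = three_compartment_phantom()
        img = gaussian_blur(truth, 7.0, parc.grid)
        mg = MullerGartner(7.0).fit(parc)
        out = mg.transform(img)
        interior = mg.class_rsf_["GM"] >= 0.9
        assert interior.any()
        assert np.allclose(out[interior], 1.5, rtol=0.02)

    def test_full_threshold_flags_everything(self, hc_parc, hc_blurred):
        mg = MullerGartner(7.0, gm_threshold=1.0).fit(hc_parc)
        out = mg.transform(hc_blurred)
        assert np.isnan(out).all()
        assert mg.n_flagged_ == out.size


# ---------------------------------------------------------------------------
# synthetic image + Yang family
# ---------------------------------------------------------------------------


class TestSyntheticImage:
    def test_truth_round_trip(self, hc_parc, hc_truth):
        tv = region_means(hc_truth.values, hc_parc)
        assert np.allclose(synthetic_image(hc_parc, tv), hc_truth.values, atol=1e-12)

    def test_unit_means(self, hc_parc):
        s = synthetic_image(hc_parc, {r: 1.0 for r in hc_parc.region_ids})
        assert np.array_equal(s > 0, hc_parc.brain_mask())

    def test_means_round_trip(self, hc_parc):
        m = pd.Series({r: float(r) for r in hc_parc.region_ids})
        assert region_means(synthetic_image(hc_parc, m), hc_parc).equals(m)

    def test_missing_region_raises(self, hc_parc):
        with pytest.raises(KeyError):
            synthetic_image(hc_parc, {hc_parc.region_ids[0]: 1.0})


class TestYang:
    def test_uniform_synthetic_is_identity_interior(self, hc_parc, hc_blurred):
        s = np.ones(hc_parc.grid.shape)
        out = yang_ratio(hc_blurred, s, PSFModel(7.0), hc_parc.grid)
        inner = (slice(8, -8),) * 2 + (slice(6, -6),)
        assert np.allclose(out[inner], hc_blurred[inner], atol=1e-6)

    def test_exact_inversion_identity(self, hc_parc, hc_truth):
        s = hc_truth.values
        img = gaussian_blur(s, 7.0, hc_parc.grid)
        out = yang_ratio(img, s, PSFModel(7.0), hc_parc.grid)
        brain = hc_parc.brain_mask()
        assert np.allclose(out[brain], s[brain], atol=1e-6)

    def test_scale_invariance(self, hc_parc, hc_truth, hc_blurred):
        a = yang_ratio(hc_blurred, hc_truth.values, PSFModel(7.0), hc_parc.grid)
        b = yang_ratio(hc_blurred, 5.0 * hc_truth.values, PSFModel(7.0), hc_parc.grid)
        brain = hc_parc.brain_mask()
        assert np.allclose(a[brain], b[brain], rtol=1e-9)


class TestRBV:
    def test_roi_recovery_matches_gtm(self, hc_parc, hc_blurred):
        rbv = RBV(7.0).fit(hc_parc)
        out = rbv.transform(hc_blurred)
        roi = region_means(out, hc_parc)[analysis_ids(hc_parc)]
        gtm = rbv.gtm_.transform(hc_blurred)[analysis_ids(hc_parc)]
        assert np.abs((roi - gtm) / gtm).max() < 0.01

    def test_voxel_recovery_interior(self, hc_parc, hc_truth, hc_blurred):
        out = RBV(7.0).fit(hc_parc).transform(hc_blurred)
        wm = hc_parc.mask(hc_parc.ids_for("cerebral_wm"))
        from scipy.ndimage import binary_erosion

        deep = binary_erosion(wm, iterations=3)
        assert np.allclose(out[deep], hc_truth.values[deep], rtol=0.01)

    def test_tiny_fwhm_is_identity(self, hc_parc, hc_blurred):
        out = RBV(1e-6).fit(hc_parc).transform(hc_blurred)
        brain = hc_parc.brain_mask()
        assert np.allclose(out[brain], hc_blurred[brain], rtol=1e-6)


class TestIterativeYang:
    def test_one_iteration_is_yang_with_observed_means(self, hc_parc, hc_blurred):
        one = IterativeYang(7.0, n_iter=1).fit(hc_parc).transform(hc_blurred)
        s = synthetic_image(hc_parc, region_means(hc_blurred, hc_parc))
        ref = yang_ratio(hc_blurred, s, PSFModel(7.0), hc_parc.grid)
        assert np.allclose(one, ref, equal_nan=True)

    def test_default_ten_iterations(self):
        assert IterativeYang().n_iter == 10

    def test_convergence_within_two_percent(self, hc_parc, hc_truth, hc_blurred):
        """Analysis-ROI means converge to truth; error non-increasing after iter 2."""
        ids = analysis_ids(hc_parc)
        tv = region_means(hc_truth.values, hc_parc)[ids]
        errors = []
        for n in (2, 4, 6, 10):
            out = iy_correct(hc_blurred, hc_parc, PSFModel(7.0), n_iter=n)
            m = region_means(out, hc_parc)[ids]
            errors.append(np.abs((m - tv) / tv).max())
        assert errors[-1] < 0.02
        assert all(b <= a + 1e-6 for a, b in zip(errors, errors[1:]))


# ---------------------------------------------------------------------------
# SFS-RR
# ---------------------------------------------------------------------------


class TestSFSRR:
    def test_zero_fraction_is_identity(self, hc_parc, hc_blurred):
        out = SFSRR(7.0, n_levels=3, structural_fraction=0.0).fit(hc_parc).transform(hc_blurred)
        assert np.abs(out - hc_blurred).max() < 1e-6

    def test_full_fraction_self_structural_is_identity(self, hc_parc, hc_blurred):
        est = SFSRR(7.0, n_levels=3, structural_fraction=1.0).fit(hc_parc)
        out = est.transform(hc_blurred, structural=hc_blurred)
        assert np.abs(out - hc_blurred).max() < 1e-6

    def test_incompatible_levels_rejected(self, hc_parc):
        with pytest.raises(ValueError, match="n_levels"):
            SFSRR(7.0, n_levels=7).fit(hc_parc)

    def test_mod_variant_improves_on_base(self, hc_parc, hc_truth, hc_blurred):
        """GTM-seeded structural image beats observed-mean structural image."""
        psf = PSFModel(7.0)
        base = sfsrr_correct(hc_blurred, hc_parc, psf, n_levels=3)
        mod = sfsrr_correct(hc_blurred, hc_parc, psf, structural_source="gtm_means", n_levels=3)
        tv = region_means(hc_truth.values, hc_parc)
        ids = [hc_parc.ids_for(n)[0] for n in ("hippocampus", "parahippocampal", "fusiform")]
        err_base = np.abs((region_means(base, hc_parc)[ids] - tv[ids]) / tv[ids])
        err_mod = np.abs((region_means(mod, hc_parc)[ids] - tv[ids]) / tv[ids])
        assert (err_mod <= err_base + 1e-9).all()

    def test_per_subband_rule_runs(self, hc_parc, hc_blurred):
        out = SFSRR(7.0, n_levels=3, weighting_rule="per_subband_fit").fit(hc_parc).transform(
            hc_blurred
        )
        assert np.isfinite(out).all()


# ---------------------------------------------------------------------------
# estimator API conventions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "est",
    [
        GTM(6.5),
        Labbe(6.5),
        MullerGartner(6.5, gm_threshold=0.4),
        RBV(6.5),
        IterativeYang(6.5, n_iter=4),
        SFSRR(6.5, n_levels=2),
    ],
    ids=lambda e: type(e).__name__,
)
def test_sklearn_param_conventions(est):
    params = est.get_params()
    assert params["fwhm_mm"] == 6.5
    cl = clone(est)
    assert cl.get_params() == params
    cl.set_params(fwhm_mm=8.0)
    assert cl.get_params()["fwhm_mm"] == 8.0
    assert est.get_params()["fwhm_mm"] == 6.5


def test_wrapper_functions_match_estimators(hc_parc, hc_blurred):
    psf = PSFModel(7.0)
    assert gtm_solve(hc_blurred, hc_parc, psf).equals(
        GTM(7.0).fit(hc_parc).transform(hc_blurred)
    )
    assert labbe_solve(hc_blurred, hc_parc, psf).equals(
        Labbe(7.0).fit(hc_parc).transform(hc_blurred)
    )
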