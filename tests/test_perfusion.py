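"""Contrast enhancement, AIF extraction, and bSVD perfusion quantification."""

import numpy as np
import pytest

from perfct.perfusion import (
    AifCurve,
    PerfusionConstants,
    bsvd_deconvolve,
    compute_cbv,
    compute_maps,
    contrast_enhancement,
    extract_aif,
)
from perfct.phantom import (
    GM, WM,
    DynamicSeries,
    GammaVariateAif,
    ground_truth_maps,
    tissue_ce_curve,
)


@pytest.fixture(scope="module")
def aif_50():
    t = np.arange(50.0)
    return AifCurve(values=GammaVariateAif()(t), dt=1.0)


class TestContrastEnhancement:
    def test_constant_pixel_gives_zero_ce(self):
        series = DynamicSeries(data=np.full((4, 4, 20), 35.0), dt=1.0)
        ce = contrast_enhancement(series)
        np.testing.assert_array_equal(ce.data, 0.0)

    def test_baseline_window_mean_is_zero(self, desk_phantom):
        _, _, series = desk_phantom
        ce = contrast_enhancement(series, (0, 8))
        np.testing.assert_allclose(
            ce.data[:, :, 0:8].mean(axis=2), 0.0, atol=1e-12
        )

    def test_definition(self):
        data = np.zeros((1, 1, 10))
        data[0, 0] = [2, 4, 3, 3, 5, 6, 7, 8, 9, 10]
        ce = contrast_enhancement(DynamicSeries(data=data, dt=1.0), (0, 4))
        assert ce.data[0, 0, 4] == pytest.approx(5 - 3.0)

    def test_empty_baseline_rejected(self):
        series = DynamicSeries(data=np.zeros((2, 2, 5)), dt=1.0)
        with pytest.raises(ValueError):
            contrast_enhancement(series, (3, 3))


class TestExtractAif:
    def test_two_population_separation(self):
        """A few arterial pixels among flat tissue: the AIF is the tall curve."""
        t = np.arange(40.0)
        tall = GammaVariateAif(amplitude=200.0)(t)
        data = np.zeros((10, 10, 40))
        data += 5.0 * np.sin(t / 9.0)  # weak common drift
        data[4:6, 4:6, :] += tall
        roi = np.zeros((10, 10), dtype=bool)
        roi[2:8, 2:8] = True
        aif = extract_aif(DynamicSeries(data=data, dt=1.0), roi, seed=0)
        np.testing.assert_allclose(aif.values, tall + 5.0 * np.sin(t / 9.0), atol=12.0)
        assert aif.values.max() == pytest.approx(tall.max(), rel=0.1)

    def test_identical_curves_returned_verbatim(self):
        t = np.arange(30.0)
        curve = GammaVariateAif()(t)
        data = np.broadcast_to(curve, (8, 8, 30)).copy()
        roi = np.ones((8, 8), dtype=bool)
        aif = extract_aif(DynamicSeries(data=data, dt=1.0), roi, seed=0)
        np.testing.assert_allclose(aif.values, curve, atol=1e-8)

    def test_deterministic_for_fixed_seed(self, desk_phantom):
        _, labels, series = desk_phantom
        ce = contrast_enhancement(series)
        a = extract_aif(ce, labels.rois["ica"], seed=3)
        b = extract_aif(ce, labels.rois["ica"], seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_roi_smaller_than_clusters_rejected(self):
        series = DynamicSeries(data=np.zeros((4, 4, 10)), dt=1.0)
        roi = np.zeros((4, 4), dtype=bool)
        roi[0, 0:3] = True
        with pytest.raises(ValueError):
            extract_aif(series, roi, n_clusters=5)


class TestBsvdDeconvolve:
    def test_zero_curve_gives_zero_flow(self, aif_50):
        est = bsvd_deconvolve(np.zeros(50), aif_50)
        np.testing.assert_array_equal(est.k_curve, 0.0)
        assert est.cbf == 0.0

    def test_recovers_cbf_from_forward_convolution(self, aif_50):
        """Round trip through the indicator-dilution forward model."""
        for cbf, cbv in [(60.0, 4.0), (25.0, 2.0)]:
            ce = tissue_ce_curve(cbf, cbv, aif_50.values, 1.0)
            est = bsvd_deconvolve(ce, aif_50, threshold_frac=1e-10)
            assert est.cbf == pytest.approx(cbf, rel=1e-6)

    def test_linearity_in_ce(self, aif_50):
        ce = tissue_ce_curve(60.0, 4.0, aif_50.values, 1.0)
        e1 = bsvd_deconvolve(ce, aif_50, threshold_frac=1e-10)
        e2 = bsvd_deconvolve(2.0 * ce, aif_50, threshold_frac=1e-10)
        assert e2.cbf == pytest.approx(2.0 * e1.cbf, rel=1e-9)

    def test_delay_insensitivity(self, aif_50):
        """Block-circulant embedding: a 2-frame delay barely changes CBF."""
        ce = tissue_ce_curve(60.0, 4.0, aif_50.values, 1.0)
        shifted = np.roll(ce, 2)
        shifted[:2] = 0.0
        e0 = bsvd_deconvolve(ce, aif_50)
        e2 = bsvd_deconvolve(shifted, aif_50)
        assert abs(e2.cbf - e0.cbf) < 0.10 * e0.cbf

    def test_flat_aif_rejected(self):
        flat = AifCurve(values=np.zeros(20), dt=1.0)
        with pytest.raises(ValueError):
            bsvd_deconvolve(np.ones(20), flat)


class TestComputeCbv:
    def test_blood_pixel_limit(self, aif_50):
        """CE identical to the AIF: CBV = 100 k_H / rho ~ 70.2 mL/100 g."""
        cbv = compute_cbv(aif_50.values.copy(), aif_50)
        assert cbv == pytest.approx(100 * 0.73 / 1.04, rel=1e-12)

    def test_linear_in_ce(self, aif_50):
        ce = tissue_ce_curve(60.0, 4.0, aif_50.values, 1.0)
        assert compute_cbv(2 * ce, aif_50) == pytest.approx(
            2 * compute_cbv(ce, aif_50), rel=1e-12
        )

    def test_zero_aif_area_rejected(self):
        with pytest.raises(ValueError):
            compute_cbv(np.ones(10), AifCurve(values=np.zeros(10), dt=1.0))


class TestComputeMaps:
    def test_parameter_recovery_on_noise_free_phantom(self, desk_phantom):
        """End-to-end: rendered series back to the tissue-table CBF/CBV."""
        spec, labels, series = desk_phantom
        ce = contrast_enhancement(series)
        aif = extract_aif(ce, labels.rois["ica"], seed=0)
        maps = compute_maps(ce, aif, labels.brain_mask, threshold_frac=1e-10)
        for label in (GM, WM):
            tissue = spec.tissue_table[label]
            sel = labels.labels == label
            assert maps.cbf[sel].mean() == pytest.approx(tissue.cbf, rel=0.05)
            assert maps.cbv[sel].mean() == pytest.approx(tissue.cbv, rel=0.02)

    def test_recovery_robust_to_sampling_rate(self):
        """Recovery at dt=0.5 s and 1 s is equally accurate.

        The discrete-exponential residue makes the convolution/deconvolution
        pair exactly consistent at any frame spacing, so the only residual
        error is the (equal-horizon) truncation tail; both rates must sit
        far inside the CBV recovery bound.
        """
        from perfct.phantom import PhantomSpec, build_phantom, render_dynamic_hu

        errs = {}
        for dt, n_frames in ((1.0, 50), (0.5, 100)):
            spec = PhantomSpec(grid_size=64, n_frames=n_frames, dt=dt)
            labels = build_phantom(spec)
            series = render_dynamic_hu(labels, spec)
            ce = contrast_enhancement(series, (0, int(8 / dt)))
            aif = AifCurve(values=spec.aif_params(spec.frame_times), dt=dt)
            maps = compute_maps(ce, aif, labels.brain_mask, threshold_frac=1e-10)
            sel = labels.labels == GM
            errs[dt] = abs(maps.cbv[sel].mean() - 4.0) / 4.0
        assert errs[0.5] < 0.002 and errs[1.0] < 0.002

    def test_mtt_central_volume_identity(self, desk_phantom):
        _, labels, series = desk_phantom
        ce = contrast_enhancement(series)
        aif = extract_aif(ce, labels.rois["ica"], seed=0)
        maps = compute_maps(ce, aif, labels.brain_mask)
        sel = maps.perfused
        np.testing.assert_array_equal(
            maps.mtt[sel], 60.0 * maps.cbv[sel] / maps.cbf[sel]
        )

    def test_masked_out_pixels_are_zero(self, desk_phantom):
        _, labels, series = desk_phantom
        ce = contrast_enhancement(series)
        aif = extract_aif(ce, labels.rois["ica"], seed=0)
        maps = compute_maps(ce, aif, labels.brain_mask)
        outside = ~labels.brain_mask
        assert maps.cbf[outside].max() == 0.0
        assert maps.cbv[outside].max() == 0.0
        assert maps.mtt[outside].max() == 0.0
        assert np.isfinite(maps.mtt).all()

    def test_gm_wm_flow_ratio(self, desk_phantom):
        spec, labels, series = desk_phantom
        ce = contrast_enhancement(series)
        aif = extract_aif(ce, labels.rois["ica"], seed=0)
        maps = compute_maps(ce, aif, labels.brain_mask, threshold_frac=1e-10)
        gt_cbf, _, _ = ground_truth_maps(labels, spec)
        want = gt_cbf[labels.labels == GM].mean() / gt_cbf[labels.labels == WM].mean()
        got = maps.cbf[labels.labels == GM].mean() / maps.cbf[labels.labels == WM].mean()
        assert got == pytest.approx(want, rel=0.10)
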