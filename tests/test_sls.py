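"""Masked intensity statistics, histograms, penetration and resolution."""

from __future__ import annotations

import numpy as np
import pytest

from vesiquant import (
    Mask3D,
    VoxelVolume,
    estimate_lateral_resolution,
    foreground_detect,
    masked_histogram,
    masked_stats,
    penetration_stats,
)
from vesiquant.phantom import REGION_LABELS


class TestMaskedStats:
    def test_uniform_intensity_worked_example(self):
        # 1000 voxels of intensity 100 at (2.5,1,1) µm: integrated 1e5,
        # volume 2500 µm³, normalized 40 a.u. µm⁻³
        data = np.zeros((10, 10, 10))
        mask = np.zeros((10, 10, 10), bool)
        mask.ravel()[:1000] = True
        data[mask] = 100.0
        st = masked_stats(VoxelVolume(data, (2.5, 1, 1)), Mask3D(mask, (2.5, 1, 1)))
        assert st.integrated_intensity == pytest.approx(1.0e5)
        assert st.physical_volume_um3 == pytest.approx(2500.0)
        assert st.normalized_intensity == pytest.approx(40.0)

    def test_zero_volume_zero_normalized(self):
        vol = VoxelVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        mask = Mask3D(np.ones((4, 4, 4), bool), (1, 1, 1))
        assert masked_stats(vol, mask).normalized_intensity == 0.0

    def test_empty_mask_rejected(self):
        vol = VoxelVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError):
            masked_stats(vol, Mask3D(np.zeros((4, 4, 4), bool), (1, 1, 1)))

    def test_additive_over_disjoint_masks(self, rng):
        vol = VoxelVolume(rng.random((6, 8, 8)) * 100, (2.5, 1, 1))
        a = np.zeros((6, 8, 8), bool)
        b = np.zeros((6, 8, 8), bool)
        a[:3], b[3:] = True, True
        sp = (2.5, 1, 1)
        st_a = masked_stats(vol, Mask3D(a, sp))
        st_b = masked_stats(vol, Mask3D(b, sp))
        st_ab = masked_stats(vol, Mask3D(a | b, sp))
        assert st_ab.integrated_intensity == pytest.approx(
            st_a.integrated_intensity + st_b.integrated_intensity
        )


class TestMaskedHistogram:
    @pytest.mark.parametrize("scale", ["linear", "log"])
    def test_counts_conserve_mask_size(self, scale, rng):
        vol = VoxelVolume((rng.random((8, 25, 25)) * 60000).astype(np.uint16), (1, 1, 1))
        mask = Mask3D(rng.random((8, 25, 25)) > 0.5, (1, 1, 1))
        h = masked_histogram(vol, mask, n_bins=256, scale=scale)
        assert h.total() == mask.count()
        assert (np.diff(h.bin_edges) > 0).all()

    def test_constant_region_single_bin(self):
        vol = VoxelVolume(np.full((4, 4, 4), 1234, np.uint16), (1, 1, 1))
        mask = Mask3D(np.ones((4, 4, 4), bool), (1, 1, 1))
        h = masked_histogram(vol, mask, n_bins=4096)
        assert (h.counts > 0).sum() == 1
        assert h.total() == 64

    def test_empty_mask_warns_and_returns_empty(self):
        vol = VoxelVolume(np.zeros((3, 3, 3), np.uint16), (1, 1, 1))
        with pytest.warns(UserWarning):
            h = masked_histogram(vol, Mask3D(np.zeros((3, 3, 3), bool), (1, 1, 1)))
        assert h.total() == 0

    def test_no_nanobot_phantom_has_no_high_intensity_tail(self):
        from vesiquant.phantom import PhantomSpec, generate_bladder_phantom

        spec = PhantomSpec(
            seed=2,
            surface_density_tumour=0.0,
            surface_density_healthy=0.0,
            grid_shape=(48, 120, 120),
            lumen_radius_um=35.0,
            urothelium_thickness_um=12.0,
            lamina_thickness_um=6.0,
            detrusor_thickness_um=4.0,
            tumour_basal_radius_um=20.0,
            tumour_protrusion_um=22.0,
        )
        _, scattered, truth = generate_bladder_phantom(spec)
        tissue = Mask3D(
            truth.region_labels.data != REGION_LABELS["exterior"], spec.spacing
        )
        h = masked_histogram(scattered, tissue, n_bins=4096)
        # cutoff from the speckle noise model: the 1 − 1/(100 N) quantile of
        # the multiplicative lognormal on the baseline
        from scipy import stats

        z = stats.norm.isf(1.0 / (100 * tissue.count()))
        cutoff = spec.scattered_baseline * np.exp(spec.speckle_sigma * z)
        high_bins = h.bin_edges[:-1] > cutoff
        assert h.counts[high_bins].sum() == 0


class TestForegroundDetect:
    def test_bimodal_signal_recovered(self, rng):
        data = rng.normal(100, 5, (10, 20, 20))
        spots = rng.random((10, 20, 20)) > 0.99
        data[spots] = 5000.0
        vol = VoxelVolume(data, (1, 1, 1))
        mask = Mask3D(np.ones(data.shape, bool), (1, 1, 1))
        fg, thr = foreground_detect(vol, mask)
        assert thr is not None
        assert (fg.data & spots).sum() / spots.sum() >= 0.99

    def test_constant_intensities_empty_with_warning(self):
        vol = VoxelVolume(np.full((4, 4, 4), 7.0), (1, 1, 1))
        mask = Mask3D(np.ones((4, 4, 4), bool), (1, 1, 1))
        with pytest.warns(UserWarning):
            fg, thr = foreground_detect(vol, mask)
        assert thr is None and fg.count() == 0

    def test_explicit_threshold_is_definitional(self, rng):
        data = rng.random((5, 6, 6)) * 100
        vol = VoxelVolume(data, (1, 1, 1))
        mask = Mask3D(np.ones(data.shape, bool), (1, 1, 1))
        fg, thr = foreground_detect(vol, mask, threshold=40.0)
        assert thr == 40.0
        assert (fg.data == (data > 40.0)).all()


class TestPenetrationStats:
    def test_median_of_known_depths(self):
        sp = (1.0, 1.0, 1.0)
        surface = np.zeros((1, 5, 50), bool)
        surface[0, :, 0] = True
        fg = np.zeros_like(surface)
        fg[0, 2, 10] = fg[0, 2, 20] = fg[0, 2, 30] = True
        region = np.ones_like(surface)
        st = penetration_stats(Mask3D(fg, sp), Mask3D(surface, sp), Mask3D(region, sp))
        assert st.median_depth_um == pytest.approx(20.0)

    def test_occupancy_fraction(self):
        sp = (1.0, 1.0, 1.0)
        region = np.zeros((10, 10, 10), bool)
        region.ravel()[:1000] = True
        fg = np.zeros_like(region)
        fg.ravel()[:50] = True
        surface = np.zeros_like(region)
        surface[0, 0, 0] = True
        st = penetration_stats(Mask3D(fg, sp), Mask3D(surface, sp), Mask3D(region, sp))
        assert st.occupancy == pytest.approx(0.05)

    def test_no_foreground_reports_missing_median(self):
        sp = (1.0, 1.0, 1.0)
        surface = np.zeros((3, 3, 3), bool)
        surface[0, 0, 0] = True
        st = penetration_stats(
            Mask3D(np.zeros((3, 3, 3), bool), sp),
            Mask3D(surface, sp),
            Mask3D(np.ones((3, 3, 3), bool), sp),
        )
        assert st.median_depth_um is None
        assert st.occupancy == 0.0

    def test_phantom_median_depth_tracks_truth_puncta(self, phantom_bundle, layer_bundle):
        spec, _, scattered, truth = phantom_bundle
        masks, _, _ = layer_bundle
        tissue = Mask3D(masks["t1"].data | masks["healthy_wall"].data, spec.spacing)
        fg, _ = foreground_detect(scattered, tissue)
        st = penetration_stats(fg, masks["bc"], masks["t1"])
        truth_median = truth.puncta.query("region == 'tumour'")["depth_um"].median()
        assert st.median_depth_um == pytest.approx(truth_median, rel=0.15)


class TestLayerProfile:
    def test_uniform_intensity_gives_unit_ratios(self):
        from vesiquant import build_layers, layer_profile

        sp = (2.0, 2.0, 2.0)
        zz, yy, xx = np.mgrid[0:60, 0:60, 0:60]
        r = np.sqrt(sum(((a - 29.5) * 2.0) ** 2 for a in (zz, yy, xx)))
        bc = Mask3D(r <= 30, sp)
        empty = Mask3D(np.zeros_like(bc.data), sp)
        ls = build_layers(bc, urothelium=empty, tumour=empty, thickness_um=10)
        vol = VoxelVolume(np.full((60, 60, 60), 500.0), sp)
        res = layer_profile(vol, ls)
        assert res["ratios"]["TL3_over_TL1"] == pytest.approx(1.0)
        assert res["ratios"]["TL1_over_HL"] == pytest.approx(1.0)

    def test_empty_layer_reported_missing(self):
        from vesiquant import LayerSet, layer_profile

        sp = (1.0, 1.0, 1.0)
        full = Mask3D(np.ones((4, 4, 4), bool), sp)
        empty = Mask3D(np.zeros((4, 4, 4), bool), sp)
        ls = LayerSet(
            layers={"TL1": full, "TL2": empty, "TL3": full, "HL": full},
            thickness_um=33.0,
        )
        vol = VoxelVolume(np.full((4, 4, 4), 10.0), sp)
        with pytest.warns(UserWarning, match="TL2"):
            res = layer_profile(vol, ls)
        assert res["stats"]["TL2"] is None
        assert res["ratios"]["TL1_over_HL"] == pytest.approx(1.0)


class TestLateralResolution:
    @pytest.mark.parametrize(
        "sigma_um,expected_fwhm",
        [(1.02, 2.402), (0.6497, 1.530)],
    )
    def test_noiseless_gaussian_fwhm_identity(self, sigma_um, expected_fwhm):
        px = 0.5
        yy, xx = np.mgrid[0:41, 0:41]
        s = sigma_um / px
        img = 50 + 1000 * np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / (2 * s**2))
        assert estimate_lateral_resolution(img, px) == pytest.approx(expected_fwhm, abs=0.01)

    def test_noisy_fit_bias_below_two_percent(self):
        px = 0.5
        yy, xx = np.mgrid[0:41, 0:41]
        s = 1.02 / px
        clean = 50 + 1000 * np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / (2 * s**2))
        rng = np.random.default_rng(0)
        fits = [
            estimate_lateral_resolution(clean + rng.normal(0, 50, clean.shape), px)
            for _ in range(100)
        ]
        assert abs(np.mean(fits) - 2.402) / 2.402 < 0.02

    def test_flat_patch_rejected(self):
        with pytest.raises(RuntimeError):
            estimate_lateral_resolution(np.full((21, 21), 5.0), 0.5)
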