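"""Evaluation metrics: closed forms, invariances, reference cross-checks."""

import numpy as np
import pytest

from octa.core_io import DecorrelationMap, DegenerateInputError, ValidationError
from octa.decorr import make_label
from octa.metrics import (
    MetricsReport,
    SSIMParams,
    SurfaceDetectionError,
    crop_roi,
    detect_surface,
    enface_mip,
    evaluate_methods,
    normalize_to_gray,
    psnr,
    squared_error_map,
    ssim,
)
from octa.phantom import Vessel, generate_phantom
from conftest import small_phantom_spec


def _map(values, y=0):
    return DecorrelationMap(values=np.asarray(values, dtype=float), y_index=y, source="sd", n_used=2)


class TestNormalizeToGray:
    def test_endpoint_mapping(self):
        np.testing.assert_allclose(
            normalize_to_gray(np.array([[0.0, 0.5, 1.0]])), [[0.0, 127.5, 255.0]]
        )

    def test_idempotent_on_full_range(self, rng):
        img = rng.random((8, 8)) * 255
        img[0, 0], img[-1, -1] = 0.0, 255.0
        np.testing.assert_allclose(normalize_to_gray(img), img)

    def test_positive_affine_invariance(self, rng):
        img = rng.random((10, 10))
        np.testing.assert_allclose(
            normalize_to_gray(3.7 * img + 11.0), normalize_to_gray(img), atol=1e-10
        )

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateInputError):
            normalize_to_gray(np.ones((4, 4)))


class TestPSNR:
    def test_affine_related_inputs_give_infinity(self, rng):
        img = rng.random((12, 12))
        assert psnr(_map(img), _map(2.5 * img + 0.3)) == np.inf

    def test_single_max_error_pixel_closed_form(self):
        """One pixel wrong by the full 255 range on an M-pixel image: 10*log10(M)."""
        m = 16 * 16
        label = np.zeros((16, 16))
        label[0, 0] = 1.0  # spans full range after normalization
        pred = label.copy()
        pred[0, 1] = 1.0  # after norm: pred has extra 255 at (0,1)
        # construct directly on the gray scale instead: difference at exactly 1 px
        a = np.zeros((16, 16)); a[0, 0] = 255.0
        b = a.copy(); b[8, 8] = 255.0
        b[0, 0] = 255.0
        # normalized copies of a and b are themselves; MSE = 255^2/M
        val = psnr(_map(a), _map(b))
        assert val == pytest.approx(10 * np.log10(m), rel=1e-12)

    def test_agrees_with_straight_formula_oracle(self, rng):
        """Independent from-the-definition implementation on random images."""
        for _ in range(5):
            a, b = rng.random((9, 13)), rng.random((9, 13))
            na = (a - a.min()) / (a.max() - a.min()) * 255
            nb = (b - b.min()) / (b.max() - b.min()) * 255
            expected = 10 * np.log10(255**2 / np.mean((na - nb) ** 2))
            assert psnr(_map(a), _map(b)) == pytest.approx(expected, abs=1e-9)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            psnr(_map(rng.random((4, 4))), _map(rng.random((4, 5))))


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        x = normalize_to_gray(rng.random((32, 32)))
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_images_closed_form(self):
        a, b = 80.0, 160.0
        p = SSIMParams()
        expected = (2 * a * b + p.c1) / (a**2 + b**2 + p.c1)
        got = ssim(np.full((16, 16), a), np.full((16, 16), b))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_symmetry(self, rng):
        x = normalize_to_gray(rng.random((20, 20)))
        y = normalize_to_gray(rng.random((20, 20)))
        assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)

    def test_bounded_by_one(self, rng):
        for _ in range(5):
            x = normalize_to_gray(rng.random((16, 16)))
            y = normalize_to_gray(rng.random((16, 16)))
            assert ssim(x, y) <= 1.0

    def test_agrees_with_skimage_reference(self, rng):
        """Cross-check against the independent reference implementation."""
        from skimage.metrics import structural_similarity

        x = normalize_to_gray(rng.random((48, 40)))
        y = normalize_to_gray(rng.random((48, 40)))
        ref = structural_similarity(
            x, y, data_range=255, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=0.01, K2=0.03,
        )
        assert ssim(x, y) == pytest.approx(ref, abs=1e-6)


class TestSurfaceAndROI:
    def test_step_edge_detected(self):
        img = np.zeros((100, 30))
        img[40:] = 1.0
        assert detect_surface(img) == pytest.approx(40, abs=2)

    def test_phantom_surface_within_two_pixels(self, small_phantom):
        got = detect_surface(small_phantom.volume.blocks[0].frames[0])
        assert abs(got - small_phantom.spec.surface_z) <= 2

    def test_flat_noise_image_fails(self, rng):
        with pytest.raises(SurfaceDetectionError):
            detect_surface(rng.random((60, 30)) + 10.0)

    def test_crop_rows(self, rng):
        dmap = _map(rng.random((200, 10)))
        out = crop_roi(dmap, surface=30, depth_px=150)
        np.testing.assert_array_equal(out.values, dmap.values[30:180])

    def test_out_of_bounds_clamped_with_warning(self, rng):
        dmap = _map(rng.random((100, 10)))
        with pytest.warns(UserWarning):
            out = crop_roi(dmap, surface=30, depth_px=150)
        assert out.values.shape == (70, 10)

    def test_zero_depth_rejected(self, rng):
        with pytest.raises(ValidationError):
            crop_roi(_map(rng.random((100, 10))), surface=0, depth_px=0)

    def test_metric_locality_under_crop(self, rng):
        """Values outside the ROI cannot influence an ROI-restricted metric."""
        a = rng.random((100, 20))
        b = a.copy()
        b[80:] = 99.0  # corrupt only below the ROI
        ra, rb = crop_roi(_map(a), 10, 60), crop_roi(_map(b), 10, 60)
        assert psnr(ra, rb) == np.inf


class TestMIP:
    def test_single_row_band_is_verbatim(self, rng):
        maps = [_map(rng.random((30, 8)), y) for y in range(4)]
        out = enface_mip(maps, 5, 5, surface=2)
        np.testing.assert_array_equal(out, np.stack([m.values[7] for m in maps]))

    def test_matches_brute_force_loop(self, rng):
        maps = [_map(rng.random((20, 6)), y) for y in range(5)]
        out = enface_mip(maps, 3, 9, surface=2)
        for y in range(5):
            for x in range(6):
                expected = max(maps[y].values[z, x] for z in range(5, 12))
                assert out[y, x] == expected

    def test_nested_band_decomposition(self, rng):
        maps = [_map(rng.random((40, 6)), y) for y in range(3)]
        full = enface_mip(maps, 0, 29, surface=5)
        upper = enface_mip(maps, 0, 14, surface=5)
        lower = enface_mip(maps, 15, 29, surface=5)
        np.testing.assert_array_equal(full, np.maximum(upper, lower))

    def test_vessel_depth_selectivity(self):
        """A vessel 70 px below the surface shows in the 60-90 band, not 120-150."""
        spec = small_phantom_spec(
            height_px=180, width_px=48, surface_z=8, n_y_locations=6,
            vessel_list=(Vessel(center_z=8 + 70, center_x=24, radius_px=5, rho=0.05),),
            attenuation_per_px=0.005, seed=33,
        )
        ph = generate_phantom(spec)
        labels = [make_label(b) for b in ph.volume.blocks]
        shallow = enface_mip(labels, 60, 90, surface=8)
        deep = enface_mip(labels, 120, 150, surface=8)
        vessel_cols = slice(20, 29)
        bg_cols = slice(0, 12)
        contrast_shallow = shallow[:, vessel_cols].mean() / shallow[:, bg_cols].mean()
        contrast_deep = deep[:, vessel_cols].mean() / deep[:, bg_cols].mean()
        assert contrast_shallow > 1.5
        assert contrast_deep < 1.2

    def test_empty_band_rejected(self, rng):
        maps = [_map(rng.random((20, 6)))]
        with pytest.raises(ValidationError):
            enface_mip(maps, 10, 5, surface=0)


class TestSquaredError:
    def test_identical_inputs_zero(self, rng):
        m = rng.random((5, 5))
        se, mean = squared_error_map(m, m)
        assert se.max() == 0.0 and mean == 0.0

    def test_hand_example(self):
        se, mean = squared_error_map(np.array([[0.0, 1.0]]), np.array([[1.0, 0.0]]))
        np.testing.assert_array_equal(se, [[1.0, 1.0]])
        assert mean == 1.0


class TestEvaluateMethods:
    def test_self_comparison_is_perfect(self, small_phantom):
        labels = [make_label(b) for b in small_phantom.volume.blocks]
        report = evaluate_methods(labels, {"sd_10": labels}, surface=4, roi_depth_px=28)
        df = report.to_dataframe()
        assert (df["psnr_db"] == np.inf).all()
        np.testing.assert_allclose(df["ssim"], 1.0, atol=1e-9)

    def test_row_count_bookkeeping(self, small_phantom):
        from octa.decorr import DecorrParams, windowed_decorrelation

        labels = [make_label(b) for b in small_phantom.volume.blocks]
        methods = {
            f"sd_{n}": [
                windowed_decorrelation(b, DecorrParams(n_frames=n))
                for b in small_phantom.volume.blocks
            ]
            for n in (2, 4)
        }
        report = evaluate_methods(labels, methods, surface=4, roi_depth_px=28,
                                  mip_bands=[(0, 27)])
        assert len(report.rows) == 2 * len(labels)
        assert len(report.mip_mse) == 2
        agg = report.aggregates()
        assert set(agg["method"]) == {"sd_2", "sd_4"}
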