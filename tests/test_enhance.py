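import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from cvdenhance.colorspace import EncodedImage, LabImage, rgb_to_lab
from cvdenhance.enhance import (
    CorrectionVector,
    EnhanceConfig,
    SegmentationMask,
    collapse_to_map,
    enhance_image,
    gaussian_kernel_3x3,
    otsu_mask,
    otsu_mask_tiled,
    recolor_mask,
    saliency_error,
    smooth_3x3,
    weighted_difference,
)
from cvdenhance.fixtures import make_scene_with_mask
from cvdenhance.saliency import SaliencyMap


def brute_force_otsu(values, nbins=256):
    """Exhaustive 256-way between-class-variance search (oracle)."""
    lo, hi = values.min(), values.max()
    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = hist.sum()
    best_var, best_t = -1.0, lo
    for split in range(nbins - 1):
        if hist[split] == 0:
            continue  # same partition as the previous occupied split
        n0 = hist[: split + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[: split + 1] * centers[: split + 1]).sum() / n0
        mu1 = (hist[split + 1 :] * centers[split + 1 :]).sum() / n1
        var = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[split]
    return best_t


class TestSaliencyError:
    def test_identical_maps_zero(self, rng):
        s = SaliencyMap(rng.random((8, 8)))
        assert not saliency_error(s, s).values.any()

    def test_complementary_binary_maps_all_ones(self):
        v = np.zeros((6, 6))
        v[:3] = 1.0
        err = saliency_error(SaliencyMap(v), SaliencyMap(1.0 - v))
        np.testing.assert_array_equal(err.values, 1.0)

    def test_matches_per_pixel_oracle(self, rng):
        a, b = rng.random((10, 10)), rng.random((10, 10))
        err = saliency_error(SaliencyMap(a), SaliencyMap(b)).values
        raw = np.array(
            [[abs(a[i, j] - b[i, j]) for j in range(10)] for i in range(10)]
        )
        np.testing.assert_allclose(err, raw / raw.max(), atol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            saliency_error(SaliencyMap(np.zeros((4, 4))), SaliencyMap(np.zeros((5, 4))))


class TestWeightedDifference:
    def test_zero_error_annihilates(self, rng):
        lab = LabImage(rng.random((5, 5, 3)) * 50)
        err = saliency_error(SaliencyMap(np.zeros((5, 5))), SaliencyMap(np.zeros((5, 5))))
        d = weighted_difference(lab, LabImage(np.zeros((5, 5, 3))), err)
        assert not d.any()

    def test_unit_error_gives_plain_difference(self, rng):
        a = LabImage(rng.random((5, 5, 3)) * 50)
        b = LabImage(rng.random((5, 5, 3)) * 50)
        from cvdenhance.enhance import SaliencyErrorMap

        d = weighted_difference(a, b, SaliencyErrorMap(np.ones((5, 5))))
        np.testing.assert_allclose(d, a.pixels - b.pixels)

    def test_signs_retained(self):
        a = LabImage(np.full((1, 1, 3), 10.0))
        b = LabImage(np.full((1, 1, 3), 30.0))
        from cvdenhance.enhance import SaliencyErrorMap

        d = weighted_difference(a, b, SaliencyErrorMap(np.ones((1, 1))))
        assert (d < 0).all()


class TestCollapse:
    def test_zero_weights_annihilate(self, rng):
        d = rng.normal(size=(6, 6, 3))
        out = collapse_to_map(d, CorrectionVector(0, 0, 0))
        assert not out.any()

    def test_red_only_weight_matches_oracle(self, rng):
        d = rng.normal(size=(6, 6, 3))
        out = collapse_to_map(d, CorrectionVector(2, 0, 0))
        oracle = np.array(
            [[2.0 * abs(d[i, j, 0]) / 3.0 for j in range(6)] for i in range(6)]
        )
        oracle = (oracle - oracle.min()) / (oracle.max() - oracle.min())
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            CorrectionVector(-1, 1, 1)


class TestSmooth:
    def test_kernel_sums_to_one(self):
        assert abs(gaussian_kernel_3x3().sum() - 1.0) < 1e-12

    def test_constant_map_unchanged(self):
        m = np.full((9, 9), 0.4)
        np.testing.assert_allclose(smooth_3x3(m), m, atol=1e-12)

    def test_impulse_response_is_kernel(self):
        m = np.zeros((9, 9))
        m[4, 4] = 1.0
        out = smooth_3x3(m)
        np.testing.assert_allclose(out[3:6, 3:6], gaussian_kernel_3x3(), atol=1e-12)

    def test_mass_preserved_under_reflect(self, rng):
        m = rng.random((17, 23))
        assert abs(smooth_3x3(m).sum() - m.sum()) < 1e-9


class TestOtsu:
    def test_bimodal_halves(self):
        m = np.zeros((10, 10))
        m[5:] = 1.0
        mask = otsu_mask(m)
        assert 0.0 < mask.threshold_used < 1.0
        np.testing.assert_array_equal(mask.values, m == 1.0)

    def test_constant_map_empty_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = otsu_mask(np.full((6, 6), 0.3))
        assert mask.area == 0

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(50, 200)
        m = np.concatenate(
            [
                rng.normal(0.25, 0.08, n),
                rng.normal(0.75, 0.08, rng.integers(50, 200)),
            ]
        )
        m = np.clip(m, 0, 1).reshape(1, -1)
        mask = otsu_mask(m)
        assert mask.threshold_used == pytest.approx(brute_force_otsu(m), abs=1e-12)

    def test_mask_is_strictly_above_threshold(self, rng):
        m = rng.random((12, 12))
        mask = otsu_mask(m)
        np.testing.assert_array_equal(mask.values, m > mask.threshold_used)

    def test_tiled_variant_runs(self, rng):
        m = rng.random((32, 32))
        mask = otsu_mask_tiled(m, (2, 2))
        assert mask.values.shape == (32, 32)


class TestRecolor:
    def test_direct_negation(self):
        lab = LabImage(np.array([[[50.0, 30.0, -20.0]]]))
        mask = SegmentationMask(np.ones((1, 1), dtype=bool), 0.5)
        out = recolor_mask(lab, mask).pixels[0, 0]
        np.testing.assert_array_equal(out, [50.0, -30.0, 20.0])

    def test_empty_mask_is_identity(self, rng):
        lab = LabImage(rng.random((6, 6, 3)) * 40)
        mask = SegmentationMask(np.zeros((6, 6), dtype=bool), 0.5)
        np.testing.assert_array_equal(recolor_mask(lab, mask).pixels, lab.pixels)

    @given(
        hnp.arrays(
            np.float64,
            (4, 4, 3),
            elements=st.floats(min_value=-60.0, max_value=60.0),
        ),
        hnp.arrays(np.bool_, (4, 4)),
    )
    @settings(max_examples=50, deadline=None)
    def test_involution_property(self, pixels, mask_values):
        pixels[..., 0] = np.abs(pixels[..., 0])  # valid L*
        lab = LabImage(pixels)
        mask = SegmentationMask(mask_values, 0.0)
        twice = recolor_mask(recolor_mask(lab, mask), mask)
        np.testing.assert_array_equal(twice.pixels, lab.pixels)

    def test_luminance_untouched(self, rng):
        lab = LabImage(rng.random((8, 8, 3)) * 50)
        mask = SegmentationMask(rng.random((8, 8)) > 0.5, 0.0)
        out = recolor_mask(lab, mask)
        np.testing.assert_array_equal(out.pixels[..., 0], lab.pixels[..., 0])


class TestEnhancePipeline:
    def test_grayscale_degenerates_to_identity(self):
        img, _ = make_scene_with_mask((96, 96), seed=1, grayscale=True)
        res = enhance_image(img, "protan")
        assert res.mask.area == 0
        assert np.abs(res.enhanced.pixels - img.pixels).max() < 1.0 / 255.0

    def test_red_disc_segmented_and_hue_flipped(self):
        img, disc = make_scene_with_mask((128, 128), seed=0)
        res = enhance_image(img, "protan")
        m = res.mask.values
        assert m[disc].mean() >= 0.5
        lab_in = rgb_to_lab(img).pixels
        lab_out = rgb_to_lab(res.enhanced).pixels
        inside = m & disc
        # formerly red pixels move to the opposite chroma half-plane
        assert lab_in[inside, 1].mean() > 20.0
        assert lab_out[inside, 1].mean() < 0.0

    def test_locality_outside_mask(self):
        img, _ = make_scene_with_mask((96, 96), seed=3)
        res = enhance_image(img, "protan")
        outside = ~res.mask.values
        assert np.abs(res.enhanced.pixels - img.pixels)[outside].max() < 1.0 / 255.0

    def test_luminance_preserved_inside_mask_before_clipping(self):
        img, _ = make_scene_with_mask((96, 96), seed=3)
        res = enhance_image(img, "protan", debug=True)
        lab_in = rgb_to_lab(img)
        recolored = recolor_mask(lab_in, res.mask)
        np.testing.assert_allclose(
            recolored.pixels[..., 0], lab_in.pixels[..., 0], atol=1e-6
        )

    def test_output_shape_and_simulated_view(self):
        img, _ = make_scene_with_mask((64, 64), seed=5)
        res = enhance_image(img, "deutan")
        assert res.enhanced.shape == img.shape
        assert res.simulated_view is not None
        assert res.simulated_view.shape == img.shape

    def test_debug_exposes_intermediates(self):
        img, _ = make_scene_with_mask((64, 64), seed=5)
        res = enhance_image(img, "protan", debug=True)
        for key in ("collapsed_map", "smoothed_map", "weighted_diff_lab"):
            assert key in res.debug

    def test_identical_orig_and_sim_is_identity(self):
        # achromatic input: simulation is a numerical no-op, so the whole
        # pipeline must degenerate
        gray = np.repeat(np.linspace(0.1, 0.9, 48).reshape(-1, 1, 1), 3, axis=2)
        img = EncodedImage(np.repeat(gray, 48, axis=1))
        res = enhance_image(img, "deutan")
        assert res.mask.area == 0
        assert np.abs(res.enhanced.pixels - img.pixels).max() < 1.0 / 255.0

    def test_tiled_otsu_mode(self):
        img, _ = make_scene_with_mask((64, 64), seed=2)
        res = enhance_image(img, "protan", EnhanceConfig(otsu_mode="tiled"))
        assert res.mask.values.shape == (64, 64)

    def test_mask_cleanup_flag(self):
        img, disc = make_scene_with_mask((128, 128), seed=0)
        res_raw = enhance_image(img, "protan")
        res_clean = enhance_image(
            img, "protan", EnhanceConfig(min_component_frac=0.001)
        )
        assert res_clean.mask.area <= res_raw.mask.area
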