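"""Similarity metrics: identities, closed forms, reference agreement."""

import numpy as np
import pandas as pd
import pytest

from mrxform.metrics import (
    IdentityExtractor,
    RandomConvExtractor,
    bssim,
    compare_models,
    lpips_distance,
    psnr,
    scssim,
    ssim2d,
    ssim3d,
    wilcoxon_one_sided,
)

rng = np.random.default_rng(0)


def _pair(shape=(8, 24, 24), noise=0.1, seed=1):
    local = np.random.default_rng(seed)
    a = local.random(shape)
    b = np.clip(a + noise * local.standard_normal(shape), 0, 1)
    return a, b


class TestSsim:
    def test_identity_is_one_hundred(self):
        a, _ = _pair()
        assert ssim3d(a, a) == pytest.approx(100.0)

    def test_agreement_with_reference_implementation(self):
        from skimage.metrics import structural_similarity as sk_ssim

        for seed in range(20):
            a, b = _pair(seed=seed)
            ref = 100 * sk_ssim(a, b, win_size=7, gaussian_weights=False, data_range=1.0)
            assert abs(ssim3d(a, b) - ref) < 1e-6

    def test_contrast_inverted_binary_phantom_matches_reference(self):
        from skimage.metrics import structural_similarity as sk_ssim

        a = (rng.random((8, 24, 24)) > 0.5).astype(float)
        b = 1.0 - a
        ref = 100 * sk_ssim(a, b, win_size=7, gaussian_weights=False, data_range=1.0)
        assert abs(ssim3d(a, b) - ref) < 1e-6

    def test_joint_translation_leaves_value_nearly_unchanged(self):
        # content embedded in a zero margin; shifting both volumes together
        # moves every local window identically except at the crop borders
        a = np.zeros((8, 32, 32))
        b = np.zeros((8, 32, 32))
        core_a, core_b = _pair(shape=(8, 16, 16), seed=3)
        a[:, 8:24, 8:24] = core_a
        b[:, 8:24, 8:24] = core_b
        s0 = ssim3d(a, b)
        s1 = ssim3d(np.roll(a, 3, axis=2), np.roll(b, 3, axis=2))
        assert abs(s0 - s1) < 0.5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim3d(np.zeros((4, 8, 8)), np.zeros((4, 8, 9)))

    def test_symmetry(self):
        a, b = _pair(seed=5)
        assert ssim3d(a, b) == pytest.approx(ssim3d(b, a))


class TestPsnr:
    def test_identical_inputs_give_inf_sentinel(self):
        a, _ = _pair()
        assert psnr(a, a) == float("inf")

    def test_closed_form_twenty_db(self):
        a = np.zeros((2, 8, 8))
        b = np.full((2, 8, 8), 0.1)  # MSE 0.01, peak 1
        assert psnr(a, b) == pytest.approx(20.0)

    def test_halving_mse_adds_three_db(self):
        a = np.zeros((2, 8, 8))
        b = np.full((2, 8, 8), 0.1)
        c = np.full((2, 8, 8), 0.1 / np.sqrt(2))
        assert psnr(a, c) - psnr(a, b) == pytest.approx(10 * np.log10(2), abs=1e-9)


class TestBssim:
    def test_identity(self):
        a, _ = _pair()
        assert bssim(a, a) == pytest.approx(100.0)

    def test_additive_constant_invariance(self):
        a, _ = _pair(noise=0)
        assert bssim(a, np.clip(a + 0.07, None, None)) == pytest.approx(100.0)

    def test_blur_degrades_edges_more_than_tiny_noise(self):
        from scipy import ndimage

        a, _ = _pair(noise=0, seed=9)
        sharp = ndimage.median_filter(a, size=(1, 3, 3))
        blurred = ndimage.gaussian_filter(sharp, sigma=(0, 2, 2))
        noisy = np.clip(sharp + 1e-4 * rng.standard_normal(sharp.shape), 0, 1)
        assert bssim(sharp, blurred) < bssim(sharp, noisy)


class TestScssim:
    def test_identity(self):
        a, _ = _pair()
        assert scssim(a, a) == pytest.approx(100.0)

    def test_equal_profiles_score_perfect_even_for_different_volumes(self):
        s1 = rng.random((16, 16))
        s2 = rng.random((16, 16))
        a = np.repeat(s1[None], 6, axis=0)  # all consecutive SSIMs are 1
        b = np.repeat(s2[None], 6, axis=0)
        assert scssim(a, b) == pytest.approx(100.0)

    def test_noise_slice_lowers_score_monotonically(self):
        a, _ = _pair(shape=(6, 16, 16), noise=0, seed=2)
        local = np.random.default_rng(12)
        noise = local.standard_normal((16, 16))
        vals = []
        for amp in (0.05, 0.8):
            b = a.copy()
            b[3] = np.clip(a[3] + amp * noise, 0, 1)
            vals.append(scssim(a, b))
        assert vals[0] < 100.0
        assert vals[1] < vals[0]

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError):
            scssim(np.zeros((1, 8, 8)), np.zeros((1, 8, 8)))


class TestLpips:
    def test_identity_is_zero_for_any_extractor(self):
        a, _ = _pair()
        for fx in (IdentityExtractor(), RandomConvExtractor(seed=1)):
            assert lpips_distance(a, a, fx) == pytest.approx(0.0)

    def test_degenerate_extractor_reduces_to_mse(self):
        a, b = _pair(seed=7)
        assert lpips_distance(a, b, IdentityExtractor()) == pytest.approx(((a - b) ** 2).mean())

    def test_symmetry(self):
        a, b = _pair(seed=8)
        fx = RandomConvExtractor(seed=0)
        assert lpips_distance(a, b, fx) == pytest.approx(lpips_distance(b, a, fx))

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lpips_distance(np.zeros((2, 8, 8)), np.zeros((2, 16, 16)))


class TestCompareModels:
    def _report(self, values_by_model):
        rows = []
        for model, vals in values_by_model.items():
            for i, v in enumerate(vals):
                rows.append({"subject_id": f"s{i}", "model": model, "ssim": v})
        return pd.DataFrame(rows)

    def test_identical_models_are_both_best(self):
        vals = list(rng.random(20))
        rep = self._report({"a": vals, "b": vals})
        pvals, best = compare_models(rep, "ssim")
        assert best == {"a", "b"}
        assert pvals[("a", "b")] == 1.0

    def test_uniform_improvement_is_significant_at_n20(self):
        base = list(rng.random(20))
        rep = self._report({"a": [v + 1 for v in base], "b": base})
        pvals, best = compare_models(rep, "ssim")
        assert pvals[("a", "b")] < 0.05
        assert best == {"a"}

    def test_decision_invariant_to_subject_order(self):
        base = list(rng.random(15))
        rep = self._report({"a": [v + 1 for v in base], "b": base, "c": base})
        shuffled = rep.sample(frac=1.0, random_state=3)
        _, best1 = compare_models(rep, "ssim")
        _, best2 = compare_models(shuffled, "ssim")
        assert best1 == best2

    def test_lpips_direction_lower_is_better(self):
        base = list(rng.random(20))
        rows = []
        for model, vals in {"a": base, "b": [v + 1 for v in base]}.items():
            for i, v in enumerate(vals):
                rows.append({"subject_id": f"s{i}", "model": model, "lpips": v})
        _, best = compare_models(pd.DataFrame(rows), "lpips")
        assert best == {"a"}

    def test_unpaired_rows_rejected(self):
        assert wilcoxon_one_sided([1, 2, 3], [1, 2, 3]) == 1.0
        with pytest.raises(ValueError):
            wilcoxon_one_sided([1, 2, 3], [1, 2])
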