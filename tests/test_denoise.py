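"""The complexity filter: brute-force oracles, thresholding, pipeline contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from lcwd import (
    SUPPORTED_WAVELETS,
    Image2D,
    StdMap,
    alpha_map,
    apply_condition,
    decompose,
    denoise,
    global_threshold,
    hardzero_denoise,
    local_std_map,
    reconstruct,
)


# ---- independent brute-force references (double loops, explicit formulas) ----

def bruteforce_std_map(hh: np.ndarray) -> np.ndarray:
    p = np.pad(hh, 1, mode="symmetric")
    out = np.empty_like(hh, dtype=np.float64)
    for i in range(hh.shape[0]):
        for j in range(hh.shape[1]):
            win = p[i : i + 3, j : j + 3].ravel()
            ybar = win.mean()
            out[i, j] = np.sqrt(np.sum((win - ybar) ** 2) / 9.0)
    return out


def bruteforce_alpha_map(sigma: np.ndarray) -> np.ndarray:
    p = np.pad(sigma, 1, mode="symmetric")
    out = np.empty_like(sigma, dtype=np.float64)
    for i in range(sigma.shape[0]):
        for j in range(sigma.shape[1]):
            win = p[i : i + 3, j : j + 3].ravel()
            out[i, j] = abs(sigma[i, j] - np.median(win))
    return out


matrices = hnp.arrays(
    np.float64,
    st.tuples(st.integers(3, 16), st.integers(3, 16)),
    elements=st.floats(-100, 100, allow_nan=False),
)


class TestStdMap:
    def test_constant_matrix_gives_zero_sigma(self):
        assert np.array_equal(local_std_map(np.full((5, 7), 3.3)).sigma, np.zeros((5, 7)))

    def test_interior_window_hand_value(self):
        # 3x3 window holding 0..8: mean 4, squared deviations sum to 60
        hh = np.arange(9, dtype=float).reshape(3, 3)
        sm = local_std_map(hh)
        assert sm.sigma[1, 1] == pytest.approx(np.sqrt(60.0 / 9.0), abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(matrices)
    def test_matches_bruteforce(self, hh):
        assert np.allclose(local_std_map(hh).sigma, bruteforce_std_map(hh), atol=1e-10, rtol=0)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            local_std_map(np.zeros((2, 5)))

    def test_sigma_nonnegative(self, rng):
        assert np.all(local_std_map(rng.standard_normal((20, 20))).sigma >= 0)


class TestThreshold:
    def test_odd_count_median(self):
        assert global_threshold(StdMap(np.array([[1.0, 2.0, 3.0]]), 3)) == 2.0

    def test_all_zero_map(self):
        assert global_threshold(StdMap(np.zeros((4, 4)), 16)) == 0.0

    def test_even_count_uses_lower_median(self):
        sm = StdMap(np.array([[0.5, 1.5], [2.5, 9.0]]), 4)
        assert global_threshold(sm) == 1.5
        assert global_threshold(sm, convention="midpoint") == 2.0

    @settings(deadline=None, max_examples=30)
    @given(hnp.arrays(np.float64, st.integers(1, 50), elements=st.floats(0, 50)))
    def test_lower_median_is_sorted_element(self, vals):
        sm = StdMap(vals.reshape(1, -1), vals.size)
        t = global_threshold(sm)
        assert t == np.sort(vals)[(vals.size - 1) // 2]

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            global_threshold(StdMap(np.ones((2, 2)), 4), convention="upper")


class TestAlphaMap:
    def test_constant_sigma_gives_zero_alpha(self):
        assert np.array_equal(alpha_map(StdMap(np.full((6, 6), 2.0), 36)), np.zeros((6, 6)))

    def test_isolated_spike_alpha_equals_spike(self):
        # window {0,...,0,5,...}: median of nine values with eight zeros is 0
        sigma = np.zeros((3, 3))
        sigma[1, 1] = 5.0
        assert alpha_map(StdMap(sigma, 9))[1, 1] == 5.0

    @settings(deadline=None, max_examples=30)
    @given(hnp.arrays(np.float64, st.tuples(st.integers(3, 16), st.integers(3, 16)),
                      elements=st.floats(0, 100, allow_nan=False)))
    def test_matches_bruteforce(self, sigma):
        got = alpha_map(StdMap(sigma, sigma.size))
        assert np.allclose(got, bruteforce_alpha_map(sigma), atol=1e-12, rtol=0)


class TestCondition:
    def test_strict_inequality_on_degenerate_zero_case(self, rng):
        hh = rng.standard_normal((8, 8))
        d = apply_condition(hh, np.zeros((8, 8)), 0.0)
        assert np.array_equal(d.wc_out, hh)  # 0 > 0 is false
        assert not d.noise_mask.any()

    def test_exceeding_alpha_zeroes_coefficient(self):
        hh = np.full((4, 4), 7.0)
        alpha = np.zeros((4, 4))
        alpha[2, 3] = 5.0
        d = apply_condition(hh, alpha, 2.0)
        assert d.wc_out[2, 3] == 0.0
        assert d.noise_mask.sum() == 1

    def test_threshold_above_max_alpha_is_identity(self, rng):
        hh = rng.standard_normal((10, 10))
        alpha = np.abs(rng.standard_normal((10, 10)))
        d = apply_condition(hh, alpha, float(alpha.max()) + 1.0)
        assert np.array_equal(d.wc_out, hh)

    def test_mask_and_output_are_consistent(self, rng):
        hh = rng.standard_normal((12, 12))
        alpha = np.abs(rng.standard_normal((12, 12)))
        d = apply_condition(hh, alpha, 0.5)
        assert np.all(d.wc_out[d.noise_mask] == 0)
        assert np.array_equal(d.wc_out[~d.noise_mask], hh[~d.noise_mask])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_condition(np.zeros((4, 4)), np.zeros((4, 5)), 1.0)

    def test_mask_is_antitone_in_threshold(self, rng):
        # lowering T never un-zeroes a coefficient
        hh = rng.standard_normal((16, 16))
        alpha = np.abs(rng.standard_normal((16, 16)))
        thresholds = np.sort(rng.uniform(0, alpha.max(), 8))
        masks = [apply_condition(hh, alpha, t).noise_mask for t in thresholds]
        for lo, hi in zip(masks[:-1], masks[1:]):
            assert np.all(lo | ~hi)  # hi ⇒ lo


class TestDenoisePipeline:
    @pytest.mark.parametrize("wavelet", SUPPORTED_WAVELETS)
    def test_constant_image_is_a_fixed_point(self, wavelet):
        img = Image2D(np.full((64, 64), 128.0))
        out, dec = denoise(img, wavelet)
        assert np.abs(out.pixels - img.pixels).max() < 1e-6

    def test_zero_hh_image_is_a_fixed_point(self, random_image):
        dec = decompose(random_image, "db4")
        flat = reconstruct(dec.replace_bands(HH=np.zeros(dec.subband_shape)))
        out, _ = denoise(flat, "db4")
        assert np.abs(out.pixels - flat.pixels).max() < 1e-6

    def test_only_hh_is_touched(self, brain_phantom):
        from lcwd import NoiseSpec, add_rician

        noisy = add_rician(brain_phantom, NoiseSpec("rician", percent=9.0, seed=0))
        out, decision = denoise(noisy, "db4")
        before = decompose(noisy, "db4")
        after = decompose(out, "db4")
        assert np.allclose(after.LL, before.LL, atol=1e-6)
        assert np.allclose(after.LH, before.LH, atol=1e-6)
        assert np.allclose(after.HL, before.HL, atol=1e-6)
        hh_kept = np.abs(after.HH - before.HH) < 1e-6
        hh_zeroed = np.abs(after.HH) < 1e-6
        assert np.all(np.where(decision.noise_mask, hh_zeroed, hh_kept))

    def test_decision_record_invariants(self, brain_phantom):
        from lcwd import NoiseSpec, add_awgn

        noisy = add_awgn(brain_phantom, NoiseSpec("awgn", sigma=20.0, seed=1))
        _, d = denoise(noisy, "haar")
        assert d.threshold >= 0
        assert np.all(d.alpha >= 0)
        assert np.all(d.wc_out[d.noise_mask] == 0)

    def test_kernel_scope_zeroes_dilated_neighbourhood(self, brain_phantom):
        from lcwd import NoiseSpec, add_awgn
        from scipy import ndimage

        noisy = add_awgn(brain_phantom, NoiseSpec("awgn", sigma=10.0, seed=2))
        _, dc = denoise(noisy, "db2", zero_scope="center")
        _, dk = denoise(noisy, "db2", zero_scope="kernel")
        grown = ndimage.binary_dilation(dc.noise_mask, structure=np.ones((3, 3), bool))
        assert np.array_equal(dk.noise_mask, grown)
        assert np.all(dk.wc_out[dk.noise_mask] == 0)

    def test_unknown_zero_scope_rejected(self, random_image):
        with pytest.raises(ValueError):
            denoise(random_image, "haar", zero_scope="everything")


class TestHardzero:
    def test_all_bands_on_constant_image_is_identity(self):
        img = Image2D(np.full((32, 32), 99.0))
        out = hardzero_denoise(img, "sym2", bands={"LH", "HL", "HH"})
        assert np.abs(out.pixels - img.pixels).max() < 1e-8

    def test_hh_band_matches_subband_surgery(self, random_image):
        out = hardzero_denoise(random_image, "db4", bands={"HH"})
        dec = decompose(random_image, "db4")
        direct = reconstruct(dec.replace_bands(HH=np.zeros(dec.subband_shape)))
        assert np.array_equal(out.pixels, direct.pixels)

    def test_matches_denoise_with_all_true_mask(self, random_image):
        # forcing every alpha above T reproduces the T=0 hard threshold on HH
        dec = decompose(random_image, "db4")
        forced = apply_condition(dec.HH, np.ones(dec.subband_shape), 0.0)
        assert forced.noise_mask.all()
        rec = reconstruct(dec.replace_bands(HH=forced.wc_out))
        hz = hardzero_denoise(random_image, "db4", bands={"HH"})
        assert np.allclose(rec.pixels, hz.pixels, atol=1e-12)

    def test_empty_or_unknown_bands_rejected(self, random_image):
        with pytest.raises(ValueError):
            hardzero_denoise(random_image, "haar", bands=set())
        with pytest.raises(ValueError):
            hardzero_denoise(random_image, "haar", bands={"LL"})
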