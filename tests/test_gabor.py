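"""Gabor bank construction, magnitude responses, normalization and PCA."""

import math

import numpy as np
import pytest

from geobia.gabor import (
    DEFAULT_ORIENTATIONS,
    DEFAULT_WAVELENGTHS,
    GaborBank,
    GaborFilter,
    TextureStack,
    apply_bank,
    build_bank,
    normalize_stack,
    octave_envelope_width,
    required_overlap,
    stack_pca,
)
from geobia.raster import Raster


def sinusoid(shape, wavelength, theta_deg, amplitude=1.0, offset=0.5):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    th = math.radians(theta_deg)
    phase = (cols * math.cos(th) + rows * math.sin(th)) / wavelength
    return Raster(offset + amplitude * np.sin(2 * math.pi * phase))


class TestBank:
    def test_default_bank_has_sixteen_filters(self):
        bank = build_bank()
        assert len(bank) == 16
        assert {f.wavelength for f in bank.filters} == set(DEFAULT_WAVELENGTHS)
        assert {f.theta_deg for f in bank.filters} == set(DEFAULT_ORIENTATIONS)

    def test_single_pair_gives_single_filter(self):
        assert len(build_bank([8.0], [0.0])) == 1

    def test_order_is_deterministic_orientation_major(self):
        b1 = build_bank([4.0, 8.0], [0.0, 90.0])
        b2 = build_bank([4.0, 8.0], [0.0, 90.0])
        assert b1.filters == b2.filters
        assert [(f.theta_deg, f.wavelength) for f in b1.filters] == [
            (0.0, 4.0),
            (0.0, 8.0),
            (90.0, 4.0),
            (90.0, 8.0),
        ]

    def test_empty_or_duplicate_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_bank([], [0.0])
        with pytest.raises(ValueError):
            build_bank([4.0, 4.0], [0.0])

    def test_default_envelope_is_one_octave(self):
        f = build_bank([8.0], [0.0]).filters[0]
        assert f.gamma == pytest.approx(octave_envelope_width())
        # spatial envelope sd ~ 0.56 wavelengths for a 1-octave filter
        assert f.sigma_u / f.wavelength == pytest.approx(0.5622, abs=1e-3)


class TestResponses:
    def test_constant_image_gives_near_zero_magnitude(self):
        bank = build_bank([4.0, 8.0], [0.0, 90.0])
        stack = apply_bank(Raster(np.full((64, 64), 3.7)), bank)
        assert np.abs(stack.bands).max() <= 1e-6 * 3.7

    def test_offset_invariance_of_magnitude(self):
        bank = build_bank([6.0], [0.0])
        img = sinusoid((64, 64), 6.0, 0.0)
        shifted = Raster(img.values + 5.0)
        a = apply_bank(img, bank).bands
        b = apply_bank(shifted, bank).bands
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_matched_filter_has_maximal_mean_magnitude(self):
        bank = build_bank([4.0, 8.0, 16.0], [0.0, 45.0, 90.0, 135.0])
        img = sinusoid((96, 96), 8.0, 45.0)
        stack = apply_bank(img, bank)
        means = stack.bands.mean(axis=(1, 2))
        matched = next(
            i
            for i, f in enumerate(bank.filters)
            if f.wavelength == 8.0 and f.theta_deg == 45.0
        )
        assert np.argmax(means) == matched
        others = np.delete(means, matched)
        assert means[matched] > others.max()

    def test_quarter_turn_of_image_swaps_orientation_responses(self):
        bank = build_bank([8.0], [0.0, 90.0])
        img = sinusoid((96, 96), 8.0, 0.0)
        rot = Raster(np.rot90(img.values).copy())
        means = apply_bank(img, bank).bands.mean(axis=(1, 2))
        means_rot = apply_bank(rot, bank).bands.mean(axis=(1, 2))
        # response of the 0-degree filter moves to the 90-degree filter
        np.testing.assert_allclose(means[0], means_rot[1], rtol=0.05)
        np.testing.assert_allclose(means[1], means_rot[0], rtol=0.05)

    def test_tiled_equals_untiled_on_interior(self):
        bank = build_bank([2.82842712475, 7.0710678], [0.0, 45.0])
        rng = np.random.default_rng(0)
        img = Raster(rng.uniform(0, 1, (128, 128)))
        whole = apply_bank(img, bank)
        need = required_overlap(bank)
        tiled = apply_bank(img, bank, tile=2 * need + 1, overlap=need)
        np.testing.assert_allclose(tiled.bands, whole.bands, rtol=1e-6, atol=1e-9)

    def test_insufficient_overlap_or_tiny_tile_rejected(self):
        bank = build_bank([8.0], [0.0])
        img = Raster(np.zeros((64, 64)))
        need = required_overlap(bank)
        with pytest.raises(ValueError):
            apply_bank(img, bank, tile=64, overlap=need - 1)
        with pytest.raises(ValueError):
            apply_bank(img, bank, tile=2 * need, overlap=need)

    def test_direct_convolution_oracle_at_probe_pixels(self):
        # independent check of one filter response by explicit summation
        f = GaborFilter(wavelength=5.0, theta_deg=45.0, gamma=0.8, n=0.8)
        bank = GaborBank(filters=(f,), smoothing_sigmas=(0.0,))
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (48, 48))
        stack = apply_bank(Raster(img), bank)
        k = f.kernel()
        r = k.shape[0] // 2
        for (py, px) in [(20, 20), (24, 17), (30, 30)]:
            acc = 0.0 + 0.0j
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    acc += img[py - dy, px - dx] * k[r + dy, r + dx]
            assert stack.bands[0, py, px] == pytest.approx(abs(acc), rel=1e-9)


class TestNormalizeAndPca:
    def _stack(self, arrays):
        bank = build_bank([4.0] * 1, list(np.linspace(0, 170, len(arrays))))
        return TextureStack(bands=np.stack(arrays), bank=bank)

    def test_zscore_moments_and_idempotence(self, rng):
        arrays = [rng.uniform(0, i + 1, (16, 16)) for i in range(3)]
        norm = normalize_stack(self._stack(arrays))
        for band in norm.bands:
            assert abs(band.mean()) < 1e-9
            assert abs(band.std() - 1.0) < 1e-9
        again = normalize_stack(norm)
        np.testing.assert_allclose(again.bands, norm.bands, atol=1e-9)

    def test_constant_band_normalizes_to_zeros(self, rng):
        arrays = [np.full((8, 8), 2.0), rng.uniform(0, 1, (8, 8))]
        norm = normalize_stack(self._stack(arrays))
        np.testing.assert_allclose(norm.bands[0], 0.0)

    def test_rank_one_stack_pc1_explains_everything(self):
        base = np.outer(np.arange(1, 9), np.arange(1, 9)).astype(float)
        stack = self._stack([base, 2 * base, -0.5 * base])
        norm = normalize_stack(stack)
        _, model = stack_pca(norm, k=1, return_model=True)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_two_band_toy_explained_variance(self):
        # bands [1,2,3,4] and [2,4,6,8] per pixel: perfectly collinear
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        stack = self._stack([a, 2 * a])
        _, model = stack_pca(stack, k=1, return_model=True)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_pc1_variance_dominates_every_band(self, rng):
        arrays = [rng.standard_normal((16, 16)) for _ in range(4)]
        norm = normalize_stack(self._stack(arrays))
        scores = stack_pca(norm, k=1)[0].values
        assert scores.var() >= max(b.var() for b in norm.bands) - 1e-9

    def test_pc_scores_are_orthogonal(self, rng):
        arrays = [rng.standard_normal((16, 16)) for _ in range(4)]
        norm = normalize_stack(self._stack(arrays))
        scores = [r.values.ravel() for r in stack_pca(norm, k=3)]
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.corrcoef(scores[i], scores[j])[0, 1]
                assert abs(r) < 1e-6

    def test_sign_convention_makes_pca_deterministic(self, rng):
        arrays = [rng.standard_normal((12, 12)) for _ in range(4)]
        norm = normalize_stack(self._stack(arrays))
        s1 = stack_pca(norm, k=2)
        s2 = stack_pca(norm, k=2)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_k_out_of_range_rejected(self, rng):
        norm = normalize_stack(
            self._stack([rng.standard_normal((8, 8)) for _ in range(3)])
        )
        with pytest.raises(ValueError):
            stack_pca(norm, k=0)
        with pytest.raises(ValueError):
            stack_pca(norm, k=4)
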