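"""Loss arithmetic, screening maps, and the numpy/autograd dual paths."""

import numpy as np
import pytest

from bpfuse.errors import InvalidInputError
from bpfuse.losses import (AdversarialLabels, LossWeights, ScreeningMaps,
                           adversarial_loss, calibrate_weights,
                           discriminator_loss, generator_total, gradient_loss,
                           pixel_loss, screening_maps)
from bpfuse.nn.autograd import Tensor

import oracles


def half_maps(shape):
    return ScreeningMaps(np.full(shape, 0.5), np.full(shape, 0.5))


class TestScreeningMaps:
    def test_textured_vs_flat(self, rng):
        m = rng.random((16, 16))            # busy everywhere
        i = np.full((16, 16), 0.3)          # constant: zero variance
        maps = screening_maps(m, i)
        np.testing.assert_array_equal(maps.map1, 1.0)
        np.testing.assert_array_equal(maps.map2, 0.0)

    def test_tie_rule_on_identical_inputs(self, rng):
        m = rng.random((12, 12))
        maps = screening_maps(m, m.copy())
        np.testing.assert_array_equal(maps.map1, 0.5)
        np.testing.assert_array_equal(maps.map2, 0.5)

    def test_matches_window_variance_oracle(self, rng):
        m, i = rng.random((10, 11)), rng.random((10, 11))
        maps = screening_maps(m, i, window=5)
        map1, map2 = oracles.screening_maps_loop(m, i, 5)
        np.testing.assert_allclose(maps.map1, map1, atol=1e-12)
        np.testing.assert_allclose(maps.map2, map2, atol=1e-12)

    def test_constant_mode_and_validation(self, rng):
        maps = screening_maps(rng.random((8, 8)), rng.random((8, 8)),
                              mode="constant")
        np.testing.assert_array_equal(maps.map1, 0.5)
        with pytest.raises(InvalidInputError):
            screening_maps(rng.random((8, 8)), rng.random((8, 9)))
        with pytest.raises(InvalidInputError):
            screening_maps(rng.random((8, 8)), rng.random((8, 8)), window=4)
        with pytest.raises(InvalidInputError):
            ScreeningMaps(np.full((4, 4), 0.7), np.full((4, 4), 0.7))


class TestAdversarialLoss:
    def test_hand_values(self):
        assert adversarial_loss([1.0, 1.0]) == 0.0
        assert adversarial_loss([0.0]) == 1.0
        assert adversarial_loss([0.5, 0.5]) == 0.25

    def test_empty_batch_rejected(self):
        with pytest.raises(InvalidInputError):
            adversarial_loss([])

    def test_tensor_path_matches_numpy(self, rng):
        s = rng.random(6)
        assert adversarial_loss(Tensor(s)).item() == pytest.approx(
            adversarial_loss(s), abs=1e-12
        )


class TestPixelLoss:
    def test_zero_at_documented_minimizers(self, rng):
        m, i = rng.random((8, 8)), rng.random((8, 8))
        ones = ScreeningMaps(np.ones((8, 8)), np.zeros((8, 8)))
        assert pixel_loss(m, m, i, ones) == 0.0
        flipped = ScreeningMaps(np.zeros((8, 8)), np.ones((8, 8)))
        assert pixel_loss(i, m, i, flipped) == 0.0

    def test_one_pixel_arithmetic(self):
        maps = half_maps((1, 1))
        val = pixel_loss(np.array([[0.5]]), np.array([[0.0]]),
                         np.array([[1.0]]), maps)
        assert val == pytest.approx(0.25, abs=1e-15)

    def test_matches_loop_oracle_and_tensor_path(self, rng):
        fused, m, i = (rng.random((9, 9)) for _ in range(3))
        maps = screening_maps(m, i, window=5)
        val = pixel_loss(fused, m, i, maps)
        assert val == pytest.approx(
            oracles.pixel_loss_loop(fused, m, i, maps.map1, maps.map2),
            abs=1e-12,
        )
        tval = pixel_loss(Tensor(fused[None, None]), m, i, maps).item()
        assert tval == pytest.approx(val, abs=1e-12)

    def test_swap_symmetry(self, rng):
        fused, m, i = (rng.random((8, 8)) for _ in range(3))
        maps = screening_maps(m, i)
        swapped = ScreeningMaps(maps.map2, maps.map1)
        assert pixel_loss(fused, m, i, maps) == pytest.approx(
            pixel_loss(fused, i, m, swapped), abs=1e-12
        )


class TestGradientLoss:
    def test_zero_cases(self, rng):
        m = rng.random((8, 8))
        y = rng.random((8, 8))
        ones = ScreeningMaps(np.ones((8, 8)), np.zeros((8, 8)))
        assert gradient_loss(m, m, y, ones) == 0.0
        const = np.full((8, 8), 0.4)
        assert gradient_loss(const, np.full((8, 8), 0.1),
                             np.full((8, 8), 0.9), half_maps((8, 8))) == 0.0

    def test_matches_loop_oracle_and_tensor_path(self, rng):
        fused, m, y = (rng.random((10, 10)) for _ in range(3))
        maps = screening_maps(m, y)
        val = gradient_loss(fused, m, y, maps)
        assert val == pytest.approx(
            oracles.gradient_loss_loop(fused, m, y, maps.map1, maps.map2),
            abs=1e-12,
        )
        tval = gradient_loss(Tensor(fused[None, None]), m, y, maps).item()
        assert tval == pytest.approx(val, abs=1e-10)


class TestTotalsAndLabels:
    def test_generator_total_arithmetic(self):
        w = LossWeights(1.0, 1.0)
        assert generator_total(0.1, 0.2, 0.3, w) == pytest.approx(0.6)
        assert generator_total(0.7, 5.0, 9.0, LossWeights(0, 0)) == 0.7
        w2 = LossWeights(2.0, 1.0)
        base = generator_total(0.0, 0.2, 0.0, LossWeights(1.0, 1.0))
        assert generator_total(0.0, 0.2, 0.0, w2) == pytest.approx(2 * base)

    def test_discriminator_loss_hand_values(self):
        assert discriminator_loss([0.0, 0.0], [1.0, 1.0]) == 0.0
        assert discriminator_loss([0.5, 0.5], [0.5, 0.5]) == pytest.approx(0.5)
        assert discriminator_loss([1.0], [0.0]) == pytest.approx(2.0)
        with pytest.raises(InvalidInputError):
            discriminator_loss([0.5], [0.5, 0.5])
        with pytest.raises(InvalidInputError):
            discriminator_loss([], [])

    def test_labels_validation(self):
        with pytest.raises(InvalidInputError):
            AdversarialLabels(a=1.0, b=0.0)
        with pytest.raises(InvalidInputError):
            LossWeights(lambda1=-1.0)

    def test_calibration_balances_components(self):
        w = calibrate_weights(0.4, 0.2, 0.05)
        assert 0.4 == pytest.approx(w.lambda1 * 0.2)
        assert 0.4 == pytest.approx(w.lambda2 * 0.05)
        # degenerate components keep weight 1
        assert calibrate_weights(0.4, 0.0, 0.0) == LossWeights(1.0, 1.0)
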