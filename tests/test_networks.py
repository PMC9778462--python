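"""Generator, discriminator, BPDB and CBAM contracts."""

import numpy as np
import pytest

from bpfuse.errors import ConfigurationError, InvalidInputError
from bpfuse.losses import AdversarialLabels, screening_maps
from bpfuse.nn import (BPDB, CBAM, Discriminator, DiscriminatorConfig,
                       Generator, GeneratorConfig, Tensor)
from bpfuse.nn.autograd import conv2d


SMALL = GeneratorConfig(base_channels=8)
DISC_SMALL = DiscriminatorConfig(channel_schedule=(8, 16, 32))


def test_bpdb_preserves_shape_and_is_finite(rng):
    block = BPDB(8, rng=rng)
    x = rng.standard_normal((8, 16, 16))
    out = block.forward_array(x)
    assert out.shape == x.shape
    assert np.all(np.isfinite(out))


def test_bpdb_zero_weights_propagate_zero(rng):
    block = BPDB(6, rng=rng)
    for p in block.parameters():
        p.data[:] = 0.0
    out = block.forward_array(rng.standard_normal((6, 10, 10)))
    np.testing.assert_array_equal(out, 0.0)


def test_bpdb_channel_mismatch_is_config_error(rng):
    block = BPDB(8, rng=rng)
    with pytest.raises(ConfigurationError):
        block(Tensor(np.zeros((1, 4, 8, 8))))


def test_cbam_preserves_shape_and_zero_channels(rng):
    att = CBAM(8, rng=rng)
    x = rng.standard_normal((8, 12, 12))
    x[3] = 0.0
    out = att.forward_array(x)
    assert out.shape == x.shape
    np.testing.assert_array_equal(out[3], 0.0)


def test_cbam_sigmoid_gate_contracts(rng):
    att = CBAM(8, gate="sigmoid", rng=rng)
    # non-trivial gate weights (init is pass-through)
    for p in att.parameters():
        p.data = rng.standard_normal(p.data.shape) * 0.2
    x = rng.standard_normal((8, 10, 10))
    out = att.forward_array(x)
    assert np.all(np.abs(out) <= np.abs(x) + 1e-12)


def test_cbam_rejects_single_channel(rng):
    with pytest.raises(ConfigurationError):
        CBAM(1, rng=rng)


def test_generator_shape_range_determinism(rng):
    gen = Generator(SMALL, rng=rng)
    m, y = rng.random((40, 56)), rng.random((40, 56))
    out1 = gen.fuse(m, y)
    out2 = gen.fuse(m, y)
    assert out1.shape == (40, 56)
    assert out1.min() >= 0.0 and out1.max() <= 1.0
    np.testing.assert_array_equal(out1, out2)


def test_generator_branches_are_independent(rng):
    gen = Generator(SMALL, rng=rng)
    m, y = rng.random((32, 32)), rng.random((32, 32))
    direct = gen.fuse(m, y)
    swapped = gen.fuse(y, m)
    assert np.abs(direct - swapped).max() > 1e-6


def test_generator_rejects_mismatched_inputs(rng):
    gen = Generator(SMALL, rng=rng)
    with pytest.raises(InvalidInputError):
        gen.fuse(rng.random((32, 32)), rng.random((32, 33)))


def test_parameter_count_matches_hand_computation(rng):
    """Parameter count is a pure function of the configs.

    base_channels=8, reduction 8, kernel 3:
      branch = conv(1->8)+conv(8->8) + BPDB(8): 7 conv(8->8) + CBAM(8)
      composite at 16 channels, head conv(16->8) + conv(8->1).
    """
    per_conv = lambda ci, co, k=3: co * ci * k * k + co
    branch = (per_conv(1, 8) + per_conv(8, 8)            # extraction
              + 7 * per_conv(8, 8)                       # BPDB
              + (8 * 1 + 1) + (1 * 8 + 8)                # CBAM shared MLP
              + per_conv(2, 1, 1))                       # CBAM spatial 1x1
    composite = (7 * per_conv(16, 16)
                 + (16 * 2 + 2) + (2 * 16 + 16) + per_conv(2, 1, 1))
    head = per_conv(16, 8) + per_conv(8, 1)
    expected = 2 * branch + composite + head
    assert Generator(SMALL, rng=rng).n_parameters() == expected

    disc_expected = (per_conv(1, 8) + per_conv(8, 16) + per_conv(16, 32)
                     + (32 * 1 + 1))
    assert Discriminator(DISC_SMALL, rng=rng).n_parameters() == disc_expected


def test_discriminator_outputs_probabilities(rng):
    disc = Discriminator(DISC_SMALL, rng=rng)
    for _ in range(5):
        s = disc.score(rng.standard_normal((32, 32)))
        assert 0.0 <= s <= 1.0
    assert disc.score(np.zeros((32, 32))) == disc.score(np.zeros((32, 32)))


def test_discriminator_batch_equals_per_sample(rng):
    disc = Discriminator(DISC_SMALL, rng=rng)
    maps = rng.standard_normal((4, 1, 32, 32))
    batched = disc(Tensor(maps)).data
    singles = np.array([disc(Tensor(maps[k:k + 1])).data[0] for k in range(4)])
    np.testing.assert_allclose(batched, singles, atol=1e-12)


def test_discriminator_rejects_non_finite(rng):
    disc = Discriminator(DISC_SMALL, rng=rng)
    bad = np.zeros((32, 32))
    bad[0, 0] = np.nan
    with pytest.raises(InvalidInputError):
        disc.score(bad)


def test_spectral_norm_bounds_weight_scale(rng):
    cfg = DiscriminatorConfig(channel_schedule=(8, 16), use_spectral_norm=True)
    disc = Discriminator(cfg, rng=rng)
    for p in disc.parameters():
        p.data *= 50.0      # inflate weights; scores must stay in [0, 1]
    s = disc.score(rng.standard_normal((16, 16)))
    assert 0.0 <= s <= 1.0


def test_total_loss_gradients_finite_everywhere(rng):
    from bpfuse.losses import _laplacian_tensor

    gen = Generator(SMALL, rng=rng)
    disc = Discriminator(DISC_SMALL, rng=rng)
    m = rng.random((2, 1, 32, 32))
    y = rng.random((2, 1, 32, 32))
    maps = screening_maps(m[0, 0], y[0, 0])
    fused = gen(Tensor(m), Tensor(y))
    lap_f = _laplacian_tensor(fused, "4")
    scores = disc(lap_f.abs())
    labels = AdversarialLabels()
    loss = (((scores - labels.c) ** 2).mean()
            + (maps.map1 * (fused - m) ** 2 + maps.map2 * (fused - y) ** 2).mean()
            + (lap_f ** 2).mean())
    loss.backward()
    for p in gen.parameters() + disc.parameters():
        assert p.grad is not None
        assert np.all(np.isfinite(p.grad))
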