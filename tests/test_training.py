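"""Dataset splitting, the adversarial loop, fusion and ablation grids."""

import dataclasses

import numpy as np
import pytest

from bpfuse.colorspace import rgb_to_ycbcr
from bpfuse.errors import ConfigurationError, InvalidInputError
from bpfuse.losses import gradient_loss, pixel_loss, screening_maps
from bpfuse.nn.autograd import Tensor
from bpfuse.losses import _laplacian_tensor
from bpfuse.training import (AblationFlags, Checkpoint, FusionRecord,
                             TrainConfig, desk_config, evaluate_records,
                             fuse_pair, load_records, run_ablation,
                             split_dataset, train)

TINY = desk_config(epochs=2, seed=11, dtype="float64")


class TestSplitDataset:
    def test_published_ratio_on_ten_records(self):
        parts = split_dataset(list(range(10)), (0.7, 0.2, 0.1), seed=0)
        assert tuple(len(p) for p in parts) == (7, 2, 1)

    def test_reproducible_and_exhaustive(self):
        records = list(range(23))
        a = split_dataset(records, seed=4)
        b = split_dataset(records, seed=4)
        assert a == b
        merged = sorted(x for part in a for x in part)
        assert merged == records

    def test_too_few_records_rejected(self):
        with pytest.raises(InvalidInputError):
            split_dataset([1, 2], (0.7, 0.2, 0.1), seed=0)
        with pytest.raises(InvalidInputError):
            split_dataset(list(range(10)), (0.5, 0.2, 0.1), seed=0)


class TestTrainLoop:
    def test_smoke_run_logs_finite_losses(self, phantom_records_32):
        ckpt = train(TINY, phantom_records_32)
        assert len(ckpt.loss_log) == 2 * 2   # 2 epochs x ceil(8/4) steps
        for row in ckpt.loss_log:
            assert all(np.isfinite(v) for v in row.values())

    def test_update_ratio_is_exactly_p(self, phantom_records_32):
        for p in (1, 2, 3):
            cfg = dataclasses.replace(TINY, disc_steps_per_gen=p, epochs=1)
            ckpt = train(cfg, phantom_records_32)
            assert ckpt.disc_updates == p * ckpt.gen_updates

    def test_fixed_seed_reproduces_weights(self, phantom_records_32):
        recs = [FusionRecord(r.structural, r.companion)
                for r in phantom_records_32]
        c1 = train(TINY, phantom_records_32)
        c2 = train(TINY, recs)
        for a, b in zip(c1.generator.state_arrays(), c2.generator.state_arrays()):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(c1.discriminator.state_arrays(),
                        c2.discriminator.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_empty_train_set_rejected(self):
        with pytest.raises(InvalidInputError):
            train(TINY, [])

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(batch_size=0)
        with pytest.raises(ConfigurationError):
            TrainConfig(split=(0.5, 0.2, 0.1))

    def test_batched_losses_match_module_functions(self, phantom_records_32):
        """The in-graph batched loss equals the per-image loss functions."""
        rec = phantom_records_32[0]
        m, i = rec.structural, rec.companion_gray
        maps = screening_maps(m, i)
        fused = np.clip(0.5 * m + 0.5 * i, 0, 1)
        ft = Tensor(fused[None, None])
        lp_batch = (maps.map1 * (ft - m) ** 2 + maps.map2 * (ft - i) ** 2).mean()
        assert lp_batch.item() == pytest.approx(
            pixel_loss(fused, m, i, maps), abs=1e-12
        )
        lf = _laplacian_tensor(ft, "4")
        from bpfuse.gradients import laplacian
        lg_batch = (maps.map1 * (lf - laplacian(m)) ** 2
                    + maps.map2 * (lf - laplacian(i)) ** 2).mean()
        assert lg_batch.item() == pytest.approx(
            gradient_loss(fused, m, i, maps), abs=1e-10
        )


class TestFusePair:
    def test_color_route_preserves_chroma(self, phantom_records_32):
        ckpt = train(TINY, phantom_records_32[:4])
        rec = phantom_records_32[0]
        out = fuse_pair(ckpt, rec.structural, rec.companion)
        assert out.shape == rec.companion.shape
        src = rgb_to_ycbcr(rec.companion)
        redone = rgb_to_ycbcr(out)
        in_gamut = np.all((out > 1e-9) & (out < 1 - 1e-9), axis=-1)
        np.testing.assert_allclose(redone.cb[in_gamut], src.cb[in_gamut],
                                   atol=1e-5)
        np.testing.assert_allclose(redone.cr[in_gamut], src.cr[in_gamut],
                                   atol=1e-5)

    def test_ct_route_is_grayscale(self, phantom_records_32, rng):
        ckpt = train(TINY, phantom_records_32[:4])
        ct = rng.random((32, 32))
        out = fuse_pair(ckpt, phantom_records_32[0].structural, ct)
        assert out.ndim == 2
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_same_checkpoint_same_output(self, phantom_records_32):
        ckpt = train(TINY, phantom_records_32[:4])
        rec = phantom_records_32[1]
        o1 = fuse_pair(ckpt, rec.structural, rec.companion)
        o2 = fuse_pair(ckpt, rec.structural, rec.companion)
        np.testing.assert_array_equal(o1, o2)

    def test_size_mismatch_rejected(self, phantom_records_32, rng):
        ckpt = train(TINY, phantom_records_32[:4])
        with pytest.raises(InvalidInputError):
            fuse_pair(ckpt, rng.random((32, 32)), rng.random((16, 16, 3)))


class TestCheckpointRoundTrip:
    def test_save_load_preserves_behaviour(self, phantom_records_32, tmp_path):
        ckpt = train(TINY, phantom_records_32[:4])
        path = tmp_path / "model.npz"
        ckpt.save(path)
        loaded = Checkpoint.load(path)
        rec = phantom_records_32[0]
        np.testing.assert_allclose(
            fuse_pair(loaded, rec.structural, rec.companion),
            fuse_pair(ckpt, rec.structural, rec.companion),
            atol=1e-12,
        )
        assert loaded.config == ckpt.config
        assert loaded.gen_updates == ckpt.gen_updates

    def test_loss_csv_export(self, phantom_records_32, tmp_path):
        ckpt = train(TINY, phantom_records_32[:4])
        csv_path = tmp_path / "log.csv"
        ckpt.write_loss_csv(csv_path)
        lines = csv_path.read_text().strip().splitlines()
        assert lines[0] == "step,l_gan,l_pixel,l_grad,l_total,l_d"
        assert len(lines) == len(ckpt.loss_log) + 1


class TestAblation:
    def test_module_grid_has_four_complete_rows(self, phantom_records_32):
        cfg = dataclasses.replace(TINY, epochs=1)
        table = run_ablation(cfg, phantom_records_32[:4],
                             phantom_records_32[4:6], grid="modules")
        assert len(table) == 4
        assert list(table["architecture"]) == [
            "backbone", "backbone+bpdb", "backbone+cbam", "backbone+bpdb+cbam"
        ]
        for col in ("ag", "ei", "q_abf", "q_cv"):
            assert np.isfinite(table[col]).all()

    def test_loss_grid_has_three_rows(self, phantom_records_32):
        cfg = dataclasses.replace(TINY, epochs=1)
        table = run_ablation(cfg, phantom_records_32[:4],
                             phantom_records_32[4:6], grid="losses")
        assert len(table) == 3

    def test_disabling_modules_preserves_shapes(self, phantom_records_32):
        flags = AblationFlags(use_bpdb=False, use_cbam=False)
        cfg = dataclasses.replace(TINY, epochs=1, ablation=flags)
        ckpt = train(cfg, phantom_records_32[:4])
        rec = phantom_records_32[0]
        assert fuse_pair(ckpt, rec.structural, rec.companion).shape == \
            rec.companion.shape


def test_evaluate_records_reports_per_pair(phantom_records_32):
    ckpt = train(TINY, phantom_records_32[:4])
    reports = evaluate_records(ckpt, phantom_records_32[4:6])
    assert len(reports) == 2
    for rep in reports:
        assert np.isfinite(list(rep.as_dict().values())).all()


def test_load_records_round_trip(tmp_path):
    from bpfuse.phantoms import PhantomSpec, make_dataset

    make_dataset(PhantomSpec(size=(32, 32), blob_sigma=3.0, seed=2), 3, tmp_path)
    records = load_records(tmp_path)
    assert len(records) == 3
    assert records[0].structural.shape == (32, 32)
    assert records[0].companion.shape == (32, 32, 3)
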