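import csv

import numpy as np
import pytest

import dosegan
from dosegan import nn
from dosegan.losses import LossWeights, discriminator_loss
from dosegan.phantom import generate_cohort
from dosegan.preprocess import ChannelStack, assemble_channel_stack
from dosegan.training import (
    TrainConfig,
    augment_sample,
    build_models,
    learning_rate_at,
    load_checkpoint,
    make_split,
    predict_dose,
    rotate_transverse,
    save_checkpoint,
    train_adversarial,
    write_loss_log,
)


def make_stacks(n=2, shape=32, scheme="B", seed=5):
    cases = generate_cohort(n, shape=(shape,) * 3, seed=seed)
    return [
        assemble_channel_stack(ct, st, dose, scheme) for ct, st, dose in cases
    ]


class TestSchedule:
    @pytest.mark.parametrize(
        "epoch,lr",
        [(0, 0.002), (100, 0.002), (200, 0.002), (350, 0.001), (500, 0.0)],
    )
    def test_plateau_then_linear_decay(self, epoch, lr):
        cfg = TrainConfig()
        assert learning_rate_at(epoch, cfg) == pytest.approx(lr)

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            learning_rate_at(501, TrainConfig())


class TestSplit:
    def test_cohort_of_118_gives_20_test_and_98_trainval(self):
        plan = make_split(list(range(118)), n_test=20, seed=3)
        assert len(plan.test_ids) == 20
        pool = set()
        for train, val in plan.folds:
            assert len(val) == 14  # 98 / 7
            assert len(train) == 84  # 6:1 train:validation
            assert not (set(train) & set(val))
            pool |= set(val)
        assert len(pool) == 98
        assert not (pool & set(plan.test_ids))

    def test_validation_folds_partition_the_pool(self):
        plan = make_split(list(range(118)), n_test=20, seed=9)
        vals = [frozenset(v) for _, v in plan.folds]
        assert sum(len(v) for v in vals) == 98
        assert len(frozenset().union(*vals)) == 98

    def test_same_seed_identical_plan(self):
        p1 = make_split(list(range(50)), 10, seed=11)
        p2 = make_split(list(range(50)), 10, seed=11)
        assert p1.test_ids == p2.test_ids and p1.folds == p2.folds


class TestAugmentation:
    def _stack(self, size=112):
        rng = np.random.default_rng(0)
        chans = rng.normal(size=(2, size, size, size)).astype(np.float32)
        chans[1] = (chans[1] > 0).astype(np.float32) * 2 - 1  # binary-ish mask channel
        return ChannelStack("C", chans, ("dose", "ct"), 5400.0)

    def test_emits_96_cubed_crops(self):
        out = augment_sample(self._stack(), seed=0, crop_size=96)
        assert out.channels.shape == (2, 96, 96, 96)

    def test_rotation_is_transverse_only_and_involutive(self, rng):
        vals = rng.normal(size=(1, 4, 6, 6))
        # 180-degree rotation applied twice restores the original
        np.testing.assert_array_equal(
            rotate_transverse(rotate_transverse(vals, 2), 2), vals
        )
        # slices permute only within themselves (transverse plane)
        rot = rotate_transverse(vals, 1)
        for z in range(4):
            assert set(rot[0, z].ravel()) == set(vals[0, z].ravel())

    def test_seed_reproducibility(self):
        s = self._stack(size=100)
        a = augment_sample(s, seed=123, crop_size=96)
        b = augment_sample(s, seed=123, crop_size=96)
        np.testing.assert_array_equal(a.channels, b.channels)

    def test_mask_channels_stay_binary(self, small_case):
        ct, st, dose = small_case
        stack = assemble_channel_stack(ct, st, dose, "B")
        out = augment_sample(stack, seed=1, crop_size=16)
        ptv = out.channels[2]
        assert set(np.unique(ptv)) <= set(np.unique(stack.channels[2]))

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            augment_sample(self._stack(size=64), seed=0, crop_size=96)


class TestTrainingLoop:
    def test_checkpoint_zero_equals_initialisation(self, tmp_path):
        stacks = make_stacks()
        cfg = TrainConfig(scheme="B", epochs=1, decay_start=1, batch_size=2,
                          crop_size=32, seed=2, width_mult=0.0625, augment=False,
                          checkpoint_dir=str(tmp_path))
        master = np.random.SeedSequence(cfg.seed)
        seed_g, seed_d = (int(s.generate_state(1)[0] % 2**31) for s in master.spawn(4)[:2])
        gen0, disc0 = build_models(cfg, seed_g, seed_d)
        init_params = [p.data.copy() for p in gen0.parameters()]
        train_adversarial(stacks, cfg)
        gen1, disc1 = build_models(cfg, 0, 0)
        load_checkpoint(tmp_path / "epoch_0000.npz", gen1, disc1)
        for p0, p1 in zip(init_params, gen1.parameters()):
            np.testing.assert_array_equal(p0, p1.data)

    def test_one_discriminator_step_reduces_its_loss(self):
        stacks = make_stacks()
        cfg = TrainConfig(scheme="B", epochs=0, batch_size=2, crop_size=32,
                          seed=2, width_mult=0.0625, augment=False, decay_start=0)
        gen, disc = build_models(cfg, 1, 2)
        real = np.stack([s.channels for s in stacks]).astype(np.float32)
        x = real[:, 1:]
        with nn.no_grad():
            fake = gen(x).data
        fake_in = np.concatenate([fake, x], axis=1)

        def d_loss():
            lr_ = disc(nn.Var(real, requires_grad=False))
            lf_ = disc(nn.Var(fake_in, requires_grad=False))
            return discriminator_loss(lr_, lf_)[2]

        opt = nn.Adam(disc.parameters(), lr=0.002, betas=(0.5, 0.999))
        before = float(d_loss().data)
        loss = d_loss()
        loss.backward()
        opt.step()
        after = float(d_loss().data)
        assert after < before

    def test_updates_do_not_leak_across_networks(self):
        # a discriminator update must leave generator weights untouched and
        # vice versa (checked by hashing the weight arrays around each step)
        stacks = make_stacks()
        cfg = TrainConfig(scheme="B", epochs=0, batch_size=2, crop_size=32,
                          seed=4, width_mult=0.0625, augment=False, decay_start=0)
        gen, disc = build_models(cfg, 5, 6)
        real = np.stack([s.channels for s in stacks]).astype(np.float32)
        x = real[:, 1:]

        def hashes(net):
            return [hash(p.data.tobytes()) for p in net.parameters()]

        opt_d = nn.Adam(disc.parameters(), lr=0.002, betas=(0.5, 0.999))
        opt_g = nn.Adam(gen.parameters(), lr=0.002, betas=(0.5, 0.999))

        g_before = hashes(gen)
        with nn.no_grad():
            fake = gen(x).data
        lr_ = disc(nn.Var(real, requires_grad=False))
        lf_ = disc(nn.Var(np.concatenate([fake, x], axis=1), requires_grad=False))
        discriminator_loss(lr_, lf_)[2].backward()
        opt_d.step()
        assert hashes(gen) == g_before  # D step leaves G untouched

        d_before = hashes(disc)
        opt_d.zero_grad()
        pred = gen(nn.Var(x, requires_grad=False))
        logits = disc(nn.concat([pred, nn.Var(x, requires_grad=False)], axis=1))
        from dosegan.losses import generator_adversarial_loss

        generator_adversarial_loss(logits).backward()
        opt_g.step()
        assert hashes(disc) == d_before  # G step leaves D untouched
        assert hashes(gen) != g_before  # and G itself did move

    def test_supervised_l1_decreases_over_first_epochs(self):
        # lambda_cGAN = 0 reduces training to L1+AVD regression; on a single
        # fixed batch the training L1 should fall monotonically early on
        stacks = make_stacks(n=2)
        cfg = TrainConfig(scheme="B", epochs=10, decay_start=10, batch_size=2,
                          crop_size=32, seed=6, width_mult=0.0625, augment=False,
                          loss_weights=LossWeights(0.0, 10.0, 100.0))
        _, _, history = train_adversarial(stacks, cfg)
        l1 = [h.g_l1 for h in history]
        assert all(b < a for a, b in zip(l1, l1[1:]))

    def test_loss_log_has_one_row_per_epoch(self, tmp_path):
        stacks = make_stacks()
        log = tmp_path / "losses.csv"
        cfg = TrainConfig(scheme="B", epochs=2, decay_start=2, batch_size=2,
                          crop_size=32, seed=2, width_mult=0.0625, augment=False,
                          log_csv=str(log))
        _, _, history = train_adversarial(stacks, cfg)
        with open(log) as fh:
            rows = list(csv.reader(fh))
        assert rows[0] == ["epoch", "d_gt", "d_pre", "d_total", "g_adv",
                           "g_avd", "g_l1", "g_total"]
        assert len(rows) == 1 + 2
        for rep, row in zip(history, rows[1:]):
            assert float(row[7]) == pytest.approx(rep.g_total)


class TestPrediction:
    def test_shape_range_and_determinism(self, small_case):
        ct, st, _ = small_case
        stack = assemble_channel_stack(ct, st, None, "B", prescription=5400.0)
        cfg = TrainConfig(scheme="B", width_mult=0.0625)
        gen, _ = build_models(cfg, 3, 4)
        d1 = predict_dose(gen, stack)
        d2 = predict_dose(gen, stack)
        assert d1.values.shape == ct.shape
        assert d1.values.min() >= 0.0
        assert d1.values.max() <= 1.2 * 5400.0
        np.testing.assert_array_equal(d1.values, d2.values)

    def test_checkpoint_round_trip(self, tmp_path, small_case):
        ct, st, _ = small_case
        stack = assemble_channel_stack(ct, st, None, "B", prescription=5400.0)
        cfg = TrainConfig(scheme="B", width_mult=0.0625)
        gen, disc = build_models(cfg, 3, 4)
        ref = predict_dose(gen, stack)
        save_checkpoint(tmp_path / "ck.npz", gen, disc, 7)
        gen2, disc2 = build_models(cfg, 99, 98)
        epoch = load_checkpoint(tmp_path / "ck.npz", gen2, disc2)
        assert epoch == 7
        out = predict_dose(gen2, stack)
        np.testing.assert_array_equal(ref.values, out.values)
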