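"""Training-loop checks: variant gating, update isolation, determinism,
supervised convergence, and scaled-down end-to-end recovery."""

import math

import numpy as np
import pytest
from dataclasses import replace

from lashgan.phantom import build_paired_dataset, build_unpaired_dataset, default_configs
from lashgan.trainer import (
    TrainConfig,
    VariantError,
    build_networks,
    fit,
    from_model,
    paired_batch,
    paired_step,
    set_global_seed,
    split_validation,
    to_model,
    unpaired_step,
)

TINY = dict(image_size=32, depth=4, base_channels=4, channel_cap=16,
            disc_base_channels=4, batch_size=2)


@pytest.fixture(scope="module")
def tiny_data():
    pc, ec = default_configs(32)
    paired = build_paired_dataset(8, pc, ec, 0)
    unpaired = build_unpaired_dataset(4, 4, pc, ec, 1)
    return paired, unpaired


def test_model_space_roundtrip(rng):
    img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
    x = to_model(img)
    assert x.shape == (3, 16, 16) and -1.0 <= x.min() and x.max() <= 1.0
    np.testing.assert_array_equal(from_model(x), img)


class TestSteps:
    def test_paired_step_updates_generator(self, tiny_data):
        paired, _ = tiny_data
        cfg = TrainConfig(variant="cgan_sub", rng_seed=0, **TINY)
        nets = build_networks(cfg)
        before = nets.g.param_hash()
        rep = paired_step(paired[:2], nets, cfg.weights)
        assert nets.g.param_hash() != before
        assert rep.l_l1 is not None and rep.l_l1 >= 0
        assert rep.l_uca is None and rep.d2_loss is None

    def test_paired_step_never_updates_discriminator_with_g_gradients(
            self, tiny_data):
        # freezing lr on D1 to zero isolates the bookkeeping: D1's parameters
        # must be bit-identical after the generator half of the step
        paired, _ = tiny_data
        cfg = TrainConfig(variant="cgan_sub", rng_seed=1, **TINY)
        nets = build_networks(cfg)
        nets.d1_opt.lr = 0.0
        before = nets.d1.param_hash()
        paired_step(paired[:2], nets, cfg.weights)
        assert nets.d1.param_hash() == before

    def test_unpaired_step_contract(self, tiny_data):
        paired, (u_cor, u_cln) = tiny_data
        cfg = TrainConfig(variant="full", rng_seed=2, **TINY)
        nets = build_networks(cfg)
        r_before = nets.r.param_hash()
        rep = unpaired_step(u_cor[:2], u_cln[:2], nets, cfg.weights)
        assert rep.l_l1 is None and rep.l_ref is None
        assert rep.l_uca is not None and rep.d2_loss is not None
        assert nets.r.param_hash() == r_before  # refiner bypassed

    def test_unpaired_step_rejected_without_unconditional_branch(self, tiny_data):
        _, (u_cor, u_cln) = tiny_data
        cfg = TrainConfig(variant="cgan_sub", rng_seed=0, **TINY)
        nets = build_networks(cfg)
        with pytest.raises(VariantError, match="cgan_sub"):
            unpaired_step(u_cor[:2], u_cln[:2], nets, cfg.weights)

    def test_d2_loss_near_ln2_at_initialization(self, tiny_data):
        """A freshly initialized discriminator is uninformative: its BCE sits
        near ln 2 (median over 10 seeds)."""
        _, (u_cor, u_cln) = tiny_data
        losses = []
        for seed in range(10):
            cfg = TrainConfig(variant="full", rng_seed=seed, **TINY)
            nets = build_networks(cfg)
            nets.g_opt.lr = nets.d2_opt.lr = 0.0
            rep = unpaired_step(u_cor[:2], u_cln[:2], nets, cfg.weights)
            losses.append(rep.d2_loss)
        assert abs(float(np.median(losses)) - math.log(2)) < 0.3

    def test_determinism_without_flips(self, tiny_data):
        paired, _ = tiny_data
        reports = []
        for _ in range(2):
            cfg = TrainConfig(variant="cgan_sub", rng_seed=3,
                              flip_probability=0.0, **TINY)
            nets = build_networks(cfg)
            reports.append(paired_step(paired[:2], nets, cfg.weights).as_dict())
        assert reports[0] == reports[1]

    def test_supervised_convergence_on_one_pair(self, tiny_data):
        """With adversarial feedback frozen (D1 learning rate 0), repeated
        steps on a single pair drive the L1 term below 0.05."""
        paired, _ = tiny_data
        cfg = TrainConfig(variant="cgan_sub", rng_seed=4, noise_mode="none",
                          learning_rate=5e-3, **TINY)
        nets = build_networks(cfg)
        nets.d1_opt.lr = 0.0
        batch = paired_batch(paired[:1])
        l1 = None
        for _ in range(400):
            l1 = paired_step(batch, nets, cfg.weights).l_l1
        assert l1 < 0.05


class TestFit:
    def test_history_and_variant_gating(self, tiny_data):
        paired, unpaired = tiny_data
        cfg = TrainConfig(variant="cgan_ref", epochs=2, rng_seed=5, **TINY)
        nets, hist = fit(paired, None, cfg)
        assert len(hist) == 2
        assert len(hist.val_psnr) == 2
        assert nets.d2 is None  # no unconditional branch in cgan_ref
        assert nets.r is not None

    def test_refiner_untouched_in_cgan_sub(self, tiny_data):
        paired, _ = tiny_data
        cfg = TrainConfig(variant="cgan_sub", epochs=1, rng_seed=6, **TINY)
        nets, _ = fit(paired, None, cfg)
        assert nets.r is None

    def test_equal_seeds_reproduce_history(self, tiny_data):
        paired, unpaired = tiny_data
        runs = []
        for _ in range(2):
            cfg = TrainConfig(variant="full", epochs=1, rng_seed=7, **TINY)
            _, hist = fit(paired, unpaired, cfg)
            runs.append(hist.epoch_losses[0])
        assert runs[0] == runs[1]

    def test_different_seeds_differ(self, tiny_data):
        paired, _ = tiny_data
        hashes = []
        for seed in (0, 1):
            cfg = TrainConfig(variant="cgan_sub", epochs=1, rng_seed=seed, **TINY)
            nets, _ = fit(paired, None, cfg)
            hashes.append(nets.g.param_hash())
        assert hashes[0] != hashes[1]

    def test_empty_required_dataset_rejected(self, tiny_data):
        paired, _ = tiny_data
        cfg = TrainConfig(variant="full", epochs=1, rng_seed=0, **TINY)
        with pytest.raises(ValueError, match="unpaired"):
            fit(paired, None, cfg)
        with pytest.raises(ValueError, match="paired"):
            fit([], None, replace(cfg, variant="cgan_sub"))

    def test_validation_split_is_deterministic(self, tiny_data):
        paired, _ = tiny_data
        cfg = TrainConfig(variant="cgan_sub", rng_seed=9, **TINY)
        t1, v1 = split_validation(paired, cfg)
        t2, v2 = split_validation(paired, cfg)
        assert [s.sample_id for s in v1] == [s.sample_id for s in v2]
        assert len(v1) >= 1
        assert {s.sample_id for s in t1}.isdisjoint({s.sample_id for s in v1})


def test_set_global_seed_controls_legacy_stream():
    set_global_seed(11)
    a = np.random.random(4)
    set_global_seed(11)
    np.testing.assert_array_equal(a, np.random.random(4))
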