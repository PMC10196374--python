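"""Joint adversarial training of the restoration model.

One shared generator ``G`` is trained from two directions at once: paired
steps show it pixel-aligned corrupted/clean pairs (conditional discriminator
``D1``, L1 generation loss, and the refiner ``R`` with its L1 refinement
loss), while unpaired steps expose it to corrupted images and clean images
drawn from disjoint pools (unconditional discriminator ``D2``).  Paired and
unpaired steps alternate at a configurable ratio.

Four ablation variants gate which sub-networks and loss terms are active:

========== ==================== =============================
variant     networks             generator losses
========== ==================== =============================
cgan_sub    G, D1                adversarial (cond.) + L1
cgan_ref    G, R, D1             + refinement L1
cgan_gan    G, D1, D2            + adversarial (uncond.)
full        G, R, D1, D2         all four terms
========== ==================== =============================

The refiner is updated only in paired steps, because its loss is defined on
paired references; unpaired steps bypass it entirely.  Discriminator and
generator updates are strictly separated: gradients that a generator update
pushes through a discriminator are discarded before that discriminator's own
next update.

Optimization follows the conditional-GAN convention: Adam with learning rate
2e-4 and betas (0.5, 0.999), random horizontal flipping for augmentation, and
the loss weights lambda1 = 100, lambda2 = 10.  Defaults here are desk-scale
(64x64 phantoms, base_channels 8, batch 4); ``full_scale_config`` returns
the full-scale regime (1024x1024, 8 encoder stages, base 64, batch 15,
200 epochs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .losses import (
    LossReport,
    LossWeights,
    discriminator_loss,
    discriminator_loss_grads,
    generator_adversarial_grad,
    generator_adversarial_loss,
    l1_generation_loss,
    l1_grad,
    refinement_loss,
    total_generator_loss,
)
from .metrics import psnr, ssim
from .nets import (
    DiscriminatorSpec,
    GeneratorSpec,
    PatchDiscriminator,
    UNet,
    build_discriminator,
    build_generator,
    build_refiner,
    forward_restore,
)
from .nn import Adam
from .phantom import PairedSample, derive_seed

logger = logging.getLogger(__name__)

VARIANTS = ("cgan_sub", "cgan_ref", "cgan_gan", "full")


class VariantError(RuntimeError):
    """An operation is not permitted under the active ablation variant."""


@dataclass
class TrainConfig:
    """Training hyper-parameters and ablation variant selection."""

    epochs: int = 20
    learning_rate: float = 2e-4
    batch_size: int = 4
    flip_probability: float = 0.5
    alternation_ratio: tuple[int, int] = (1, 1)   # paired : unpaired per cycle
    variant: str = "full"
    weights: LossWeights = field(default_factory=LossWeights)
    rng_seed: int = 0
    image_size: int = 64
    depth: int | None = None          # None: min(8, log2(image_size))
    base_channels: int = 8
    channel_cap: int = 512
    disc_base_channels: int = 8
    noise_mode: str = "dropout"
    saturating: bool = False
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    @property
    def net_depth(self) -> int:
        if self.depth is not None:
            return self.depth
        return min(8, int(np.log2(self.image_size)))

    @property
    def uses_refiner(self) -> bool:
        return self.variant in ("cgan_ref", "full")

    @property
    def uses_unpaired(self) -> bool:
        return self.variant in ("cgan_gan", "full")

    def generator_spec(self) -> GeneratorSpec:
        return GeneratorSpec(depth=self.net_depth,
                             base_channels=self.base_channels,
                             channel_cap=self.channel_cap,
                             noise_mode=self.noise_mode)


def full_scale_config(**overrides) -> TrainConfig:
    """The full-scale training regime (1024x1024 patches, batch 15, 200 epochs)."""
    cfg = TrainConfig(epochs=200, batch_size=15, image_size=1024, depth=8,
                      base_channels=64, channel_cap=512, disc_base_channels=64)
    return replace(cfg, **overrides)


@dataclass
class NetBundle:
    """The trainable networks of one variant, with their optimizers."""

    variant: str
    g: UNet
    d1: PatchDiscriminator
    r: UNet | None = None
    d2: PatchDiscriminator | None = None
    g_opt: Adam | None = None
    r_opt: Adam | None = None
    d1_opt: Adam | None = None
    d2_opt: Adam | None = None


@dataclass
class History:
    """Per-epoch aggregates of one training run."""

    epoch_losses: list[dict] = field(default_factory=list)
    val_psnr: list[float] = field(default_factory=list)
    val_ssim: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_psnr: float = -np.inf
    seed: int = 0

    def __len__(self) -> int:
        return len(self.epoch_losses)


def set_global_seed(seed: int) -> np.random.Generator:
    """Seed the legacy global numpy stream and return a fresh Generator.

    All internal randomness (initialization, data order, augmentation,
    dropout) is derived from explicit seeds, so this mainly guards against
    stray ``np.random`` calls in user code.
    """
    np.random.seed(seed % (2 ** 32))
    return np.random.default_rng(seed)


def build_networks(config: TrainConfig) -> NetBundle:
    """Instantiate the sub-networks the variant needs, with derived seeds."""
    gspec = config.generator_spec()
    g = build_generator(gspec, seed=derive_seed(config.rng_seed, 10))
    d1 = build_discriminator(
        DiscriminatorSpec(conditional=True, base_channels=config.disc_base_channels),
        seed=derive_seed(config.rng_seed, 12))
    bundle = NetBundle(variant=config.variant, g=g, d1=d1)
    if config.uses_refiner:
        bundle.r = build_refiner(gspec, seed=derive_seed(config.rng_seed, 11))
    if config.uses_unpaired:
        bundle.d2 = build_discriminator(
            DiscriminatorSpec(conditional=False,
                              base_channels=config.disc_base_channels),
            seed=derive_seed(config.rng_seed, 13))
    lr = config.learning_rate
    bundle.g_opt = Adam(g.parameters(), lr=lr)
    bundle.d1_opt = Adam(d1.parameters(), lr=lr)
    if bundle.r is not None:
        bundle.r_opt = Adam(bundle.r.parameters(), lr=lr)
    if bundle.d2 is not None:
        bundle.d2_opt = Adam(bundle.d2.parameters(), lr=lr)
    return bundle


# --- data plumbing -----------------------------------------------------------

def to_model(img: np.ndarray) -> np.ndarray:
    """uint8 HWC [0,255] -> float32 CHW [-1,1]."""
    return (img.astype(np.float32) / 127.5 - 1.0).transpose(2, 0, 1)


def from_model(x: np.ndarray) -> np.ndarray:
    """float32 CHW [-1,1] -> uint8 HWC [0,255]."""
    return np.clip(np.rint((x.transpose(1, 2, 0) + 1.0) * 127.5),
                   0, 255).astype(np.uint8)


def paired_batch(samples: list[PairedSample],
                 flips: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Stack paired samples into normalized (corrupted, clean) NCHW batches.

    ``flips`` is a boolean mask applying horizontal flips identically to both
    images of a pair.
    """
    xs, ys = [], []
    for i, s in enumerate(samples):
        cor, cln = s.corrupted, s.clean
        if flips is not None and flips[i]:
            cor, cln = cor[:, ::-1], cln[:, ::-1]
        xs.append(to_model(cor))
        ys.append(to_model(cln))
    return np.stack(xs), np.stack(ys)


def _discriminator_update(d, d_opt, real_in, fake_in):
    d_opt.zero_grad()
    real_map = d.forward(real_in, train=True)
    g_real, _ = discriminator_loss_grads(real_map, real_map)
    d.backward(g_real)
    fake_map = d.forward(fake_in, train=True)
    _, g_fake = discriminator_loss_grads(fake_map, fake_map)
    d.backward(g_fake)
    loss = discriminator_loss(real_map, fake_map)
    d_opt.step()
    return loss, real_map, fake_map


def _zero_params(net) -> None:
    for p in net.parameters():
        p.zero_grad()


def paired_step(batch, nets: NetBundle, w: LossWeights,
                saturating: bool = False) -> LossReport:
    """One optimization step on a paired batch.

    Updates ``D1`` on real/fake pairs, then ``G`` (and ``R`` when active)
    on the conditional adversarial term + lambda1 * L1 (+ lambda2 *
    refinement L1).  ``batch`` is either a list of :class:`PairedSample` or a
    pre-normalized ``(x, y)`` NCHW pair.
    """
    if isinstance(batch, (list, tuple)) and batch and isinstance(batch[0], PairedSample):
        x, y = paired_batch(list(batch))
    else:
        x, y = batch

    g, r, d1 = nets.g, (nets.r if nets.variant in ("cgan_ref", "full") else None), nets.d1

    fake = g.forward(x, train=True)
    refined = r.forward(fake, train=True) if r is not None else None

    d1_loss, _, _ = _discriminator_update(
        d1, nets.d1_opt,
        np.concatenate([x, y], axis=1),
        np.concatenate([x, fake], axis=1))

    # generator (and refiner) update
    nets.g_opt.zero_grad()
    if nets.r_opt is not None:
        nets.r_opt.zero_grad()
    fake_map = d1.forward(np.concatenate([x, fake], axis=1), train=True)
    l_ca = generator_adversarial_loss(fake_map, saturating)
    gin = d1.backward(generator_adversarial_grad(fake_map, saturating))
    grad_fake = gin[:, x.shape[1]:].copy()
    _zero_params(d1)  # generator gradients must never update the discriminator

    l_l1 = l1_generation_loss(fake, y)
    grad_fake += w.lambda1 * l1_grad(fake, y)

    l_ref = None
    if r is not None:
        l_ref = refinement_loss(refined, y)
        grad_fake += r.backward(w.lambda2 * l1_grad(refined, y))
    g.backward(grad_fake)

    report = LossReport(l_ca=l_ca, l_l1=l_l1, l_ref=l_ref, d1_loss=d1_loss)
    report.total = total_generator_loss(report, w)
    report.check_finite()

    nets.g_opt.step()
    if r is not None:
        nets.r_opt.step()
    return report


def unpaired_step(corrupted_batch, clean_batch, nets: NetBundle,
                  w: LossWeights, saturating: bool = False) -> LossReport:
    """One optimization step on unpaired pools (D2 and G only).

    The refiner and the paired losses are not touched; the two batches must
    come from disjoint pools.  Raises :class:`VariantError` for variants
    without the unconditional branch.
    """
    if nets.variant not in ("cgan_gan", "full") or nets.d2 is None:
        raise VariantError(
            f"variant {nets.variant!r} has no unconditional branch; "
            "unpaired_step is not available")
    xu = corrupted_batch if isinstance(corrupted_batch, np.ndarray) \
        else np.stack([to_model(s.corrupted) for s in corrupted_batch])
    yu = clean_batch if isinstance(clean_batch, np.ndarray) \
        else np.stack([to_model(img) for img in clean_batch])

    g, d2 = nets.g, nets.d2
    fake = g.forward(xu, train=True)

    d2_loss, _, _ = _discriminator_update(d2, nets.d2_opt, yu, fake)

    nets.g_opt.zero_grad()
    fake_map = d2.forward(fake, train=True)
    l_uca = generator_adversarial_loss(fake_map, saturating)
    gin = d2.backward(generator_adversarial_grad(fake_map, saturating))
    _zero_params(d2)
    g.backward(gin)

    report = LossReport(l_uca=l_uca, d2_loss=d2_loss)
    report.total = total_generator_loss(report, w)
    report.check_finite()

    nets.g_opt.step()
    return report


def _aggregate(reports: list[LossReport]) -> dict:
    out: dict = {}
    for key in LossReport.FIELDS:
        vals = [getattr(rep, key) for rep in reports
                if getattr(rep, key) is not None]
        out[key] = float(np.mean(vals)) if vals else None
    return out


def evaluate_restoration(nets: NetBundle, samples: list[PairedSample]
                         ) -> tuple[float, float, float]:
    """Mean (PSNR restored, SSIM restored, PSNR corrupted) on held-out pairs."""
    r = nets.r if nets.variant in ("cgan_ref", "full") else None
    ps, ss, pc = [], [], []
    for s in samples:
        x = to_model(s.corrupted)[None]
        restored = from_model(forward_restore(nets.g, r, x)[0])
        ps.append(min(psnr(restored, s.clean), 99.0))
        ss.append(ssim(restored, s.clean))
        pc.append(min(psnr(s.corrupted, s.clean), 99.0))
    return float(np.mean(ps)), float(np.mean(ss)), float(np.mean(pc))


def split_validation(paired: list[PairedSample], config: TrainConfig
                     ) -> tuple[list[PairedSample], list[PairedSample]]:
    """Deterministic train/validation split of the paired set."""
    rng = np.random.default_rng(derive_seed(config.rng_seed, 20))
    idx = rng.permutation(len(paired))
    n_val = max(1, int(round(config.val_fraction * len(paired)))) \
        if len(paired) > 1 else 0
    val = [paired[i] for i in idx[:n_val]]
    train = [paired[i] for i in idx[n_val:]]
    return train, val


def fit(paired: list[PairedSample],
        unpaired: tuple[list[PairedSample], list[np.ndarray]] | None,
        config: TrainConfig) -> tuple[NetBundle, History]:
    """Train the configured variant end-to-end.

    Paired and unpaired steps are interleaved per ``alternation_ratio`` with
    per-epoch seeded shuffling; validation PSNR/SSIM are recorded each epoch
    on a held-out paired split, and the parameters achieving the best
    validation PSNR are restored into the returned bundle.
    """
    if not paired:
        raise ValueError("paired dataset must be non-empty")
    if config.uses_unpaired and (unpaired is None or not unpaired[0] or not unpaired[1]):
        raise ValueError(
            f"variant {config.variant!r} requires non-empty unpaired pools")

    set_global_seed(config.rng_seed)
    nets = build_networks(config)
    train_set, val_set = split_validation(paired, config)
    if not train_set:
        train_set, val_set = list(paired), list(paired)

    history = History(seed=config.rng_seed)
    best_state: dict | None = None
    n_paired_steps, n_unpaired_steps = config.alternation_ratio

    for epoch in range(config.epochs):
        erng = np.random.default_rng(derive_seed(config.rng_seed, 30, epoch))
        order = erng.permutation(len(train_set))
        if config.uses_unpaired:
            u_cor, u_cln = unpaired
            uc_order = erng.permutation(len(u_cor))
            ul_order = erng.permutation(len(u_cln))
            uc_pos = ul_pos = 0
        reports: list[LossReport] = []

        bs = config.batch_size
        batches = [order[i:i + bs] for i in range(0, len(order), bs)]
        pending_unpaired = 0
        for bi, batch_idx in enumerate(batches):
            samples = [train_set[i] for i in batch_idx]
            flips = erng.random(len(samples)) < config.flip_probability
            x, y = paired_batch(samples, flips)
            reports.append(paired_step((x, y), nets, config.weights,
                                       config.saturating))

            if config.uses_unpaired and (bi + 1) % max(n_paired_steps, 1) == 0:
                pending_unpaired += n_unpaired_steps
            while config.uses_unpaired and pending_unpaired > 0:
                pending_unpaired -= 1
                xi = [u_cor[uc_order[(uc_pos + k) % len(u_cor)]]
                      for k in range(bs)]
                yi = [u_cln[ul_order[(ul_pos + k) % len(u_cln)]]
                      for k in range(bs)]
                uc_pos += bs
                ul_pos += bs
                reports.append(unpaired_step(xi, yi, nets, config.weights,
                                             config.saturating))

        history.epoch_losses.append(_aggregate(reports))
        if val_set:
            vp, vs, _ = evaluate_restoration(nets, val_set)
        else:  # pragma: no cover - only for 1-sample datasets
            vp, vs = np.nan, np.nan
        history.val_psnr.append(vp)
        history.val_ssim.append(vs)
        logger.info("epoch %d/%d: val PSNR %.2f dB, SSIM %.4f, G total %.4f",
                    epoch + 1, config.epochs, vp, vs,
                    history.epoch_losses[-1].get("total") or np.nan)
        if vp > history.best_val_psnr:
            history.best_val_psnr = vp
            history.best_epoch = epoch
            best_state = {
                name: [a.copy() for a in net.state_arrays()]
                for name, net in _named_nets(nets).items()}

    if best_state is not None:
        for name, net in _named_nets(nets).items():
            net.load_state_arrays(best_state[name])
    return nets, history


def _named_nets(nets: NetBundle) -> dict:
    out = {"g": nets.g, "d1": nets.d1}
    if nets.r is not None:
        out["r"] = nets.r
    if nets.d2 is not None:
        out["d2"] = nets.d2
    return out


__all__ = [
    "History",
    "NetBundle",
    "TrainConfig",
    "VARIANTS",
    "VariantError",
    "build_networks",
    "evaluate_restoration",
    "fit",
    "from_model",
    "paired_batch",
    "paired_step",
    "full_scale_config",
    "set_global_seed",
    "split_validation",
    "to_model",
    "unpaired_step",
]
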