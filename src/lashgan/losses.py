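"""Adversarial and reconstruction losses for joint paired/unpaired training.

Four terms drive the generator ``G`` and refiner ``R``:

* a conditional adversarial term, where ``D1`` scores (input, candidate)
  pairs from the paired pool,
* an L1 generation term between ``G``'s output and the clean reference,
* an unconditional adversarial term, where ``D2`` scores single images from
  the unpaired pool,
* an L1 refinement term between ``R(G(x))`` and the clean reference.

The weighted total is ``L_ca + lambda1 * L1 + L_uca + lambda2 * L_ref`` with
lambda1 = 100 and lambda2 = 10 by default.  All losses are means over map
elements, pixels, channels and batch, so the weights are scale-free across
image and map sizes.

Discriminator losses are the usual binary cross-entropy pushing real
confidence maps toward 1 and fake ones toward 0, averaged over the two
halves, so an uninformative discriminator (everything 0.5) sits exactly at
ln 2.  The generator by default minimizes the non-saturating surrogate
``-log D(fake)``; ``saturating=True`` restores the literal minimax form
``log(1 - D(fake))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-12


class LossDomainError(ValueError):
    """Confidence map values outside (0, 1)."""


@dataclass(frozen=True)
class LossWeights:
    """Weights of the L1 generation term and the refinement term."""

    lambda1: float = 100.0
    lambda2: float = 10.0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossReport:
    """Named scalar loss components of one training step.

    ``None`` marks a component that the step does not evaluate (e.g. L1 and
    refinement terms are undefined on unpaired steps).
    """

    l_ca: float | None = None       # generator's conditional adversarial term
    l_l1: float | None = None       # L1 between G(x) and the clean reference
    l_uca: float | None = None      # generator's unconditional adversarial term
    l_ref: float | None = None      # L1 between R(G(x)) and the clean reference
    d1_loss: float | None = None
    d2_loss: float | None = None
    total: float | None = None

    FIELDS = ("l_ca", "l_l1", "l_uca", "l_ref", "d1_loss", "d2_loss", "total")

    def as_dict(self) -> dict[str, float | None]:
        return {k: getattr(self, k) for k in self.FIELDS}

    def check_finite(self) -> None:
        for k in self.FIELDS:
            v = getattr(self, k)
            if v is not None and not np.isfinite(v):
                raise FloatingPointError(f"non-finite loss component {k!r}: {v}")


def _check_map(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    if m.size and (m.min() <= 0.0 or m.max() >= 1.0):
        raise LossDomainError(
            f"{name} must lie strictly in (0, 1); got range "
            f"[{m.min():.3g}, {m.max():.3g}]")
    return m


def _bce_real(m: np.ndarray) -> float:
    return float(-np.log(m + _EPS).mean())


def _bce_fake(m: np.ndarray) -> float:
    return float(-np.log1p(-m + _EPS).mean())


def discriminator_loss(real_map: np.ndarray, fake_map: np.ndarray) -> float:
    """Mean BCE pushing real maps to 1 and fake maps to 0 (average of halves)."""
    real = _check_map(real_map, "real_map")
    fake = _check_map(fake_map, "fake_map")
    return 0.5 * (_bce_real(real) + _bce_fake(fake))


def generator_adversarial_loss(fake_map: np.ndarray, saturating: bool = False) -> float:
    """Generator's adversarial term from the discriminator's fake-map scores."""
    fake = _check_map(fake_map, "fake_map")
    if saturating:
        return float(np.log1p(-fake + _EPS).mean())
    return _bce_real(fake)


def conditional_adversarial_terms(
    d1_real_map: np.ndarray, d1_fake_map: np.ndarray, saturating: bool = False
) -> tuple[float, float]:
    """(D1 loss, generator's conditional adversarial loss)."""
    return (discriminator_loss(d1_real_map, d1_fake_map),
            generator_adversarial_loss(d1_fake_map, saturating))


def unconditional_adversarial_terms(
    d2_real_map: np.ndarray, d2_fake_map: np.ndarray, saturating: bool = False
) -> tuple[float, float]:
    """(D2 loss, generator's unconditional adversarial loss)."""
    return (discriminator_loss(d2_real_map, d2_fake_map),
            generator_adversarial_loss(d2_fake_map, saturating))


def l1_generation_loss(generated: np.ndarray, reference: np.ndarray) -> float:
    """Mean absolute difference over pixels, channels and batch ([-1,1] space)."""
    generated = np.asarray(generated)
    reference = np.asarray(reference)
    if generated.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: {generated.shape} vs {reference.shape}")
    return float(np.abs(generated.astype(np.float64)
                        - reference.astype(np.float64)).mean())


def refinement_loss(refined: np.ndarray, reference: np.ndarray) -> float:
    """L1 distance between the refiner's output and the clean reference."""
    return l1_generation_loss(refined, reference)


def total_generator_loss(components: LossReport, w: LossWeights) -> float:
    """Weighted total of the generator-side terms; absent terms contribute 0."""
    components.check_finite()
    total = 0.0
    if components.l_ca is not None:
        total += components.l_ca
    if components.l_l1 is not None:
        total += w.lambda1 * components.l_l1
    if components.l_uca is not None:
        total += components.l_uca
    if components.l_ref is not None:
        total += w.lambda2 * components.l_ref
    return total


# --- gradients (used by the trainer) -----------------------------------------

def discriminator_loss_grads(
    real_map: np.ndarray, fake_map: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of :func:`discriminator_loss` w.r.t. the two maps."""
    n_r, n_f = real_map.size, fake_map.size
    g_real = -0.5 / (real_map + _EPS) / n_r
    g_fake = 0.5 / (1.0 - fake_map + _EPS) / n_f
    return g_real.astype(np.float32), g_fake.astype(np.float32)


def generator_adversarial_grad(
    fake_map: np.ndarray, saturating: bool = False
) -> np.ndarray:
    """Gradient of :func:`generator_adversarial_loss` w.r.t. the fake map."""
    n = fake_map.size
    if saturating:
        g = -1.0 / (1.0 - fake_map + _EPS) / n
    else:
        g = -1.0 / (fake_map + _EPS) / n
    return g.astype(np.float32)


def l1_grad(generated: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Gradient of the mean-absolute difference w.r.t. ``generated``."""
    return (np.sign(generated - reference) / generated.size).astype(np.float32)


__all__ = [
    "LossDomainError",
    "LossReport",
    "LossWeights",
    "conditional_adversarial_terms",
    "discriminator_loss",
    "discriminator_loss_grads",
    "generator_adversarial_grad",
    "generator_adversarial_loss",
    "l1_generation_loss",
    "l1_grad",
    "refinement_loss",
    "total_generator_loss",
    "unconditional_adversarial_terms",
]
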