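"""Synthetic fundus phantoms and eyelash artifacts.

Ultra-wide-field (UWF) fundus photographs show a bright elliptical field of
view on a dark surround, a warm orange background with a radial intensity
falloff, and a branching tree of dark retinal vessels.  Eyelash artifacts are
dark, curved, semi-transparent strokes entering the frame from the image
borders (eyelashes hang from the superior and inferior eyelids).

This module generates such scenes from scratch so that the whole restoration
pipeline — paired supervised training, unpaired adversarial training, and
region-based evaluation — can run without any patient data.  Every operation
is a pure function of its configuration and seed, paired samples carry exact
artifact masks, and corrupted images are bitwise-identical to their clean
counterparts wherever the artifact alpha is zero.

The stroke model is an original stand-in: quadratic Bezier curves rooted on a
border, pointing inward, with tapering width, per-stroke opacity, optional
Gaussian blur and a faint wide halo.  It aims for visual plausibility, not
for reproducing any particular eyelash-growth simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

MASK_THRESHOLD = 0.05  # alpha above this counts as artifact support


class PhantomConfigError(ValueError):
    """A configuration field violates its invariant."""


# --- configurations ----------------------------------------------------------

@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and appearance of a clean fundus phantom.

    Defaults target the 256x256 desk scale; ``scaled_to`` rescales all pixel
    quantities for other sizes (e.g. 1024 to match full training patches).
    """

    image_size: int = 256
    fov_axes: tuple[float, float] = (118.0, 103.0)  # semi-axes, pixels
    background_base_color: tuple[float, float, float] = (192.0, 112.0, 58.0)
    background_gradient_strength: float = 0.35      # fraction of falloff at rim
    vessel_root_count: int = 6
    branch_depth: int = 4
    vessel_width_root: float = 6.0
    vessel_width_decay: float = 0.7
    vessel_darkening: float = 0.55
    texture_noise_sigma: float = 4.0                # 8-bit intensity units
    rng_seed: int = 0

    def validate(self, downsampling_factor: int | None = None) -> None:
        if self.image_size < 8:
            raise PhantomConfigError("image_size too small")
        if downsampling_factor is not None and self.image_size % downsampling_factor:
            raise PhantomConfigError(
                f"image_size={self.image_size} not divisible by the network "
                f"downsampling factor {downsampling_factor}")
        if max(self.fov_axes) > self.image_size / 2:
            raise PhantomConfigError("fov_axes must be <= image_size/2")
        if not (0 < self.vessel_width_decay < 1):
            raise PhantomConfigError("vessel_width_decay must lie in (0, 1)")
        if not (0 < self.vessel_darkening < 1):
            raise PhantomConfigError("vessel_darkening must lie in (0, 1)")
        if self.branch_depth < 1:
            raise PhantomConfigError("branch_depth must be >= 1")
        if self.vessel_root_count < 0:
            raise PhantomConfigError("vessel_root_count must be >= 0")

    def scaled_to(self, image_size: int) -> "PhantomConfig":
        f = image_size / self.image_size
        return replace(
            self,
            image_size=image_size,
            fov_axes=(self.fov_axes[0] * f, self.fov_axes[1] * f),
            vessel_width_root=self.vessel_width_root * f,
        )


@dataclass(frozen=True)
class EyelashConfig:
    """Stochastic eyelash-stroke population for one corrupted image.

    Strokes root on the top/bottom borders with high probability (superior and
    inferior eyelids); lengths and widths are in pixels at the configured
    image scale; ``curvature_range`` bends the quadratic Bezier by that
    fraction of the stroke length.
    """

    stroke_count_range: tuple[int, int] = (15, 35)
    root_edge_weights: tuple[float, float, float, float] = (0.45, 0.45, 0.05, 0.05)
    length_range: tuple[float, float] = (130.0, 290.0)
    curvature_range: tuple[float, float] = (0.04, 0.22)
    width_root_range: tuple[float, float] = (4.0, 9.0)
    width_taper: float = 0.3                 # tip width = root width * taper
    opacity_range: tuple[float, float] = (0.6, 0.95)
    shade_color: tuple[float, float, float] = (16.0, 10.0, 10.0)
    blur_sigma: float = 1.0
    halo_opacity: float = 0.12
    mask_threshold: float = MASK_THRESHOLD
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("stroke_count_range", "length_range", "curvature_range",
                     "width_root_range", "opacity_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise PhantomConfigError(f"{name} is empty: ({lo}, {hi})")
        if self.stroke_count_range[0] < 0:
            raise PhantomConfigError("stroke_count_range must be non-negative")
        if not (0 < self.width_taper <= 1):
            raise PhantomConfigError("width_taper must lie in (0, 1]")

    def scaled_to(self, factor: float) -> "EyelashConfig":
        return replace(
            self,
            length_range=(self.length_range[0] * factor, self.length_range[1] * factor),
            width_root_range=(self.width_root_range[0] * factor,
                              self.width_root_range[1] * factor),
            blur_sigma=self.blur_sigma * factor,
        )


@dataclass(frozen=True)
class Stroke:
    """One eyelash stroke: a quadratic Bezier with tapering width."""

    control_points: np.ndarray  # (3, 2) array of (x, y), root first
    width_root: float
    width_taper: float
    opacity: float

    def point(self, t: np.ndarray) -> np.ndarray:
        """Bezier point(s) at parameter t in [0, 1]; returns (..., 2)."""
        p0, p1, p2 = self.control_points
        t = np.asarray(t)[..., None]
        return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2

    def width(self, t: np.ndarray) -> np.ndarray:
        return self.width_root * (1.0 - (1.0 - self.width_taper) * np.asarray(t))

    def arc_length(self, n: int = 256) -> float:
        pts = self.point(np.linspace(0.0, 1.0, n))
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


@dataclass(frozen=True)
class PairedSample:
    """Corrupted/clean image pair with the exact artifact mask."""

    corrupted: np.ndarray   # (H, W, 3) uint8
    clean: np.ndarray       # (H, W, 3) uint8
    mask: np.ndarray        # (H, W) bool
    sample_id: str
    phantom_seed: int = 0


# --- clean phantom -----------------------------------------------------------

def _fov_ellipse(size: int, axes: tuple[float, float]) -> np.ndarray:
    c = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size]
    return ((x - c) / axes[0]) ** 2 + ((y - c) / axes[1]) ** 2  # <=1 inside


def _draw_segment(alpha: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                  width: float) -> None:
    """Union a hard-edged thick segment into ``alpha`` (max-accumulate)."""
    size = alpha.shape[0]
    r = width / 2.0
    lo = np.floor(np.minimum(p0, p1) - r - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + r + 2).astype(int)
    x0, y0 = np.clip(lo, 0, size)
    x1, y1 = np.clip(hi, 0, size)
    if x1 <= x0 or y1 <= y0:
        return
    y, x = np.mgrid[y0:y1, x0:x1]
    d = np.stack([x - p0[0], y - p0[1]], axis=-1).astype(np.float64)
    v = p1 - p0
    vv = float(v @ v)
    t = np.clip((d @ v) / vv, 0.0, 1.0) if vv > 0 else np.zeros(d.shape[:2])
    dist = np.linalg.norm(d - t[..., None] * v, axis=-1)
    np.maximum(alpha[y0:y1, x0:x1], (dist <= r).astype(alpha.dtype),
               out=alpha[y0:y1, x0:x1])


def _grow_vessel_tree(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Recursive binary branching from roots on the FOV rim, pointing inward."""
    size = cfg.image_size
    alpha = np.zeros((size, size), dtype=np.float64)
    c = (size - 1) / 2.0
    ax, ay = cfg.fov_axes
    base_len = 0.30 * min(ax, ay)

    def grow(p: np.ndarray, direction: float, level: int) -> None:
        if level >= cfg.branch_depth:
            return
        width = cfg.vessel_width_root * cfg.vessel_width_decay ** level
        length = base_len * 0.82 ** level * rng.uniform(0.8, 1.2)
        q = p + length * np.array([np.cos(direction), np.sin(direction)])
        _draw_segment(alpha, p, q, width)
        for sign in (-1.0, 1.0):
            turn = sign * rng.uniform(0.3, 0.7)
            grow(q, direction + turn, level + 1)

    for _ in range(cfg.vessel_root_count):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        root = np.array([c + 0.92 * ax * np.cos(theta),
                         c + 0.92 * ay * np.sin(theta)])
        inward = np.arctan2(c - root[1], c - root[0]) + rng.uniform(-0.4, 0.4)
        grow(root, inward, 0)
    return alpha


def generate_fundus_phantom(config: PhantomConfig, seed: int) -> np.ndarray:
    """Render a clean UWF-like phantom; deterministic in (config, seed).

    Returns an (H, W, 3) uint8 image: elliptical bright field with a radial
    gradient, additive Gaussian texture noise inside the field of view, and a
    recursively branched dark vessel tree.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    size = config.image_size
    rho2 = _fov_ellipse(size, config.fov_axes)
    inside = rho2 <= 1.0

    shading = 1.0 - config.background_gradient_strength * np.clip(rho2, 0.0, 1.0)
    img = np.asarray(config.background_base_color, dtype=np.float64)[None, None, :] \
        * shading[..., None]

    if config.vessel_root_count > 0:
        vessels = _grow_vessel_tree(config, rng)
        img *= 1.0 - config.vessel_darkening * vessels[..., None]

    if config.texture_noise_sigma > 0:
        img += rng.normal(0.0, config.texture_noise_sigma, img.shape)

    img = np.where(inside[..., None], img, 2.0)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# --- eyelash strokes ---------------------------------------------------------

_EDGE_NAMES = ("top", "bottom", "left", "right")


def _root_and_normal(edge: int, size: int, rng: np.random.Generator
                     ) -> tuple[np.ndarray, float]:
    u = rng.uniform(0.0, size - 1.0)
    if edge == 0:    # top: points down
        return np.array([u, 0.0]), np.pi / 2
    if edge == 1:    # bottom: points up
        return np.array([u, size - 1.0]), -np.pi / 2
    if edge == 2:    # left: points right
        return np.array([0.0, u]), 0.0
    return np.array([size - 1.0, u]), np.pi


def sample_eyelash_strokes(config: EyelashConfig, image_size: int, seed: int
                           ) -> list[Stroke]:
    """Draw a random stroke population; deterministic in (config, seed).

    Each stroke roots exactly on an image border, points inward (within 50
    degrees of the border normal), and is uniformly rescaled about its root so
    its Bezier arc length equals the sampled target length exactly.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    lo, hi = config.stroke_count_range
    count = int(rng.integers(lo, hi + 1))
    weights = np.asarray(config.root_edge_weights, dtype=np.float64)
    weights = weights / weights.sum()
    strokes: list[Stroke] = []
    for _ in range(count):
        edge = int(rng.choice(4, p=weights))
        root, normal = _root_and_normal(edge, image_size, rng)
        direction = normal + rng.uniform(-0.87, 0.87)  # within ~50 deg of normal
        length = rng.uniform(*config.length_range)
        curvature = rng.uniform(*config.curvature_range)
        bend_sign = rng.choice([-1.0, 1.0])
        tip = root + length * np.array([np.cos(direction), np.sin(direction)])
        mid = 0.5 * (root + tip)
        perp = np.array([-np.sin(direction), np.cos(direction)])
        ctrl = np.stack([root, mid + bend_sign * curvature * length * perp, tip])
        stroke = Stroke(
            control_points=ctrl,
            width_root=float(rng.uniform(*config.width_root_range)),
            width_taper=config.width_taper,
            opacity=float(rng.uniform(*config.opacity_range)),
        )
        # uniform scaling about the root scales arc length exactly linearly
        arc = stroke.arc_length()
        if arc > 0:
            scaled = root + (ctrl - root) * (length / arc)
            stroke = replace(stroke, control_points=scaled)
        strokes.append(stroke)
    return strokes


def _rasterize_stroke(alpha: np.ndarray, stroke: Stroke) -> None:
    """Stamp hard-edged disks densely along the Bezier (union into alpha)."""
    size = alpha.shape[0]
    n = max(int(np.ceil(stroke.arc_length() / 0.25)), 2)
    t = np.linspace(0.0, 1.0, n)
    pts = stroke.point(t)
    radii = stroke.width(t) / 2.0
    for (x, y), r in zip(pts, radii):
        x0, x1 = int(np.floor(x - r - 1)), int(np.ceil(x + r + 2))
        y0, y1 = int(np.floor(y - r - 1)), int(np.ceil(y + r + 2))
        x0, x1 = max(x0, 0), min(x1, size)
        y0, y1 = max(y0, 0), min(y1, size)
        if x1 <= x0 or y1 <= y0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        hit = (xx - x) ** 2 + (yy - y) ** 2 <= r * r
        np.maximum(alpha[y0:y1, x0:x1], hit.astype(alpha.dtype),
                   out=alpha[y0:y1, x0:x1])


def render_artifact_layer(strokes: list[Stroke], image_size: int,
                          config: EyelashConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render strokes to an alpha field in [0, 1] and its binary mask.

    Per-stroke hard rasterizations are scaled by stroke opacity and combined
    by union (max); the union is blurred by ``blur_sigma`` and a faint wide
    halo (Gaussian at 4*blur_sigma + 3 px, scaled by ``halo_opacity``) is
    added before clipping.  The mask is ``alpha > mask_threshold``.
    """
    alpha = np.zeros((image_size, image_size), dtype=np.float64)
    for stroke in strokes:
        layer = np.zeros_like(alpha)
        _rasterize_stroke(layer, stroke)
        np.maximum(alpha, stroke.opacity * layer, out=alpha)
    if strokes:
        core = gaussian_filter(alpha, config.blur_sigma) if config.blur_sigma > 0 \
            else alpha
        if config.halo_opacity > 0:
            halo = gaussian_filter(alpha, 4.0 * config.blur_sigma + 3.0)
            alpha = core + config.halo_opacity * halo
        else:
            alpha = core
        alpha = np.clip(alpha, 0.0, 1.0)
        # blur tails far below visibility are clamped to exact zero so the
        # off-artifact identity guarantee stays bitwise
        alpha[alpha < 1e-3] = 0.0
    return alpha, alpha > config.mask_threshold


def composite_artifact(clean: np.ndarray, alpha: np.ndarray,
                       config: EyelashConfig) -> np.ndarray:
    """Blend the dark shade over the clean image: (1 - a)*clean + a*shade.

    Pixels with zero alpha reproduce the clean image bitwise.  Output uint8.
    """
    if clean.shape[:2] != alpha.shape:
        raise ValueError(f"shape mismatch: image {clean.shape} vs alpha {alpha.shape}")
    shade = np.asarray(config.shade_color, dtype=np.float64)
    a = alpha[..., None]
    out = (1.0 - a) * clean.astype(np.float64) + a * shade[None, None, :]
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    # exact identity off-artifact, immune to rounding
    untouched = alpha == 0.0
    out[untouched] = clean[untouched]
    return out


# --- datasets ----------------------------------------------------------------

def artifact_background_region(sample: PairedSample,
                               brightness_threshold: float = 100.0) -> np.ndarray:
    """Homogeneous background pixels under the artifact of a paired sample.

    ENL rates the smoothness of a locally homogeneous area, so the natural
    evaluation region for artifact removal is the artifact's support restricted
    to bright background (vessels and the dark surround would contribute
    structural variance that has nothing to do with the artifact).
    """
    gray = sample.clean.astype(np.float64).mean(axis=-1)
    return sample.mask & (gray > brightness_threshold)


def default_configs(image_size: int = 256) -> tuple[PhantomConfig, EyelashConfig]:
    """Default phantom/eyelash configurations rescaled to ``image_size``."""
    return (PhantomConfig().scaled_to(image_size),
            EyelashConfig().scaled_to(image_size / 256.0))


def derive_seed(master_seed: int, *key: int) -> int:
    """Stable per-sample seed below 2**31, derived from the master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def make_paired_sample(phantom_cfg: PhantomConfig, eyelash_cfg: EyelashConfig,
                       phantom_seed: int, stroke_seed: int,
                       sample_id: str) -> PairedSample:
    clean = generate_fundus_phantom(phantom_cfg, phantom_seed)
    strokes = sample_eyelash_strokes(eyelash_cfg, phantom_cfg.image_size, stroke_seed)
    alpha, mask = render_artifact_layer(strokes, phantom_cfg.image_size, eyelash_cfg)
    corrupted = composite_artifact(clean, alpha, eyelash_cfg)
    return PairedSample(corrupted=corrupted, clean=clean, mask=mask,
                        sample_id=sample_id, phantom_seed=phantom_seed)


def build_paired_dataset(n: int, phantom_cfg: PhantomConfig,
                         eyelash_cfg: EyelashConfig, seed: int
                         ) -> list[PairedSample]:
    """Generate ``n`` corrupted/clean/mask triplets, reproducible per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    samples = []
    for i in range(n):
        samples.append(make_paired_sample(
            phantom_cfg, eyelash_cfg,
            phantom_seed=derive_seed(seed, 0, i, 0),
            stroke_seed=derive_seed(seed, 0, i, 1),
            sample_id=f"{i:05d}"))
    return samples


def build_unpaired_dataset(n_corrupted: int, n_clean: int,
                           phantom_cfg: PhantomConfig,
                           eyelash_cfg: EyelashConfig, seed: int
                           ) -> tuple[list[PairedSample], list[np.ndarray]]:
    """Generate disjoint corrupted and clean pools (no hidden pairing).

    The corrupted pool is returned as :class:`PairedSample` objects (the
    underlying clean phantom and mask exist and are useful for evaluation)
    but the clean pool is generated from a disjoint set of phantom seeds, so
    no clean image shares a phantom with any corrupted one.
    """
    if n_corrupted < 1 or n_clean < 1:
        raise ValueError("pool sizes must be >= 1")
    corrupted = [
        make_paired_sample(
            phantom_cfg, eyelash_cfg,
            phantom_seed=derive_seed(seed, 1, i, 0),
            stroke_seed=derive_seed(seed, 1, i, 1),
            sample_id=f"u{i:05d}")
        for i in range(n_corrupted)
    ]
    clean = [
        generate_fundus_phantom(phantom_cfg, derive_seed(seed, 2, i, 0))
        for i in range(n_clean)
    ]
    return corrupted, clean


__all__ = [
    "EyelashConfig",
    "artifact_background_region",
    "MASK_THRESHOLD",
    "PairedSample",
    "PhantomConfig",
    "PhantomConfigError",
    "Stroke",
    "build_paired_dataset",
    "build_unpaired_dataset",
    "composite_artifact",
    "default_configs",
    "derive_seed",
    "generate_fundus_phantom",
    "make_paired_sample",
    "render_artifact_layer",
    "sample_eyelash_strokes",
]
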