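"""Network architectures: shared generator, background refiner, discriminators.

The restoration model is built from three blocks:

* a U-shaped encoder/decoder generator ``G`` with symmetric skip connections
  that maps a corrupted patch to an artifact-free candidate,
* a background refinement module ``R`` with the identical U-shape (independent
  parameters) applied after ``G`` to restore detail hidden by the artifact,
* two PatchGAN-style discriminators: ``D1`` judges (input, candidate) pairs
  (conditional, 6 input channels) and ``D2`` judges single images
  (unconditional, 3 channels), each emitting a confidence map in (0, 1).

Encoder stages are 4x4 stride-2 convolutions with batch normalization and
leaky ReLU; the deepest encoder stage drops the normalization and uses ReLU.
Decoder stages are 4x4 stride-2 transposed convolutions with batch
normalization and ReLU; the last stage drops the normalization and squashes
through tanh.  Discriminators stack five 4x4 convolutions with strides
(2, 2, 2, 1, 1), batch normalization in stages 2-4, and a final sigmoid.

Stochasticity (the noise input of the adversarial formulation) enters as
decoder dropout, active only during training.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    Layer,
    LeakyReLU,
    Parameter,
    ReLU,
    Sigmoid,
    Tanh,
)

CHECKPOINT_VERSION = 1


class ShapeError(ValueError):
    """Input shape incompatible with a network's contract."""


class SpecError(ValueError):
    """Invalid network specification."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Configuration of the U-shaped generator / refiner.

    ``depth`` encoder stages each halve the spatial size, so inputs must be
    divisible by ``2**depth``.  Channel widths follow ``base_channels * 2**i``
    capped at ``channel_cap``.  ``noise_mode`` selects how stochasticity is
    injected: ``"dropout"`` (rate 0.5 in the first three decoder stages,
    training only) or ``"none"``.
    """

    depth: int = 8
    base_channels: int = 64
    channel_cap: int = 512
    in_channels: int = 3
    out_channels: int = 3
    noise_mode: str = "dropout"

    def validate(self) -> None:
        if self.depth < 1:
            raise SpecError("depth must be >= 1")
        if self.base_channels < 1:
            raise SpecError("base_channels must be >= 1")
        if self.noise_mode not in ("dropout", "none"):
            raise SpecError(f"unknown noise_mode {self.noise_mode!r}")

    @property
    def downsampling_factor(self) -> int:
        return 2 ** self.depth

    def encoder_channels(self) -> list[int]:
        return [min(self.base_channels * 2 ** i, self.channel_cap)
                for i in range(self.depth)]


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Five-layer patch discriminator configuration.

    ``conditional=True`` doubles the input channels: the discriminator sees
    the corrupted input concatenated with the candidate restoration.
    """

    conditional: bool = True
    in_channels: int = 3
    base_channels: int = 64
    layers: int = 5
    kernel: int = 4
    strides: tuple[int, ...] = (2, 2, 2, 1, 1)

    def validate(self) -> None:
        if self.layers != len(self.strides):
            raise SpecError("strides length must equal layers")
        if self.base_channels < 1:
            raise SpecError("base_channels must be >= 1")

    @property
    def input_channels(self) -> int:
        return self.in_channels * 2 if self.conditional else self.in_channels


class _Chain:
    """A straight run of layers sharing one forward/backward cache."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self) -> list[Parameter]:
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


class Network:
    """Base for trainable networks; doubles as the opaque network handle.

    Exposes the spec, the parameter count and a forward contract; evaluation
    forwards are deterministic for fixed parameters and input.
    """

    spec: object

    def parameters(self) -> list[Parameter]:
        raise NotImplementedError

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def param_hash(self) -> str:
        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()

    # --- state serialization -------------------------------------------------
    def _buffers(self) -> list[np.ndarray]:
        out = []
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm2d):
                out.extend([layer.running_mean, layer.running_var])
        return out

    def _all_layers(self) -> list[Layer]:
        raise NotImplementedError

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()] + self._buffers()

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise SpecError(
                f"state mismatch: expected {len(own)} arrays, got {len(arrays)}")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise SpecError(f"state mismatch: {dst.shape} vs {src.shape}")
            dst[...] = src


class UNet(Network):
    """U-shaped encoder/decoder with symmetric skip connections."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2 ** 31))
        d = spec.depth
        ch = spec.encoder_channels()

        self.enc: list[_Chain] = []
        in_c = spec.in_channels
        for i in range(d):
            layers: list[Layer] = [Conv2d(in_c, ch[i], 4, 2, 1, rng)]
            if i < d - 1:
                layers += [BatchNorm2d(ch[i]), LeakyReLU(0.2)]
            else:
                layers += [ReLU()]
            self.enc.append(_Chain(layers))
            in_c = ch[i]

        n_dropout = min(3, d - 1) if spec.noise_mode == "dropout" else 0
        self.dec: list[_Chain] = []
        self._dec_out_channels: list[int] = []
        for j in range(d):
            dec_in = ch[d - 1] if j == 0 else self._dec_out_channels[j - 1] + ch[d - 1 - j]
            if j < d - 1:
                out_c = ch[d - 2 - j]
                layers = [ConvTranspose2d(dec_in, out_c, 4, 2, 1, rng),
                          BatchNorm2d(out_c)]
                if j < n_dropout:
                    layers.append(Dropout(0.5, self._dropout_rng))
                layers.append(ReLU())
            else:
                out_c = spec.out_channels
                layers = [ConvTranspose2d(dec_in, out_c, 4, 2, 1, rng), Tanh()]
            self.dec.append(_Chain(layers))
            self._dec_out_channels.append(out_c)

        self._acts: list[np.ndarray] | None = None

    def _all_layers(self) -> list[Layer]:
        return [l for c in self.enc + self.dec for l in c.layers]

    def parameters(self) -> list[Parameter]:
        return [p for c in self.enc + self.dec for p in c.parameters()]

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ShapeError(
                f"expected (N,{self.spec.in_channels},H,W) input, got {x.shape}")
        f = self.spec.downsampling_factor
        if x.shape[2] % f or x.shape[3] % f:
            raise ShapeError(
                f"input spatial size {x.shape[2]}x{x.shape[3]} must be divisible "
                f"by 2**depth = {f}")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._check_input(x)
        acts = []
        h = x.astype(np.float32, copy=False)
        for stage in self.enc:
            h = stage.forward(h, train)
            acts.append(h)
        d = self.spec.depth
        for j, stage in enumerate(self.dec):
            if j > 0:
                h = np.concatenate([h, acts[d - 1 - j]], axis=1)
            h = stage.forward(h, train)
        if train:
            self._acts = acts
        return h

    def backward(self, gy: np.ndarray) -> np.ndarray:
        d = self.spec.depth
        skip_grads: list[np.ndarray | None] = [None] * d
        g = gy
        for j in reversed(range(d)):
            g = self.dec[j].backward(g)
            if j > 0:
                split = self._dec_out_channels[j - 1]
                skip_grads[d - 1 - j] = g[:, split:]
                g = g[:, :split]
        for i in reversed(range(d)):
            if i < d - 1 and skip_grads[i] is not None:
                g = g + skip_grads[i]
            g = self.enc[i].backward(g)
        self._acts = None
        return g


class PatchDiscriminator(Network):
    """Five-layer strided CNN emitting a confidence map in (0, 1)."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        widths = [spec.base_channels * m for m in (1, 2, 4, 8)]
        layers: list[Layer] = []
        in_c = spec.input_channels
        for i, stride in enumerate(spec.strides):
            out_c = widths[i] if i < spec.layers - 1 else 1
            layers.append(Conv2d(in_c, out_c, spec.kernel, stride, 1, rng))
            if 1 <= i <= 3:
                layers.append(BatchNorm2d(out_c))
            if i < spec.layers - 1:
                layers.append(LeakyReLU(0.2))
            in_c = out_c
        layers.append(Sigmoid())
        self.chain = _Chain(layers)

    def _all_layers(self) -> list[Layer]:
        return self.chain.layers

    def parameters(self) -> list[Parameter]:
        return self.chain.parameters()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.spec.input_channels:
            raise ShapeError(
                f"discriminator expects {self.spec.input_channels} channels "
                f"(conditional={self.spec.conditional}), got input {x.shape}")
        return self.chain.forward(x.astype(np.float32, copy=False), train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.chain.backward(gy)

    def output_map_size(self, size: int) -> int:
        """Closed-form spatial size of the confidence map for a square input."""
        s = size
        for stride in self.spec.strides:
            s = (s + 2 - self.spec.kernel) // stride + 1
        return s


NetworkHandle = Network  # the opaque-handle role is played by the base class


def build_generator(spec: GeneratorSpec, seed: int = 0) -> UNet:
    """Build the shared generator ``G``."""
    return UNet(spec, seed=seed)


def build_refiner(spec: GeneratorSpec, seed: int = 1) -> UNet:
    """Build the background refinement module ``R`` (same shape, own weights)."""
    return UNet(spec, seed=seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 2) -> PatchDiscriminator:
    return PatchDiscriminator(spec, seed=seed)


def forward_restore(g: UNet, r: UNet | None, x: np.ndarray) -> np.ndarray:
    """Inference path: ``R(G(x))``, or ``G(x)`` when no refiner is configured.

    ``x`` is expected in the model range [-1, 1], NCHW.
    """
    y = g.forward(x, train=False)
    if r is not None:
        y = r.forward(y, train=False)
    return y


# --- checkpoints -------------------------------------------------------------

def _spec_digest(meta: dict) -> str:
    return hashlib.sha256(
        json.dumps(meta, sort_keys=True).encode()).hexdigest()


def save_checkpoint(path, nets: dict[str, Network], extra: dict | None = None) -> None:
    """Serialize named networks plus their specs into a single ``.npz`` archive."""
    arrays: dict[str, np.ndarray] = {}
    meta: dict = {"version": CHECKPOINT_VERSION, "nets": {}, "extra": extra or {}}
    for name, net in nets.items():
        state = net.state_arrays()
        meta["nets"][name] = {
            "kind": type(net).__name__,
            "spec": asdict(net.spec),
            "n_arrays": len(state),
        }
        for i, a in enumerate(state):
            arrays[f"{name}/{i:04d}"] = a
    meta["spec_digest"] = _spec_digest(meta["nets"])
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[dict[str, Network], dict]:
    """Rebuild networks from a checkpoint; verifies version and spec digest."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise SpecError(f"unsupported checkpoint version {meta.get('version')}")
        if meta["spec_digest"] != _spec_digest(meta["nets"]):
            raise SpecError("checkpoint spec digest mismatch (corrupt archive?)")
        nets: dict[str, Network] = {}
        for name, info in meta["nets"].items():
            if info["kind"] == "UNet":
                net: Network = UNet(GeneratorSpec(**{
                    k: v for k, v in info["spec"].items()}))
            elif info["kind"] == "PatchDiscriminator":
                spec_kw = dict(info["spec"])
                spec_kw["strides"] = tuple(spec_kw["strides"])
                net = PatchDiscriminator(DiscriminatorSpec(**spec_kw))
            else:
                raise SpecError(f"unknown network kind {info['kind']!r}")
            net.load_state_arrays(
                [data[f"{name}/{i:04d}"] for i in range(info["n_arrays"])])
            nets[name] = net
    return nets, meta["extra"]


__all__ = [
    "DiscriminatorSpec",
    "GeneratorSpec",
    "Network",
    "NetworkHandle",
    "PatchDiscriminator",
    "ShapeError",
    "SpecError",
    "UNet",
    "build_discriminator",
    "build_generator",
    "build_refiner",
    "forward_restore",
    "load_checkpoint",
    "save_checkpoint",
]
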