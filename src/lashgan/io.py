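"""Image I/O, dataset directory layout, and tiled whole-frame inference.

Full UWF frames (the native acquisition is 3900 x 3072) are larger than the
training patch size, so inference covers a frame with overlapping tiles whose
outputs are blended with linear feathering; frames not divisible by the
network's downsampling factor are reflection-padded and cropped back.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .nets import UNet, forward_restore, load_checkpoint
from .phantom import EyelashConfig, PairedSample, PhantomConfig
from .trainer import from_model, to_model


class ImageIOError(IOError):
    pass


_SUPPORTED_SUFFIXES = (".png", ".tif", ".tiff")


def load_image(path) -> np.ndarray:
    """Read an 8-bit PNG/TIFF as (H, W, 3) uint8; grayscale is replicated."""
    path = Path(path)
    try:
        img = Image.open(path)
        img.load()
    except (OSError, SyntaxError) as exc:
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    if img.mode == "P":
        img = img.convert("RGB")
    if img.mode == "L":
        arr = np.asarray(img, dtype=np.uint8)
        return np.repeat(arr[..., None], 3, axis=-1)
    if img.mode == "RGB":
        return np.asarray(img, dtype=np.uint8)
    raise ImageIOError(
        f"unsupported image mode {img.mode!r} in {path}: only 8-bit "
        "grayscale or RGB is supported")


def save_image(img: np.ndarray, path) -> None:
    """Write uint8 (H, W, 3) RGB or (H, W) grayscale to PNG/TIFF."""
    path = Path(path)
    if img.dtype != np.uint8:
        raise ImageIOError(f"expected uint8 image for {path}, got {img.dtype}")
    mode = "RGB" if img.ndim == 3 else "L"
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img, mode=mode).save(path)


# --- dataset directories -----------------------------------------------------

def write_dataset(outdir, paired: list[PairedSample],
                  unpaired: tuple[list[PairedSample], list[np.ndarray]] | None,
                  phantom_cfg: PhantomConfig, eyelash_cfg: EyelashConfig,
                  seed: int) -> None:
    """Write the standard dataset layout plus a manifest of configs and seeds."""
    outdir = Path(outdir)
    for s in paired:
        save_image(s.corrupted, outdir / "paired" / "corrupted" / f"{s.sample_id}.png")
        save_image(s.clean, outdir / "paired" / "clean" / f"{s.sample_id}.png")
        save_image((s.mask * np.uint8(255)), outdir / "paired" / "mask" / f"{s.sample_id}.png")
    manifest = {
        "seed": int(seed),
        "n_paired": len(paired),
        "phantom_config": asdict(phantom_cfg),
        "eyelash_config": asdict(eyelash_cfg),
    }
    if unpaired is not None:
        corrupted, clean = unpaired
        for s in corrupted:
            save_image(s.corrupted,
                       outdir / "unpaired" / "corrupted" / f"{s.sample_id}.png")
            save_image((s.mask * np.uint8(255)),
                       outdir / "unpaired" / "mask" / f"{s.sample_id}.png")
        for i, img in enumerate(clean):
            save_image(img, outdir / "unpaired" / "clean" / f"c{i:05d}.png")
        manifest["n_unpaired_corrupted"] = len(corrupted)
        manifest["n_unpaired_clean"] = len(clean)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_paired_dataset(datadir) -> list[PairedSample]:
    """Load corrupted/clean/mask triplets from the standard layout."""
    datadir = Path(datadir)
    samples = []
    for cor_path in sorted((datadir / "paired" / "corrupted").glob("*.png")):
        sid = cor_path.stem
        clean = load_image(datadir / "paired" / "clean" / f"{sid}.png")
        mask_img = Image.open(datadir / "paired" / "mask" / f"{sid}.png")
        mask = np.asarray(mask_img.convert("L")) > 127
        samples.append(PairedSample(corrupted=load_image(cor_path), clean=clean,
                                    mask=mask, sample_id=sid))
    if not samples:
        raise ImageIOError(f"no paired samples found under {datadir}")
    return samples


def read_unpaired_dataset(datadir) -> tuple[list[np.ndarray], list[np.ndarray]]:
    datadir = Path(datadir)
    cor = [load_image(p) for p in
           sorted((datadir / "unpaired" / "corrupted").glob("*.png"))]
    cln = [load_image(p) for p in
           sorted((datadir / "unpaired" / "clean").glob("*.png"))]
    return cor, cln


# --- tiling ------------------------------------------------------------------

@dataclass(frozen=True)
class TileGrid:
    """Overlapping tile origins covering a frame completely."""

    frame_hw: tuple[int, int]
    tile_size: int
    overlap: int
    origins: tuple[tuple[int, int], ...]   # (y, x), top-left corners


def _axis_origins(extent: int, tile: int, step: int) -> list[int]:
    if tile >= extent:
        return [0]
    origins = list(range(0, extent - tile, step))
    origins.append(extent - tile)
    return sorted(set(origins))


def plan_tiles(height: int, width: int, tile_size: int = 1024,
               overlap: int = 64) -> TileGrid:
    """Plan overlapping tiles; adjacent interior tiles share ``overlap`` pixels.

    Border tiles clamp their origin so the grid never exceeds the frame; a
    tile larger than the frame yields a single origin at (0, 0).
    """
    if not (tile_size > overlap >= 0):
        raise ValueError(f"need tile_size > overlap >= 0, got {tile_size}, {overlap}")
    step = tile_size - overlap
    ys = _axis_origins(height, tile_size, step)
    xs = _axis_origins(width, tile_size, step)
    return TileGrid(frame_hw=(height, width), tile_size=tile_size,
                    overlap=overlap,
                    origins=tuple((y, x) for y in ys for x in xs))


def _feather_weights(h: int, w: int, overlap: int) -> np.ndarray:
    ramp_len = max(overlap, 1)

    def ramp(n: int) -> np.ndarray:
        i = np.arange(n, dtype=np.float64)
        return np.minimum.reduce([np.full(n, ramp_len, dtype=np.float64),
                                  i + 1, n - i]) / ramp_len

    return ramp(h)[:, None] * ramp(w)[None, :]


def _pad_to_multiple(img: np.ndarray, factor: int) -> tuple[np.ndarray, int, int]:
    h, w = img.shape[:2]
    ph = (-h) % factor
    pw = (-w) % factor
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    return img, h, w


def restore_array(g: UNet, r: UNet | None, img: np.ndarray,
                  tile_size: int | None = None, overlap: int = 64) -> np.ndarray:
    """Run the restoration path over a uint8 RGB frame of any size.

    Without ``tile_size`` the frame is processed in one pass (reflection-
    padded to the network's divisibility requirement).  With ``tile_size``
    the frame is covered by overlapping tiles blended by linear feathering;
    a single-tile plan reproduces the untiled result exactly.
    """
    factor = g.spec.downsampling_factor
    if tile_size is None:
        padded, h, w = _pad_to_multiple(img, factor)
        out = forward_restore(g, r, to_model(padded)[None])[0]
        return from_model(out)[:h, :w]

    if tile_size % factor:
        raise ValueError(
            f"tile_size={tile_size} must be divisible by the network "
            f"downsampling factor {factor}")
    # guarantee each planned tile fits in the padded frame
    h0, w0 = img.shape[:2]
    ph = max(tile_size - h0, (-h0) % factor)
    pw = max(tile_size - w0, (-w0) % factor)
    padded = np.pad(img, ((0, ph), (0, pw), (0, 0)), mode="reflect") \
        if (ph or pw) else img
    hp, wp = padded.shape[:2]
    grid = plan_tiles(hp, wp, tile_size, overlap)
    acc = np.zeros((hp, wp, 3), dtype=np.float64)
    wacc = np.zeros((hp, wp, 1), dtype=np.float64)
    weights = _feather_weights(tile_size, tile_size, overlap)[..., None]
    for y, x in grid.origins:
        tile = padded[y:y + tile_size, x:x + tile_size]
        restored = forward_restore(g, r, to_model(tile)[None])[0]
        restored = (restored.transpose(1, 2, 0) + 1.0) * 127.5
        acc[y:y + tile_size, x:x + tile_size] += weights * restored
        wacc[y:y + tile_size, x:x + tile_size] += weights
    out = np.clip(np.rint(acc / wacc), 0, 255).astype(np.uint8)
    return out[:h0, :w0]


def infer_image(checkpoint_path, input_path, output_path,
                tile_size: int | None = None, overlap: int = 64) -> None:
    """Restore one image file end-to-end from a training checkpoint."""
    nets, extra = load_checkpoint(checkpoint_path)
    if "g" not in nets:
        raise ImageIOError(f"checkpoint {checkpoint_path} has no generator")
    g = nets["g"]
    r = nets.get("r")
    img = load_image(input_path)
    save_image(restore_array(g, r, img, tile_size, overlap), output_path)


__all__ = [
    "ImageIOError",
    "TileGrid",
    "infer_image",
    "load_image",
    "plan_tiles",
    "read_paired_dataset",
    "read_unpaired_dataset",
    "restore_array",
    "save_image",
    "write_dataset",
]
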