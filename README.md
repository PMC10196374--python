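# lashgan

Eyelash-artifact removal for ultra-wide-field (UWF) fundus images.

UWF scanning-laser ophthalmoscopy captures ~200° of the retina in one frame,
but eyelashes in the optical path cast dark, curved, semi-transparent
shadows that obscure vessels and lesions. `lashgan` implements a jointly
trained conditional/unconditional adversarial restoration model that maps
corrupted patches to artifact-free ones, together with a synthetic
phantom/artifact simulator (so every experiment is reproducible without
patient data) and the evaluation metrics used for this task.

## Model

One shared U-shaped generator *G* is trained from two directions at once:

* **paired** corrupted/clean samples (x_p, y_p) drive a conditional
  discriminator *D₁* on (input, candidate) pairs, an L1 generation loss,
  and a background refinement module *R* (a second U-Net applied after *G*)
  with its own L1 refinement loss;
* **unpaired** pools of corrupted and clean images drive an unconditional
  discriminator *D₂* on single images.

The generator objective is

```
L  =  L_ca  +  λ₁·‖y_p − G(x_p)‖₁  +  L_uca  +  λ₂·‖y_p − R(G(x_p))‖₁ ,
λ₁ = 100,  λ₂ = 10
```

with binary-cross-entropy adversarial terms; inference runs `R(G(x))`.
Four ablation variants (`cgan_sub`, `cgan_ref`, `cgan_gan`, `full`) gate the
components. Everything — including the convolutional layer stack with
hand-derived backward passes — runs on NumPy; no deep-learning framework is
required. See `docs/methods.md` for the full account.

## Worked example

Train the full model on synthetic phantoms at desk scale and restore an
image (a few minutes on a laptop CPU):

```
$ lashgan simulate --out data --n-paired 48 --n-corrupted 16 --n-clean 16 \
      --image-size 64 --seed 0
wrote 48 paired and 16+16 unpaired samples to data

$ lashgan train --out model.npz --image-size 64 --epochs 30 --variant full \
      --seed 0 --n-paired 48 --n-unpaired 48
best val PSNR 21.97 dB (epoch 30); checkpoint: model.npz

$ lashgan infer --checkpoint model.npz \
      --input data/paired/corrupted/00000.png --output restored.png
wrote restored.png
```

The validation PSNR is measured between restored and clean phantoms on a
held-out split; 22.0 dB against a corrupted-input baseline of ~19.3 dB means
the model recovers roughly 2.7 dB of fidelity by removing the synthetic
lashes. `lashgan evaluate` scores folders of restored images against
references (PSNR/SSIM, and ENL inside artifact masks when masks are given),
and `lashgan ablate` trains all four variants on shared data and prints a
per-variant comparison table.

The same machinery scales to full-size training
(`lashgan.trainer.full_scale_config()`: 1024×1024 patches, batch 15, 200
epochs) given suitable hardware, and `lashgan infer --tile-size 1024`
restores frames of arbitrary size (e.g. native 3900×3072) by feathered
overlapping tiles.

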