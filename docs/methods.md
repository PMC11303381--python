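# Methods

## The model

`cnnt` denoises volumetric fluorescence microscopy (confocal/iSIM Z stacks,
wide-field or two-photon time series) with a U-net whose building block is a
transformer cell specialised for image stacks. The canonical feature tensor
is `[B, T, C, H, W]` — batch, frames (Z or time), channels, height, width.
Each frame is embedded by shared 2D 3×3 convolutions; soft attention then
acts **across the frame axis**: for head *h* with per-head channel count
`C_h = C / n_heads`,

    K_t = conv_k(x_t),  Q_t = conv_q(x_t),  V_t = conv_v(x_t)
    s[t, t'] = ⟨flatten(Q_t), flatten(K_{t'})⟩ / sqrt(C_h · H · W)
    A = softmax over t' of s
    out_t = Σ_{t'} A[t, t'] · V_{t'}

heads are concatenated on channels and fused by a 1×1 convolution. Compared
with patch-based image transformers (ViT/Swin), each whole frame is one
token, so the quadratic attention cost is in the (short) frame axis and the
spatial inductive bias stays convolutional. With convolutions shared across
frames and no positional encoding, the attention is equivariant to frame
permutations — a property of this implementation, tested as such.

A **CNNT cell** is pre-norm transformer-ordered:

    y   = x + attention(instance_norm(x))
    out = y + mixer(instance_norm(y))

where the mixer is two per-frame 3×3 convolutions (channel expansion 2×,
GELU between) and instance normalisation standardises each
(sample, frame, channel) map. The **U-net** uplifts the input to 32
channels (pre-conv), runs two downsample blocks (cells + stride-2 conv:
channels ×2, H/W ÷2; 32 → 64 → 128), two upsample blocks (2× nearest
upsampling + conv, concatenation with the matching encoder skip, 1×1 fuse,
cells; 128 → 64 → 32) and a post-conv back to the input channel count.
Each level holds four cells at full size; the desk-scale test
configuration shrinks this to 8 base channels and two cells per level — the
wiring is identical. A long **additive** skip connects input to output, so
the network predicts a residual correction; the intra-U skips are
concatenations.

Initialisation zero-initialises the post-conv and every residual output
projection, making a fresh network exactly the identity map. This both
anchors the residual parameterisation and stabilises early SSIM-loss
optimisation. A consequence used by the tests: gradient reaches the
attention/mixer input convolutions only after the first optimizer step has
moved the output projections off zero, so gradient-coverage checks use the
fully random initialisation mode.

## Training

Two regimes share one loop:

| parameter | backbone | fine-tune |
|---|---|---|
| epochs | 300 | 30 |
| learning rate | 1e-4 | 2.5e-5 |
| optimizer | AdamW, betas (0.90, 0.95), weight decay 0.01 | same |
| scheduler | reduce-on-plateau, factor 0.8 | same |
| loss | 1 − mean SSIM | same |

Each epoch draws exactly one random cutout from every pair in the dataset
(default shapes 8×128×128 and 8×160×160, chosen per pair uniformly at
random; the desk-scale tests use 8×64×64 and 4×32×32). Cutouts of equal
shape are batched; one optimizer step per batch. The scheduler monitors the
epoch training loss (no validation split is part of the protocol; the
plateau patience is 5 epochs, floor 1e-6). Gradients are clipped at global
norm 1.0 — SSIM on near-constant cutouts has small stabilising constants in
denominators and can spike. Fine-tuning updates **all** weights at the
smaller rate; no layers are frozen. Checkpoints store weights plus the
architecture, training and normalisation configuration and the loss
history; reloading reproduces forward outputs bit-identically.

Intensities are normalised per volume before training and inference: the
0.5th/99.5th percentiles map to [0, 1] (robust to hot pixels), and the
inverse map is applied to outputs on export. Low and high arms are
normalised independently, as in standard paired-restoration practice.

## Numerical engine

No deep-learning framework is used: the model, the SSIM loss and AdamW run
on `cnnt.nn`, a small reverse-mode autograd engine over numpy arrays,
written for exactly the operator set this architecture needs. Convolution
is blocked im2col: per-sample column buffers stay cache-resident and each
sample's output is one BLAS GEMM, which keeps DRAM traffic near
input+output size; the gather/scatter and the fused GELU/instance-norm
kernels are JIT-compiled with numba (pure-numpy fallbacks included). All
gradients are validated against central finite differences, and the
convolution forward against `scipy.signal.correlate2d`. Everything is
float32; training is bit-reproducible for a fixed seed on a fixed BLAS
configuration.

## Metrics

PSNR is `10·log10(data_range²/MSE)` over all voxels, with an infinite-PSNR
sentinel when MSE is exactly zero. The training loss uses the canonical
2D SSIM configuration — 11×11 Gaussian window, σ 1.5, k1 0.01, k2 0.03 —
per frame, averaged over (batch, frame), as a differentiable `1 − SSIM`.
Volumetric evaluation (SSIM3D) uses a 7×7×7 uniform window; for stacks
thinner than 7 frames the window depth clamps to the stack. Both match
`skimage.metrics.structural_similarity` with population (not sample)
covariance. `data_range` for reported metrics is the value range of the
reference volume. SSIM is exactly invariant to joint rescaling of both
inputs with a rescaled `data_range`, but only approximately invariant to
joint offsets (the luminance term); the tests distinguish the two.

## Synthetic data

The generator emulates the paired-acquisition designs the method is used
with. Clean scenes render filaments (smoothed 3D random walks, mostly
in-plane), puncta (point sources) or membranes (thin ellipsoid shells) into
a (frames, h, w) grid, blur with an anisotropic Gaussian PSF (default
σ = 1.0/1.5/1.5 voxels in z/y/x), scale the peak to `max_intensity`
(default 100) over a background (default 10). Noise follows the standard
fluorescence camera model:

    s   = photons_high · exposure_ratio / max(clean)
    obs = (Poisson(clean · s) + Normal(0, read_sigma)) / s

Both arms share the clean signal and differ only in noise, so pairs are
pixel-registered by construction; `exposure_ratio` 0.25 emulates a 25 vs
100 ms exposure split (0.125 would mimic a 4 vs 32 line-average scanner
setting). Defaults: 200 peak photons in the high arm, read noise 2 e⁻.
Repeat stacks draw `n_rep` (default 64) independent low-arm acquisitions of
one scene; `Avg n` is the mean of the first `n`, and `Avg n_rep` serves as
the ground truth of the robustness protocol.

What the generator does **not** emulate: diffraction-accurate PSFs,
photobleaching, sample motion, depth-dependent aberrations, or the
structured background of real tissue. Passing desk-scale tests therefore
demonstrates that the architecture, loss, training scheme and protocols
function and interact as designed — not that real-microscope benchmark
numbers are reproduced.

## Inference on large volumes

Volumes larger than one tile are processed with overlapped tiles (default
8×128×128, overlap = 2 frames and a quarter tile spatially), blended with a
strictly positive cosine taper and normalised by the accumulated weight, so
the blend weights form an exact partition of unity. H/W not divisible by
the U-net factor are reflect-padded and cropped back. Tiles larger than the
volume are clamped, so a small volume reduces to a direct forward pass.

## Desk-scale problem sizes

Chosen once as the package's test scale: supervised denoising trains the
8-channel, 2-cells-per-level model for 304 steps (19 epochs × 16 pairs,
batch 1) on 8×64×64 pairs at exposure ratio 0.25 — this yields a held-out
PSNR gain near +4 dB over the noisy input. The transfer check pretrains on
10 filament volumes (4×32×32) for 16 epochs, then compares 30-epoch
fine-tuning on 5 puncta pairs against 30-epoch scratch training; the
fine-tuned model wins on held-out SSIM3D in all tested seeds.

## Known limitations

- **Multi-average protocol at high n.** Output PSNR against `Avg 64` is
  capped near the model's structural error floor (~33.5 dB for the
  304-step desk model), while the input PSNR grows without bound as
  n → n_rep (infinite at n = 64, where the input *is* the ground truth).
  Writing the output as `clean + α·(input noise) + bias`, beating the input
  at n = 32 requires `bias ≲ σ·sqrt(α(1−α)/32)` — about 45 dB structural
  accuracy, far beyond a desk-scale model. The desk model therefore
  improves Avg 1–4 but scores below the input from Avg 8 upward; the
  robustness table reports both sides honestly.
- **Tiled vs whole-volume inference.** Instance norm and frame attention
  compute statistics over the whole tile, so tiles see genuinely different
  contexts than the full volume; measured worst-case disagreement is a few
  percent of the data range (99th percentile ~0.5%), independent of overlap
  and blend mode. Tiling is consistent in the partition-of-unity sense, not
  in a strict equality sense.
- Single-device, float32 only; no mixed precision, no distributed training.
- The attention flattens whole frames, so memory scales with T·C·H·W per
  tile; very long time series should be tiled along T.
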