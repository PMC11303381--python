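"""Train a small CNNT U-net on synthetic pairs and denoise a held-out volume.

A few minutes on one CPU.  Prints the SSIM-loss trajectory and the held-out
PSNR before and after denoising; the gain (several dB) is the improvement
the model delivers over the raw noisy acquisition.
"""

import numpy as np

from cnnt import (CNNTConfig, NoiseConfig, SceneConfig, TilingSpec,
                  infer_volume, make_paired_dataset, psnr)
from cnnt.training import TrainConfig, train_backbone

scene = SceneConfig(structure="filaments", volume_shape=(8, 64, 64), n_objects=12)
noise = NoiseConfig(photons_high=200.0, exposure_ratio=0.25, read_sigma=2.0)
pairs = make_paired_dataset(scene, noise, 10, master_seed=42)
train_pairs, held = pairs[:8], pairs[8:]

model_cfg = CNNTConfig(base_channels=8, n_levels_down=2, n_levels_up=2,
                       cells_per_block=2, n_heads=2)
train_cfg = TrainConfig(regime="backbone", epochs=16, batch_size=1,
                        cutout_shapes=((8, 64, 64),), seed=0)
ckpt = train_backbone(train_pairs, model_cfg, train_cfg, verbose=True)

for pair in held:
    dr = float(pair.high.voxels.max() - pair.high.voxels.min())
    denoised = infer_volume(ckpt, pair.low, TilingSpec(tile=(8, 64, 64)))
    p_in = psnr(pair.low, pair.high, dr)
    p_out = psnr(denoised, pair.high, dr)
    print(f"held-out: PSNR {p_in:.2f} dB -> {p_out:.2f} dB "
          f"(gain {p_out - p_in:+.2f} dB)")
print("\nSixteen epochs already buys a visible gain; the acceptance "
      "protocol trains ~300 steps for a >= 3 dB mean gain.")
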