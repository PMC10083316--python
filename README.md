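# bafnet — bidirectional attention fusion network for leaf segmentation

`bafnet` segments single plant leaves from RGB field photographs — the
upstream step of leaf-disease phenotyping, where spot and blight lesions must
be measured against an accurately delineated leaf. It implements a hybrid
CNN/shifted-window-transformer segmentation network for people who need a
fully inspectable, CPU-reproducible reference of this architecture family:
every block, the loss, the metrics and the training loop are pure NumPy on a
small built-in autodiff engine, verified against brute-force oracles.

## The model

Three coupled parts produce a per-pixel foreground probability p ∈ [0,1]:

- **MSFF branch** — a five-stage U-shaped encoder–decoder (channels
  32/64/128/256/512). Each encoder stage is a *Swin-Trans-Conv* block: after
  a 1×1 convolution the channels split evenly; one half runs a depth-2 Swin
  stage (W-MSA then SW-MSA, pre-norm residuals, MLP ratio 4), the other a
  residual double 3×3 convolution; a 1×1 convolution re-fuses them with a
  residual connection.
- **FSFF branch** — encoder features reduced to 32 channels, upsampled to
  full resolution, summed with the stage-1 feature, then refined by four
  Conv-BN-ReLU blocks that keep full resolution (boundary detail).
- **BAF modules** — at each decoder level a gate pair exchanges features:
  α_ms = σ(proj(Conv₁ₓ₁[F_ms ‖ avgpool(F_fg)])) rescales the decoder stream,
  α_fg = σ(proj(Conv₃ₓ₃(up(F_ms) ⊕ F_fg))) rescales the full-scale stream.

Training minimises L = α·L_bce + (1−α)·L_iou with α = 0.5, where
L_iou = −log Σ(g·p)/Σ(g+p−g·p) is the soft-Jaccard loss, via seeded SGD
(lr 0.01, batch 4, momentum 0.9). Evaluation reports PA, PR, PP, PS, IoU and
F1 from per-pixel contingency counts, aggregated as per-image means.

Four nested ablation variants are built in: `SU-Net` (half-width U-Net
baseline), `SU-Net-MSFF`, `SU-Net-MSFF-FSFF`, `BAF-Net`.

## Worked example

```python
import numpy as np
from dataclasses import replace
from bafnet import BAFNetSegmenter, LeafGenConfig, generate_leaf

# eight synthetic 64x64 leaves with paired ground-truth masks
cfg = LeafGenConfig(image_size=64, seed=0)
pairs = [generate_leaf(replace(cfg, seed=i)) for i in range(8)]
X = np.stack([im for im, _ in pairs])   # (8, 3, 64, 64) float32 in [0,1]
y = np.stack([mk for _, mk in pairs])   # (8, 64, 64) binary masks

est = BAFNetSegmenter(base_channels=8, max_iter=200, batch_size=4,
                      lr=0.01, random_state=0)
est.fit(X, y)
print(f"loss {est.loss_curve_[0]:.3f} -> {est.loss_curve_[-1]:.4f}")
print(f"train mIoU {est.score(X, y):.3f}")
```

Output:

```
loss 1.111 -> 0.0087
train mIoU 0.994
```

The loss falls from 1.111 (an untrained network near the p ≈ 0.5 regime,
where BCE ≈ ln 2 and the soft-IoU term dominates) by two orders of magnitude,
and the trained model overlaps the ground-truth masks at 99.4% mean IoU on
its training images — the architecture, gradients and optimiser all
functioning end to end at desk scale.

The estimator follows the scikit-learn contract (`get_params`/`set_params`,
`fit`/`predict`/`predict_proba`/`score`), so it composes with sklearn
model-selection tooling. The same functionality is available from the shell:

```bash
leafgen --n 40 --size 64 --seed 0 --out data/
bafnet train --data data/manifest.csv --out run/ --seed 0 --config cfg.yaml
bafnet eval --checkpoint run/checkpoint.npz --data data/manifest.csv
bafnet predict --checkpoint run/checkpoint.npz --image data/leaf_0000.png --out pred.png
bafnet ablate --data data/manifest.csv --out ablation/ --seed 0
```

`bafnet.data_io` additionally converts LabelMe polygon annotations to binary
masks (even-odd rule at pixel centres), reads/writes {0,1} mask PNGs, and
reproduces the reference train/val/test split proportions
(1015/184/186 of 1385 at the default fractions).

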