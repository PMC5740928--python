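# ffirst

Fast features invariant to rotation and scale of texture: a multi-scale,
rotation-invariant LBP histogram-Fourier texture descriptor with
segmentation-aware interior/border description and kernel-mapped
one-vs-all SVM classification, for bark/leaf-style recognition tasks.

## Method overview

1. **Pattern algebra** (`ffirst.patterns`) — all `2^P` circular binary
   patterns are partitioned into rotation orbits (binary necklaces; 36
   orbits for P=8), with per-code rotation index, period, and
   uniformity.
2. **LBP maps** (`ffirst.lbp`) — a Gaussian scale stack with radius
   schedule `R_1 = 1`, `R_i = R_{i-1}·√2`; per scale, sign-LBP (signs of
   center/neighbor differences) and magnitude-LBP (absolute differences
   thresholded at their image-wide per-neighbor mean) code images via
   bilinear circular sampling.
3. **Histogram-Fourier features** (`ffirst.features`) — per-orbit
   histograms are DFT-transformed; magnitude spectra are
   rotation-invariant. Works on the uniform-pattern subset (38 entries
   per LBP type for P=8) or the full pattern set (163 entries), with
   optional extra invariants coupling first DFT coefficients of
   adjacent equal-period orbits.
4. **Multi-scale descriptor** (`ffirst.descriptor`) — per-scale features
   from S scales are concatenated in sliding windows of c adjacent
   scales, yielding `n_conc = S − c + 1` descriptors per region
   (defaults S=8, c=5).
5. **Segmentation** (`ffirst.segmentation`) — Otsu thresholding for
   objects on near-uniform background, plus an exact per-radius split of
   a mask into interior (all LBP samples inside) and border (≥1 sample
   outside).
6. **Classification** (`ffirst.classify`) — an explicit feature map
   approximating the histogram-intersection kernel feeds per-class
   linear SVMs (one-vs-all) with Platt-calibrated posteriors; image
   scores fuse window posteriors by max, and interior/border pairs by
   max of sum or product (`a`/`i`/`b`/`ibsum`/`ibprod` variants).
7. **Synthetic fixtures** (`ffirst.fixtures`) — deterministic band-pass
   noise textures (classes distinguished by scale-invariant band
   structure) and serrated leaf-like objects with ground-truth masks, so
   everything is testable without external data.

## CLI

```sh
# generate a synthetic dataset (images + manifest.csv)
ffirst gen-fixtures data/tex --kind texture --classes 5 --per-class 20 \
    --size 128 --rotation 360 --scale-min 0.8 --scale-max 1.25

# train (manifest CSV columns: path,label[,mask_path])
ffirst fit data/tex/manifest.csv runs/model --variant a --seed 0

# predict + evaluate (rank/MRR columns appear when labels are present)
ffirst predict data/tex/manifest.csv runs/model runs/pred.csv
ffirst eval runs/pred.csv
```

Key flags: `--variant {a,i,b,ibsum,ibprod}`, `--mask-mode
{none,otsu,file}`, `--scales S`, `--window c`, `--mode {full,uniform}`,
`--plus/--no-plus`, `--seed`.

## Library example

```python
import numpy as np
from ffirst import MultiScaleConfig, extract_ffirst, train_ova, predict_image
from ffirst.fixtures import gen_texture_dataset

imgs, labels, _ = gen_texture_dataset(3, 10, seed=0, size=96)
cfg = MultiScaleConfig()                  # P=8, S=8, c=5, full set + extras
descs = [extract_ffirst(im, None, cfg) for im in imgs]
model = train_ova(descs[:24], labels[:24], seed=0)
pred = predict_image(model, descs[-1], variant="a")
print(pred.predicted, pred.scores)
```
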