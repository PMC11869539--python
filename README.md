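# imlts — integrated lung-tumor segmentation toolkit

`imlts` is a desk-scale, fully reproducible implementation of an integrated
lung-nodule analysis pipeline for CT images: wavelet Bayesian-threshold
denoising, radiomic feature extraction, semantic segmentation with a
lightweight mobile-style encoder-decoder network, and benign/malignant
classification by a clinical size rule or an RBF-kernel SVM. It is aimed at
researchers who want every stage of such a pipeline as tested, inspectable
library code that runs on a single CPU — no GPU, no external CT collections:
a built-in phantom generator produces CT-like images with exact ground truth.

## The pipeline

1. **Phantom synthesis** (`imlts.phantom`) — images with a bright body
   background, a dark elliptical lung field and ellipsoidal nodules of known
   physical diameter (default 2–30 mm), plus additive Gaussian noise
   (default σ = 20). Masks are rasterized before noise, so ground truth is
   exact; labels follow the 3 mm rule.
2. **Denoising** (`imlts.denoise`) — Z-score normalization and BayesShrink:
   decompose into sub-bands {LL…HH} / {LLL…HHH}, estimate the noise scale
   σ_N = median(|HH|)/0.6745, per band compute the signal scale
   σ_s = √max(σ_b² − σ_N², 0) and soft-threshold at T = σ_N²/σ_s (an optional
   polynomial gain γ(δ) and a √(2 log N²) universal factor are off by default).
3. **Features** (`imlts.features`) — 15 per-nodule features: GLCM contrast
   Σ P(x,y)(x−y)², correlation, homogeneity Σ P/(1+|x−y|) and entropy −Σ P log P;
   area, aspect rate, roundness 4πA/L², perimeter and circularity on the
   largest axial slice; histogram uniformity, mean, variance, raw third/fourth
   central moments and smoothness 1 − 1/(1+σ²).
4. **Segmentation** (`imlts.network`) — a U-NET whose encoder is a stack of
   inverted-residual blocks (1×1 expand → 3×3 depthwise → 1×1 project) with
   skip connections into the decoder and a sigmoid output, trained with Dice
   loss and Adam, learning-rate-on-plateau and early stopping. Implemented
   directly on NumPy arrays with hand-written backpropagation; the desk-scale
   preset (64×64 patches, width multiplier 0.35, ≈30k parameters) trains in
   about a minute on one CPU.
5. **Classification** (`imlts.classify`) — per-component equivalent diameter
   d = 2√(A/π); the size rule (malignant iff d ≥ 3 mm) or an SVM with kernel
   R(a,b) = exp(−‖a−b‖²/s²) on the 15 features.
6. **Evaluation** (`imlts.metrics`) — sensitivity, specificity, precision,
   accuracy, F-score and error rate in percent from TP/TN/FP/FN.

## Worked example

```python
import numpy as np
from imlts import (PhantomSpec, Nodule, generate_phantom, denoise_volume,
                   extract_features, measure_nodule, size_rule_classify)

spec = PhantomSpec(image_shape=(128, 128), spacing_mm=(0.5, 0.5),
                   nodules=(Nodule((64.0, 64.0), diameter_mm=8.0),),
                   noise_sigma=20.0, seed=1)
image, mask, labels = generate_phantom(spec)
clean = denoise_volume(image)
m = measure_nodule(mask)[0]
print(f"diameter {m.equivalent_diameter_mm:.2f} mm -> {size_rule_classify(m)}")
fv = extract_features(clean, mask)
print(f"roundness {fv.roundness:.3f}  entropy {fv.entropy:.3f}")
```

prints

```
diameter 7.92 mm -> malignant
roundness 0.949  entropy 3.530
```

The measured diameter is within one voxel spacing of the specified 8 mm, the
nodule is (correctly) called malignant by the ≥3 mm rule, the near-circular
nodule has roundness close to 1, and the entropy reflects the residual noise
texture inside the ROI.

The same stages are available from the shell:

```bash
imlts synth --n 10 --out data --seed 1
imlts denoise data/train_000.png den.png
imlts features data/train_000.png data/train_000_mask.png --out features.csv
imlts run --seed 1 --out runs/demo     # full pipeline with manifest
```

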