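# crstress

**How much lossy compression can a CNN image classifier tolerate?**

Medical archives routinely store radiology images with lossy JPEG 2000
compression, and compression policies differ across hospitals. `crstress`
is a desk-scale stress-testing pipeline for the question this raises
about deep-learning screening tools: how do classification performance,
cross-condition generalization, compression-as-augmentation, and saliency
fidelity change as the compression ratio (CR) grows?

The package targets the mammography screening setting — four 16-bit views
per study (LCC, LMLO, RCC, RMLO), a malignant vs normal/benign label at
roughly 1:4 prevalence — but runs entirely on its own synthetic phantom
cohort with ground-truth lesion masks, so every experiment is
reproducible from a seed on one CPU.

## What it computes

* **Codec**: JPEG 2000 (OpenJPEG via Pillow) encoding to a *target* CR
  with rate-control bisection; CR = raw pixel bytes / codestream bytes;
  PSNR = 10·log10((2¹⁶−1)²/MSE) dB, with exact reconstructions labelled
  100. CR 1 is lossless.
* **Preprocessing**: each view resized to 30 %, cropped to the chest-wall
  half of columns (minus the fifth of rows away from the breast), and the
  two views of a side concatenated into one network input.
* **Classifier (CNN3)**: three blocks of 6×6/stride-2 convolution +
  BatchNorm + ReLU + 2×2 max-pool, two hidden FC layers, a sigmoid
  output; BCE loss, Adam (lr 1e-4, β₁ 0.9, β₂ 0.999, ε 1e-8); a study is
  malignant if either side scores high (max rule). Implemented as a
  compact, fully seeded numpy engine — gradients are verified against
  finite differences.
* **Evaluation**: subject-level 5-fold cross-validation with a 7:1:2
  train/val/test split; AUROC and AUPRC with fold means, sds and normal
  95 % CIs; the full train-CR × test-CR generalization matrix; mixed-CR
  training-set augmentation.
* **Saliency**: Grad-CAM heatmaps plus a lesion-encapsulation score — the
  fraction of ground-truth lesion pixels inside the top-quantile salient
  region.

See `docs/methods.md` for the model, the phantom design and its
limitations, and every numerical convention.

## Worked example

```python
from crstress import codec, synthdata

study = synthdata.generate_study(7, "malignant", width=256, height=320,
                                 separability=0.8)
pixels = study.views["LCC"].pixels            # (320, 256) uint16
for target in (15, 100, 500):
    r = codec.compress_to_target_cr(pixels, target)
    print(f"target CR {target:>3}: achieved {r.achieved_cr:6.1f}, "
          f"{r.compressed_bytes:6d} B, PSNR {r.psnr_db:5.2f} dB")
```

prints

```
target CR  15: achieved   15.3,  10720 B, PSNR 65.64 dB
target CR 100: achieved   99.4,   1649 B, PSNR 39.08 dB
target CR 500: achieved  481.9,    340 B, PSNR 28.31 dB
```

— the rate controller lands within 10 % of each requested ratio and
fidelity falls monotonically with compression. The end-to-end experiment
(generate a cohort, compress at a CR grid, train five-fold CNN3 models
per condition, evaluate everything on everything) is available as a
library call (`experiment.run_robustness_suite`) or through the CLI:

```sh
crstress generate --n 400 --seed 3 --out cohort/
crstress matrix --data cohort/ --crs 1,15,50,100 --seed 0 --out run/
crstress report --run run/ --out report/
```

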