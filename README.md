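# adrenalct

Two-stage cascade for automatic recognition of adrenal incidentalomas (AIs)
on nonenhanced CT:

1. **Segmentation** — a 3-D residual U-Net (strided-convolution encoder,
   transposed-convolution decoder with skip connections, instance
   normalization) trained with a combined Dice + focal loss, Adam, and a
   multistep learning-rate anneal (×0.9 every 20 epochs), applied with
   overlapping sliding-window inference and connected-component /
   hole-filling postprocessing.
2. **Classification** — per-gland radiomic features (first-order, 3-D shape,
   GLCM, GLRLM, GLSZM, NGTDM) extracted from each segmented adrenal region,
   reduced by a staged variance → correlation → L1-logistic selection, and
   fed to per-side binary classifiers (random forest, logistic regression,
   SVM, k-NN, gradient boosting, naive Bayes) compared by validation AUC.

Evaluation covers DSC / IOU / RVE / HD95 segmentation metrics (with
brute-force test oracles), ROC/AUC with DeLong confidence intervals,
Youden-optimal thresholds, confusion-matrix statistics, and paired DeLong
AUC comparisons (e.g. manual vs automatic segmentation).

Because clinical CT cohorts cannot be shared, the package ships a synthetic
**phantom generator** that renders abdominal-CT-like volumes in Hounsfield
units (air shell, body ellipsoid, spine block, two bi-lobed paraspinal
glands, optional nodules) with paired ground-truth masks. A side's AI label
is positive iff its nodule's shortest diameter exceeds 10 mm, mirroring the
1 cm clinical rule. Every stage of the cascade is therefore trainable and
testable at desk scale with no patient data.

The neural network is implemented directly on NumPy (im2col/GEMM
convolutions with hand-written backward passes and an Adam optimizer), so no
deep-learning framework is required; a small-channel configuration trains in
minutes on one CPU.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including two
scaled-down training runs (~10–12 minutes on one CPU); the rest of the suite
finishes in well under a minute.

## CLI

```bash
adrenalct run-all --profile small --workdir run --seed 11   # full cascade
adrenalct phantom-generate --n 20 --out-dir cohort          # phantoms + manifest
adrenalct split cohort/manifest.tsv --ratio 0.7,0.3         # stratified split
adrenalct eval-seg pred.nii truth.nii                       # DSC/IOU/RVE/HD95
adrenalct extract-features img.nii mask.nii                 # radiomic features
adrenalct infer-seg run/segmodel.npz img.nii out.nii        # sliding-window inference
adrenalct delong a.txt b.txt labels.txt                     # paired AUC test
```

`run-all` executes phantom generation → preprocessing (PLI orientation,
(1, 1, 3) mm spacing, abdominal window W=350/L=40 → [0, 1]) → segmentation
training/inference → postprocessing → segmentation metrics → feature
extraction → per-side classification, writing a config snapshot, per-stage
logs, and `report.json` under the work directory. A YAML config (see
`adrenalct.config.DEFAULTS`) overrides any stage; `--profile small` selects
a desk-scale profile (48×48×24 phantoms, 8-16-32 channels, binary
gland-vs-background segmentation with geometric left/right assignment).

## Layout

```
src/adrenalct/
  io.py            NIfTI volumes/masks + cohort manifests
  phantom.py       synthetic cohort generator, stratified splitting
  preprocess.py    reorient / resample / window, patch sampling, augmentation
  nn/              NumPy conv-net engine (Conv3d, ConvTranspose3d, InstanceNorm, Adam)
  segnet.py        3-D residual U-Net, Dice+focal loss, training, sliding window
  postprocess.py   components, noise removal, hole filling, laterality
  seg_metrics.py   DSC / IOU / RVE / HD95 and cohort aggregation
  radiomics.py     six-family feature bank + staged feature selection
  classify.py      ROC/AUC, Youden, confusion matrices, DeLong, model zoo
  cascade.py       end-to-end orchestration, manual-vs-auto comparison
  pipeline_cli.py  click CLI
  config.py        nested run configuration with recipe defaults
```
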