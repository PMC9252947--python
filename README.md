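# petnorm

Normative modelling of tracer uptake for anomaly detection in paired
functional/anatomical volumes (PET/CT-like data), evaluated end-to-end
on synthetic phantoms.

## The problem

FDG-PET screening produces pairs of co-registered volumes: a CT-like
anatomical channel and a PET-like functional channel in standardized
uptake values (SUV).  Supervised lesion detectors need voxel-wise lesion
annotations, which are expensive.  The normative (anomaly-detection)
alternative trains only on *normal* scans: learn what uptake is expected
given the anatomy, and flag whatever deviates.

The catch is that normal uptake variability is strongly
tissue-dependent — physiologic uptake in the cardiovascular region
spreads over a wide SUV range, while lung uptake is tight.  A detector
built on raw SUV, or on the absolute error against a predicted PET
image, cannot use one threshold that is simultaneously sensitive in
quiet tissue and quiet in busy tissue.

## The method

A 2-D U-Net maps each axial anatomy slice to **two** per-pixel outputs:
the mean E(y_i) and the variance Var(y_i) of the normal-population SUV
at that pixel, trained on normal pairs with the heteroscedastic Gaussian
negative log-likelihood

    L = mean_i [ ½ exp(−s_i) (y_i − μ_i)² + ½ s_i ],     s_i = log σ_i²,

(the aleatoric-uncertainty formulation of Kendall & Gal).  Anomaly
evidence is the per-pixel Z score of the observed PET slice,

    Z_i = (y_i − E(y_i)) / sqrt(Var(y_i)),

so one global threshold means "this many standard deviations above the
local normal range" everywhere.  Lesion candidates are connected
components of {Z > 3}; a candidate is a true positive iff its centroid
lies within 5 mm of a true lesion centroid.  Evaluation runs at three
levels: per-voxel ROC, per-slice ROC on slice-maximum scores, and
per-lesion FROC (sensitivity vs false positives per scan), against two
baselines: raw SUV thresholds (1.0 / 2.0) and absolute prediction error
of a mean-only U-Net (0.5 / 1.0 SUV).

Hospital screening data of this kind are private, so the package ships a
phantom generator as a first-class module: region-structured chest-like
anatomy (air / soft tissue / lung / heart), per-region uptake with
between-scan and within-scan variability (heteroscedastic across
regions), and injectable focal Gaussian uptake lesions with known masks
and centroids.  Ground-truth per-voxel mean/SD volumes make the learned
model directly checkable against the generator.

## Worked example

```bash
petnorm all --config configs/default.yaml --seed 7 --out run7
```

or equivalently from Python:

```python
from petnorm.config import RunConfig
from petnorm.pipeline import run

cfg = RunConfig(out_dir="run7", seed=7)
run("all", cfg)
```

This generates a phantom cohort (60 training normals, 6 evaluation
normals, 12 evaluation scans with one lung and one heart lesion each, at
3 mm isotropic spacing), trains the heteroscedastic U-Net and the
mean-only baseline, writes per-scan Z-score maps as NIfTI, and emits
`run7/evaluation/metrics.json`; with seed 7 it prints:

```
"voxel_auroc":    {"z": 0.989, "suv": 0.892}
"slice_auroc":    {"z": 0.627, "suv": 0.762}
"sensitivity_at": {"1.0": 0.083, "3.0": 0.333, "10.0": 0.625}
```

Read: Z scores separate abnormal from normal *voxels* far better than
raw SUV (0.989 vs 0.892) because the variance head suppresses the
high-variance heart region while staying sensitive in the quiet lung.
The per-slice numbers show the flip side at desk scale: a slice-maximum
Z is dominated by the model's worst boundary artifact in that slice, so
the slice-level Z statistic is noisy here (see `docs/methods.md`,
Known limitations).  The `sensitivity_at` entries are points on the
lesion-level FROC curve (fraction of the 24 lesions detected at ≤1, ≤3,
≤10 false-positive candidates per scan).  `run7/report/report.json` adds
the baseline operating points and the dominance check (Z-score
sensitivity at each baseline's FP rate vs that baseline's sensitivity —
true for all four baselines in this run).

## Layout

- `petnorm.io_volumes` — NIfTI I/O, isotropic resampling, slice iteration
- `petnorm.phantom` — synthetic cohorts, lesions, ground-truth statistics
- `petnorm.nn` / `petnorm.bnn_model` — NumPy U-Net, heteroscedastic training
- `petnorm.anomaly_map` — Z maps, candidate extraction, centroid matching
- `petnorm.evaluation` — ROC / FROC, baselines, method comparison
- `petnorm.experiments` — the three phantom studies
- `petnorm.pipeline` / `petnorm.cli` — on-disk stages and the `petnorm` CLI

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
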