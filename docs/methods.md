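# Methods

## Model

The normative model is a conditional Gaussian per pixel: given an axial
anatomy slice `x`, the functional value at pixel `i` is modelled as
`y_i | x ~ N(mu_i(x), sigma_i^2(x))`.  Both heads come from one 2-D
U-Net (encoder–decoder with skip connections): channel 0 is the mean in
SUV, channel 1 the log-variance `s_i = log sigma_i^2`.  Training
minimizes the heteroscedastic Gaussian negative log-likelihood
`mean_i [ 1/2 e^{-s_i} (y_i - mu_i)^2 + 1/2 s_i ]` on normal scans only,
so the variance head absorbs whatever the anatomy cannot predict —
between-scan physiologic variation plus voxel noise — and does so
per tissue (aleatoric heteroscedasticity).

Anomaly evidence is `Z_i = (y_i - mu_i) / sigma_i`, computed per slice
and stacked into a volume.  Detection is one-sided (`Z > 3`): only
abnormally high uptake is of interest; negative Z appears in the maps
but produces no candidates.  Candidates are 3-D connected components
(26-connectivity by default) of the superthreshold set; each is scored
by its peak Z and matched to ground-truth lesions by the 5-mm
unweighted-centroid rule, nearest lesion only, ties to the smaller
lesion id.

Epistemic uncertainty via Monte-Carlo dropout is available
(`mc_samples > 1` with `dropout_rate > 0`): total variance = mean of
sampled aleatoric variances + population variance of sampled means.  The
default is the deterministic aleatoric-only mode (`mc_samples = 1`,
`dropout_rate = 0`): with dropout active in training but off at
inference, we measured a systematic few-percent bias in the predicted
mean of the small high-uptake region (a known train/test inconsistency
of dropout with ReLU networks), and the package's headline studies do
not depend on epistemic variance.

## Assumptions

- The two channels are co-registered on a common grid (as in PET/CT);
  registration is out of scope.
- Normal uptake given anatomy is unimodal and Gaussian per voxel.  The
  phantom satisfies this by construction; real tissue mixtures need not.
- Slices are processed independently (2-D model, 3-D candidate
  extraction), matching the map-per-slice design.

## Implementation of the network

The U-Net is a compact pure-NumPy implementation: im2col + GEMM
convolutions with explicit backward passes, exact max-pool gradient
routing, nearest-neighbour upsampling, inverted dropout, Adam.  Layer
gradients are verified against central finite differences in float64.
Defaults: depth 3, base 4 channels, 3x3 kernels, He initialization,
float32 training.  This is sized so that the full study suite trains on
one CPU in minutes; capacity is the binding constraint on how sharply
region boundaries are resolved (see Limitations).

Two numerical safeguards matter in practice:

- **Log-variance clamp** `s in [-10, 6]` and a variance floor of 1e-6
  SUV^2 keep the NLL and the Z denominator finite.
- **MSE warm-up + cosine decay.**  Training starts with a few epochs of
  squared-error loss on the mean head only (default: 5 of 20 epochs,
  never more than a quarter of the schedule), then switches to the NLL;
  the learning rate follows a cosine decay to ~0.  Without warm-up the
  NLL can collapse in high-variance regions — the variance head inflates
  first, the `e^{-s}` weight vanishes, and the mean head stops learning
  there (we observed a predicted heart mean near zero in one
  configuration).  Without decay, region-mean estimates oscillate by
  +-5-10% between late epochs and the final snapshot is endpoint luck.
  Both are standard remedies for heteroscedastic regression.

Anatomy input is normalized by a fixed affine `(x + 400)/500` from
config, never by per-slice statistics, which would leak slice content
into the normative prediction.  The target is regressed in raw SUV.

## Phantom generator

Each scan is a chest-like stack: per axial slice an elliptical body
(soft tissue) containing two lung ellipses and a central heart disc in
an air background, extruded along the axial axis, with per-scan jitter
of ellipse centers/axes (+-2% position, +-5% size) so anatomy varies
across the cohort.  Functional values per region r decompose as
`mu_r + b_r + e`, with `b_r ~ N(0, sigma_b_r^2)` drawn once per scan
(inter-subject physiologic variation — this is what makes the variance
head non-trivial) and `e ~ N(0, sigma_w_r^2)` per voxel; SUV is clipped
at 0.  The marginal per-voxel SD, `sigma_r = sqrt(sigma_b^2 +
sigma_w^2)`, is the quantity an ideal normative model predicts, and is
exported as ground truth.

Default regions (label, CT-like HU, mu, sigma_b, sigma_w):

| region | HU | mu (SUV) | sigma_b | sigma_w |
|---|---|---|---|---|
| air | -1000 | 0.10 | 0.01 | 0.02 |
| soft tissue | 40 | 0.80 | 0.10 | 0.15 |
| lung | -700 | 0.40 | 0.05 | 0.08 |
| heart | 70 | 2.50 | 0.80 | 0.40 |

The qualitative ordering (heart >> soft tissue > lung > air in uptake;
heart/lung total-SD ratio ~9.5) mirrors physiologic FDG uptake; the
exact numbers are free parameters.  The air mean is deliberately ~4.5
SD above zero so that clipping at 0 leaves the Gaussian statistics
intact — with a smaller mean, truncation measurably shrinks the pooled
SD of calibrated Z scores.  Anatomy adds N(0, 15 HU) texture noise.
The heart's 30-HU contrast against soft tissue under that noise is the
deliberate hard case: the organ is only separable by context.

Lesions are spherical Gaussian bumps added to the function channel only,
with half-maximum radius `radius_mm` (default 4 mm) and peak amplitude
in multiples of the local region SD (default 5), placed uniformly over
the host region's interior (>= radius_mm from the boundary), truncated
at 3x radius.  The annotation mask is the half-maximum ball — voxels
receiving more than 50% of the peak.  A lower mask fraction would label
rim voxels whose added signal is a fraction of the local noise SD;
no detector can distinguish those from noise, so including them makes
voxel-level evaluation measure the annotation rule rather than the
detector.  A consequence worth noting: the mask radius (= radius_mm)
is smaller than the 5-mm matching radius, so centroid matching tests
the detector, not the annotation geometry.

## What the phantom does and does not emulate

It emulates: anatomy-predictable uptake, tissue-dependent normal
variability with a between-scan component, focal superimposed lesions,
and the train/eval cohort structure.  It does not emulate: realistic CT
texture, respiratory motion or attenuation artifacts, diffuse
abnormality, non-Gaussian uptake distributions, or anatomy-correlated
lesions.  Tests passing on phantoms therefore demonstrate that the
implementation realizes the method's mechanism (variance-aware
normalization beats absolute scores where variability is
heterogeneous), not that the method attains any particular performance
on clinical data.

## Study conditions and problem sizes

- **Calibration**: Z maps from the true generator statistics over
  20 000 single-slice 36x36 phantoms (2.6e7 voxels).  Many small scans
  rather than few large ones because the shared per-scan offsets `b_r`
  correlate all voxels of a region: the standard error of mean(Z) is
  governed by the number of scans (per-scan SD of mean(Z) is ~0.30
  under the defaults), not voxels.
- **Recovery**: 60 training normals of 64x64x24 at 3 mm (~1.5k slices),
  20 epochs (5 warm-up), batch 16, lr 1e-3 cosine; measured on 6
  held-out normals as region-interior averages (2-voxel in-plane
  erosion).
- **Method comparison**: 30 training normals of 64x64x16, 20 epochs,
  lr 2e-3 cosine; evaluated on 4 normal + 10 abnormal scans (20
  lesions), repeated for three seeds, with both the heteroscedastic and
  the mean-only network retrained per seed.  The thinner stacks keep
  three replicates desk-scale while preserving 30 distinct scans, which
  is what the between-scan variance estimate depends on.

## Evaluation conventions

- Per-voxel ROC pools all evaluation scans; positives are annotated
  voxels, negatives all other voxels (no body-mask restriction by
  default; a per-scan evaluation mask is accepted).
- Per-slice ROC uses the slice maximum of each score over the whole
  slice; a slice is abnormal iff it contains an annotated voxel.
- FROC: candidates are fixed at the base threshold (Z > 3); the curve
  sweeps a decision threshold over candidate peak scores, ties grouped.
  FPs/scan divides by all evaluated scans, normal ones included.
  `sensitivity_at_fp_rate` is a step function (no interpolation).
- AUROC is the trapezoid over the full tie-grouped curve and is verified
  against the Mann–Whitney pairwise statistic.

## Design choices where the design was open

- Resampling aligns output voxel centers to the input origin with
  edge-clamped linear (intensity) or nearest (mask) interpolation; the
  interpolation method for the 3-mm working grid is an assumption.
- Candidates are extracted in 3-D with 26-connectivity (6 available);
  centroids are unweighted.
- The FROC operating points come from sweeping candidate peak scores
  above the fixed extraction threshold; this is the standard way to
  trace a curve from a fixed candidate set.
- Whether normal evaluation scans enter the FPs/scan denominator was
  open; they do.

## Known limitations

- Predicted SD in the small high-variance region (heart) runs ~10-30%
  high: near-boundary voxels mix two tissues whose means differ by ~1.7
  SUV, and at base-4 capacity the network resolves the organ boundary
  only approximately, so residual variance there inflates the variance
  head.  More capacity reduces the bias (base 6 roughly halves it) at
  about twice the training cost.
- The per-slice Z-score ROC is noisy at desk scale: a slice-maximum
  statistic over ~4k pixels is dominated by the model's worst boundary
  artifact in that slice.
- FROC sensitivities at low FP rates are limited by boundary artifacts
  producing high-peak false positives; the paper-scale regime (orders of
  magnitude more training data, larger networks) is out of reach on one
  CPU, and the studies here establish orderings (Z beats SUV and
  absolute error), not clinical operating points.
- Determinism holds for a fixed BLAS/thread configuration; across
  different BLAS builds bit-identity of trained weights is not
  guaranteed.
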