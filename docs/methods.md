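# Methods

## The decay model

Every pixel of a TCSPC FLIM acquisition is a histogram of photon arrival
times over the 20 ns laser period (50 MHz repetition). The expected
count in bin k with center τ_k is modelled as

    μ_k = A · [(1 − a₂) w₁ e^(−τ_k/t₁) + a₂ w₂ e^(−τ_k/t₂)] + b

with t₁ = 460 ps fixed (free NAD(P)H), t₂ ∈ [t₁, period/2] the
protein-bound lifetime, a₂ ∈ [0, 1] the bound fraction, w₁, w₂
normalising each exponential over the period so that A is the expected
total signal photons, and b a constant background offset. The
amplitude-weighted mean lifetime t_m = (1 − a₂) t₁ + a₂ t₂ is the
primary readout; a₁ = 1 − a₂ is never stored. The biexponential form is
a deliberate simplification — the bound pool in reality has several
sub-lifetimes — matching how the readout is defined in practice.

No instrument response function is modelled: excitation is treated as
instantaneous at bin 0 and fitting starts at the histogram peak (tail
fit), which sidesteps the rising edge. The background offset is
estimated from the last 5% of bins, where the decays have died off, and
held fixed in the model rather than subtracted from the data (no
flooring artefacts at low counts).

## Fitting routes

`fit_pixel` maximises the Poisson likelihood of a single histogram:
a coarse geometric grid over t₂ initialises bounded L-BFGS-B on
(A, a₂, t₂), restarted from spread starting points
(a₂ ∈ {0.25, 0.5, 0.9} × t₂ ∈ {1000, 2500} ps). Poisson MLE is the
statistically correct treatment of low-count bins; the goodness value is
a reduced Pearson chi-square.

`fit_image` must fit tens of thousands of pixels per acquisition, so it
profiles the same model over a geometric t₂ grid (40 nodes by default):
for each candidate t₂ the two component amplitudes are solved in closed
form by Neyman-weighted least squares (weights 1/max(y, 1)) with
non-negativity clamping, the best node is refined parabolically on
log t₂, and a₂ = s₂/(s₁ + s₂). At the ≥ 10³ photons per fitted
(spatially binned) pixel the pipeline operates on, this agrees with the
per-pixel MLE well inside the acceptance tolerances (region-mean a₂
within 0.05 at 5 × 10³ photons, checked for both routes in the tests).

Pixels are fitted after 3 × 3 spatial binning (clipped at borders) and
only when the binned histogram holds ≥ 100 photons (`min_photons`);
both defaults are exposed in `FitConfig`. Binned histograms are
materialised only for pixels that pass the threshold — an exact
optimisation verified against the dense `bin_spatial` in the tests. The
reported intensity map is always the raw, un-binned photon sum.

## Synthetic acquisitions

The generator emulates the statistical structure of clinical FLIM of
exfoliated cervical cells:

- **Group statistics.** Per-cell t_m is drawn from a normal
  distribution truncated to (t₁ + 1 ps, period/2) and a₂ from one
  truncated to [0.05, 1], with the published group means ± SD:
  t_m 647 ± 137, 805 ± 187, 878 ± 91, 928 ± 70 ps and a₂ 21.7 ± 28.1,
  57.8 ± 31.4, 90.6 ± 13.8, 93.4 ± 8.2 % for cancer (CC), high-grade
  CIN, benign and normal respectively. t₂ follows by inverting the
  mixture formula, clamped to [t₁, period/2]; the truncation bounds
  exist to keep that inversion stable and are package constants, not
  measurements.
- **Phantom geometry.** 2–8 non-overlapping ellipses per field (semi-axes
  5.5–9.5% of the image side, random orientation), a concentric nucleus
  at 35% of the cell radius with 0.7× amplitude (nuclei are dimmer in
  NAD(P)H autofluorescence), and ~500 expected signal photons per pixel
  (±30% between cells) — enough that 3 × 3 binning reaches the
  1.5–4.5 × 10³ photons where the fit is reliable.
- **Photon noise.** Counts are Poisson. Signal photons are drawn per
  decaying pixel; background photons (0.02 counts/bin/pixel, uniform
  over bins — dark counts and ambient light) are drawn as one Poisson
  total and scattered uniformly over (pixel, bin), which by superposition
  is distributionally identical to sampling the summed expectation.
- **Cohort mixing.** Not every image from a cancer patient shows
  malignant cells: each image of a CC / CIN patient is drawn from that
  group's profile with probability 1.0 / 0.75 and from the normal
  profile otherwise; benign and normal patients always draw from their
  own (normal-like) profile. The per-image origin is the ground-truth
  label all classification accuracies are measured against.
- **Artifacts.** `inject_artifacts` adds either one bright
  short-lifetime debris blob in the non-cellular area (kept 2 px clear
  of the cells) or many small bright speckles over a target fraction of
  the cell area — the two failure modes the QC rules must catch.

What the generator does *not* emulate: optical blur and scanning
artefacts, photobleaching, within-cell parameter gradients
(mitochondrial texture), cell overlap and clumping, and the full
morphological variety of clinical smears. Passing tests therefore show
that the analysis recovers the intended statistical structure, not that
it handles every clinical image.

## Preprocessing

Segmentation is Otsu's threshold on the intensity (photon-sum) map over
a 256-bin histogram — intensity is the only channel defined before
fitting completes — followed, in fixed order, by radius-1 disk dilation,
8-connected component labeling, removal of components under 100 px, and
hole filling. The 3 × 3 median smoothing is applied to the t_m and a₂
maps restricted to the mask (off-mask neighbours excluded), not to the
mask itself: smoothing a binary mask would be a degenerate majority
vote, and the step exists to remove noise in the parameter maps.

The qualification (QC) rules operationalise qualitative filtering
criteria with explicit numbers, all config-exposed and none of them
measured constants: reject when the off-mask 99th-percentile intensity
exceeds 1.5× the on-mask one (bright non-cellular debris), when small
(< 25 px) bright (> 2× masked median) speckles cover more than 30% of
the mask (neutrophil clutter), or when the mask holds fewer than 500 px
(at 256²; the pipeline scales this cutoff with field-of-view area).
Known limitation: the rules judge an image *relative to its cell mask*;
if segmentation itself locks onto dominant debris, the ratio rule cannot
fire. In the synthetic pipeline masks are reliable because artifacts are
injected after layout; with real data a plausibility check on the peak
statistics of the masked region is advisable.

Per-image summaries are the modal bin centers of the masked t_m
(20 ps bins) and a₂ (1% bins) distributions, ties to the lower bin.

## Featurization and clustering

Maps are rendered through a five-stop orange→yellow→green→cyan→blue
colormap: t_m over [400, 1400] ps and a₂ over [0, 100]% (display ranges
are package constants), off-mask pixels black. The t_m & a₂ modality
stacks both renderings into six channels and concatenates their feature
vectors (feature-level fusion, 2 × 9216 = 18432), which preserves the
per-modality encoder unchanged.

The default encoder is a deterministic filter bank requiring no
pre-trained weights: the image is cropped to its cell bounding box,
resized to 48 × 48, and 256 fixed random 8 × 8 × 3 filters (seeded,
ReLU) are evaluated on overlapping patches (stride 4); each filter's
response distribution is summarised by 36 evenly spaced quantiles and
the 256 × 36 = 9216 vector is ℓ₂-normalised. Pooling response
*distributions* rather than *positions* is the key design choice: with
a handful of cells per field, positional pooling makes the dominant
feature variance "where the cells happen to lie", and the unsupervised
clustering then partitions by layout instead of metabolic color. The
output geometry matches the final pooled convolutional activation of
AlexNet (256 × 6 × 6), and an actual pre-trained AlexNet backend is
available when torch/torchvision are installed (`cnn` extra); it is not
used in the tests.

PCA mean-centers (no per-feature standardisation — the features share a
scale) and keeps the smallest leading component set reaching 30%
explained variance, the setting found to balance information against
activation noise in the variance sweep {15, 20, 30, 50, 70, 90}%.
Clustering is k-means with k = 2 fixed, k-means++ seeding, 10 restarts,
best inertia wins. The cluster holding the strict majority of
normal-group training images is labeled *normal* (an exact tie is an
error, never a guess); prediction is nearest-centroid with ties resolved
to *normal*, biasing against false positives.

## Patient-level evaluation

A patient's score is 100 × (abnormal images)/(qualified images); a
patient with no qualified images is unscorable, not silently zero. The
reference standard is clinical: CC, high-grade CIN and follow-up
patients with new VIN/VaIN lesions are positive; benign, normal and
lesion-free follow-up patients are negative.

ROC thresholds are −∞, +∞ and the midpoints between consecutive
distinct pooled scores, with *score ≥ threshold ⇒ positive* applied
uniformly; AUC uses the rank (Mann–Whitney) formula with ties counting
one half. The Youden-optimal cutoff maximises J = sensitivity +
specificity − 1; exact ties prefer the higher-specificity boundary, and
the reported cutoff is the midpoint of the two distinct scores
bracketing the optimum, rounded half-up to an integer percent — the one
convention consistent with all three published cutoffs (73.5→74,
67.5→68, 45→45). The packaged validation table is checksum-verified on
load. For the t_m modality the integer cutoff 74 excludes a positive
patient scoring 73.7, reproducing the published observation that the
t_m score has the lower sensitivity; the screening performance reported
for the method comes from the a₂ and t_m & a₂ scores.

## Problem sizes and reproducibility

The end-to-end synthetic trial uses 128 × 128 px fields with 64 time
bins, a training cohort of 14 normal + 5 CC + 4 CIN patients and a
validation cohort of 3 CC + 2 CIN + 8 benign + 7 normal patients, 10
images per patient — a desk-scale configuration that preserves the
cohort structure while keeping a 20-seed trial around seven minutes on
one CPU. All stage randomness (cohort draws, k-means restarts, filter
bank) derives from one global seed through spawned substreams; re-running
any configuration reproduces its outputs exactly.

## Known limitations

- No IRF convolution or deconvolution; histograms whose peak sits late
  in the period lose tail bins to the fit.
- The vectorised image fit assumes a common tail-start bin (the pooled
  histogram peak) per image.
- t₂ is unidentifiable when a₂ ≈ 0 (only t_m is meaningful there), and
  the a₂/t₂ split degenerates as t₂ → t₁.
- QC depends on the mask marking actual cells (above).
- The synthetic trial's near-perfect AUC reflects the generator's clean
  group separation at ~500 photons/pixel; clinical performance is bounded
  by the published validation-table evaluation, not by the simulation.
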