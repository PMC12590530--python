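# Methods

`fibromech` reconstructs, as tested software, the computational chain behind
AFM-based nanomechanical fingerprinting of pulmonary fibrosis: force-volume
maps are reduced to per-pixel Young's moduli, moduli are pooled into
per-specimen elasticity spectra whose lower/higher elasticity peaks (LEP/HEP)
and heterogeneity metrics form the fingerprint, collagen I/III content is
quantified from picrosirius-red polarized histology, a statistical layer
compares groups and stages, and an SVM classifier fuses the optical and
mechanical views.  Because no public specimens accompany this problem, a
first-class synthetic-data generator provides every input with known ground
truth; all quantitative guarantees in the test suite are statements about
recovery of that ground truth.

## Contact mechanics

Each force curve is modeled as a rigid cone indenting an incompressible
elastic half-space:

    F = (2/pi) * tan(theta) * E / (1 - nu^2) * delta^2

with half-open angle `theta = 20` degrees, Poisson ratio `nu = 0.5`, and
indentation `delta = (z - z0) - (d - d0)` (piezo travel minus cantilever
bending).  Working units are nm, nN and kPa; a spring constant in N/m is
numerically an nN/nm, which removes unit conversions from the force channel.
Curves are analyzed on the approach segment only, and only samples with
`F <= 1.8 nN` (the maximum applied load) enter the fit.

**Contact-point detection.** For every candidate split index the curve is
scored as {linear baseline before} + {constrained quadratic after}; the scan
is coarse-to-fine over indices, and a curve whose best split improves the
all-baseline residual by less than 5% is flagged non-contact.  This piecewise
residual scan was chosen over derivative thresholding because it stays stable
at the low signal-to-noise of soft tissue and admits a brute-force oracle
(exhaustive search over split index and modulus), against which the fit is
tested to <0.1%.

**Modulus estimation.** E is the slope of the through-origin least-squares
regression of force on squared indentation, divided by the geometry factor —
a convex, deterministic linearization of the model; `r_squared` is reported
on that same regression.  The synthetic ramp places the true contact point
exactly on the piezo grid, so noiseless curves invert to the generating
modulus at floating-point precision; this is a property of the simulator's
sampling, not of real instruments, and the noisy-recovery tests (reference
gels at 0.5 and 1.0 kPa, mean recovery within 5%) are the claim that carries
over to practice.

**Map QC.** Pixels are rejected for non-contact, non-convergence,
non-positive modulus, or `r_squared < 0.80` (configurable; the threshold and
the minimum of 10 post-contact samples are conservative defaults, since no
published value exists for this step).  A map rejecting more than half its
pixels is flagged unusable but retained with its rejection statistics.

## Elasticity spectra and the fingerprint

Moduli are positive and right-skewed, so spectra live on log10(E):
Freedman–Diaconis histogram, Gaussian KDE with Silverman bandwidth, and a 1-
or 2-component Gaussian mixture fitted by multi-start EM with a fixed seed.
The 1-vs-2 decision is by BIC — peak counting must be an explicit criterion,
and both BIC values are reported with the summary.  Components are labeled by
mean (lower = LEP, higher = HEP) so results are invariant to EM ordering, and
"peak" positions are back-transformed component means in kPa.  Heterogeneity
is summarized by CV% (sample sd over mean, linear scale) and IQR.  Robust
outlier removal, when enabled, runs before density estimation and peak
fitting; the order is recorded on the spectrum object.

Two-spectrum comparison uses the Mann–Whitney U test on a common scale (both
samples divided by the reference spectrum's mean).  Within-sample median
centering is available behind a flag but is not the default for this test:
centering forces both medians to 1, which cancels stochastic ordering almost
exactly for these mixtures and leaves the rank test sensitive to shape only
(measured p = 0.44 on a control-vs-fibrotic pair that is p < 1e-15 on a
common scale).

## Collagen quantification

Tissue is segmented from the brightfield frame as everything not near-white
(value > 0.92 and saturation < 0.08 is background); holes under 64 px are
filled, larger clearings are kept.  Bright pixels of the polarized frame
(value >= 10% of full scale — an absolute gate, so a collagen-free dark frame
yields zero rather than rescaled noise) are classified by hue: collagen I in
the red-orange wrap-around band [315°, 45°], collagen III in the green band
[75°, 165°].  The numeric bands are configuration (echoed into every output)
because only the red-orange-vs-green convention is standard; whether
yellow-green hues belong to collagen III is left to the band edges.
Fractions are reported relative to tissue area, which makes them
magnification-independent.  SHG stacks are averaged pixelwise; SNR is
mean(signal region) / sd(background region), with Otsu fallback masks and an
explicit flag instead of an infinite number for zero-variance backgrounds.

## Statistics

- Median centering divides by the sample median (fold-of-median; the
  subtraction variant is behind a flag) — appropriate for positive moduli and
  equivalent to subtraction on the log scale.
- ROUT outlier removal is implemented for the univariate constant model: the
  robust location is the median, the robust residual scale (RSDR) is the
  68.27th percentile of absolute residuals with an n/(n−1) degrees-of-freedom
  correction, and residual t-ratios are screened by a Benjamini–Hochberg
  step-up schedule at rate Q (default 1%).  On clean normal data the mean
  flagged fraction is held at or below 2Q; below n = 10 nothing is removed.
- Group tests follow the normality-gated scheme: Shapiro–Wilk per group, then
  unpaired t-test or Mann–Whitney U (two groups), one-way ANOVA with
  Bonferroni pairwise t-tests or Kruskal–Wallis with Dunn's post hoc
  (unadjusted rank-sum z by default; the adjustment variant is a parameter).
  Stars: * < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001.
- Spearman correlation is exact for n <= 10 and tie-free inputs: the
  two-sided p doubles the permutation tail (sum of squared rank differences
  at least as extreme in the observed direction), capped at 1, by full
  enumeration.  Ties fall back to midrank rho with asymptotic p and a method
  note.  The n = 6 configuration with two disjoint adjacent rank swaps gives
  rho = 0.886 and p = 0.0333 (12 of 720 permutations in the tail).
- Relative expression uses fold = 2^(−ΔΔCt).

## Synthetic data: what it emulates and what it does not

Tissue elasticity is a two-component log-normal mixture per disease stage:
a soft LEP near 2 kPa and a stiff HEP whose mode (10 → 30 kPa) and weight
(0.03 → 0.40) grow monotonically from control through day-3 inflammation and
day-14 transition to day-21 chronic fibrosis, with the pirfenidone arms
reverting toward control (HEP weight 0.06 preventive / 0.08 therapeutic).
The kPa positions are configuration, not measured values: published spectra
are shown on log axes without printed peak positions.  HEP pixels are
spatially clustered (smoothed-noise threshold at the 1 − weight quantile), so
collagen appears as contiguous patches and sub-grid segmentation is
meaningful.  Per specimen the HEP weight is jittered by a log-normal factor;
from day 14 onward the specimen's collagen fractions track that same factor
(remodeling couples collagen to stiffness) while at day 3 they are drawn
independently (inflammation without remodeling) — this is what makes the
stage-wise correlation analysis recover "no correlation at day 3, strong
correlation at day 21".

Pre-contact baselines are linear tilt plus white noise with contact-point
jitter (defaults 0.5 nm noise, 0.5 nm/µm tilt, 10 nm jitter) — the simplest
artifact set that exercises contact detection.  Histology images realize
collagen fractions with exact pixel counts, so the class map is an exact
oracle; colors carry mild Gaussian noise.  Not emulated: cantilever
hydrodynamics and tip blunting, adhesion and viscoelasticity, stain
variability across scanners, optical aberrations, and any real biological
texture.  Passing tests therefore demonstrate correctness of the analysis
chain under controlled conditions, not performance on real specimens.

## Classification

Each specimen contributes 16 non-overlapping polarized-image tiles (64 px of
a 256 px frame) and 16 non-overlapping 4×4 sub-grids of one 16×16 force map.
Image features are HOG (32-px cells, 8 orientations) plus a uniform-LBP
histogram; AFM features are a 16-bin log-modulus histogram over a global
0.1–1000 kPa range, deciles, median, CV% and IQR.  Cross-validation is
grouped at the specimen level with k = 20; features are standardized inside
each training fold, and hyperparameters (C, and gamma/coef0 where relevant)
are chosen by a grouped inner split of the training specimens.  Reported
accuracies are always test-fold accuracies.

The four kernels are linear, RBF, sigmoid, and a "ReLU" kernel implemented
as the order-1 arc-cosine kernel — the positive-definite kernel whose
feature map is an infinite layer of ReLU units; it is the principled PSD
realization of ReLU-based classification within an SVM.

Fusion concatenates the two per-segment blocks after standardizing each and
scaling it by 1/sqrt(block dimension), so the wide HOG block cannot dominate
the compact AFM block in total variance.  The default cohort (16 control +
17 bleomycin specimens, the bleomycin arm mixing d3/d14/d21 stages) was
designed so that both modalities are informative but individually noisy —
the AFM view is local (16 curves per segment) and the optical view is
tile-level — which is the regime in which fusing them helps; under these
conditions the mean CV accuracies order optical < AFM < fused.

Chance-level checks use iid random relabeling of specimens.  Shuffling the
fixed label multiset without replacement is not used as the null: in grouped
CV at small specimen counts it depletes a test specimen's own label from its
feature cluster's training labels and drives accuracy systematically below
50% (measured ~0.37 at 20 specimens), a known small-sample artifact of
permutation nulls under cross-validation.

External validation trains on one cohort and calls each held-out specimen by
majority vote over its segments; exact ties are flagged indeterminate.

## Problem sizes and numerical choices

Default test and pipeline problem sizes are deliberately desk-scale: spectra
use 3840 moduli per specimen (15 maps × 256), fingerprint-recovery suites use
50 specimens, ROUT calibration uses 100 samples of n = 1000, classifier
experiments use 33 specimens × 16 segments over 25 seeded replicates.  EM
uses 5 restarts at a fixed seed; degenerate inputs (single-pixel spectra,
constant tiles, all-dark frames, zero-variance backgrounds, n < 10 for ROUT,
n < 4 or tied/constant inputs for correlation) return defined, flagged
results rather than exceptions wherever the quantity is still meaningful.
All randomness flows from explicit integer seeds; identical configurations
reproduce byte-identical output tables.

## Known limitations

The Sneddon fit ignores tip-radius (blunt-cone) corrections and
viscoelastic relaxation; the contact-point scan assumes a single contact
event; ROUT is restricted to the univariate constant model; SIFT/SURF
keypoint features are not offered (variable-length outputs do not fit the
fixed-dimension fusion design); the dimensionality-reduction stage of the
classifier is optional and off by default; and no claim is made that
accuracies on synthetic cohorts transfer to real murine or human data.
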