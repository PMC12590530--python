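# fibromech

Nanomechanical fingerprinting of pulmonary fibrosis, from raw AFM
force-displacement curves to a fused mechano-optical classifier.

Pulmonary fibrosis stiffens lung tissue by collagen deposition, and atomic
force microscopy resolves that stiffening at the micrometre scale: a
force-volume map records one force-displacement curve per pixel, each curve
yields a Young's modulus, and a specimen's pooled moduli form an *elasticity
spectrum*.  In fibrotic tissue that spectrum is bimodal — a lower elasticity
peak (LEP) from softened cells and a higher elasticity peak (HEP) from
collagen bundles — and the spectrum shape, its peak positions and its
heterogeneity metrics constitute a nanomechanical fingerprint of disease
stage and treatment response.  `fibromech` implements that analysis chain for
researchers in tissue biomechanics, together with picrosirius-red collagen
quantification, the accompanying statistical toolbox, and an SVM classifier
that fuses the optical and mechanical views.  Since no public dataset exists
for this problem, the package ships a first-class synthetic-data generator
(`fibromech.synth`) with exact ground truth, used by the entire test suite.

## The model at the core

A curve is fitted with the rigid-cone (Sneddon) contact model

    F = (2/π) · tanθ · E/(1−ν²) · δ²,   δ = (z − z₀) − (d − d₀)

with θ = 20°, ν = 0.5, and a 1.8 nN force cap; the contact point z₀ is found
by a piecewise baseline+cone residual scan, and E is the slope of the
through-origin regression of F on δ².  Per specimen, pooled moduli are
decomposed on log₁₀(E) into a 1- or 2-component Gaussian mixture selected by
BIC (lower component = LEP, higher = HEP), with CV% and IQR as heterogeneity
metrics.  Collagen I/III area fractions come from hue-band classification of
crossed-polarizer images (red-orange vs green, gated by brightness and a
brightfield tissue mask).  Group tests, ROUT outlier removal (Q = 1%),
exact-permutation Spearman correlation, and ΔΔCt fold changes mirror the
conventional statistical layer of such studies.  See `docs/methods.md` for
assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from fibromech import forcecurves, spectra, stats, synth

# one synthetic 1 kPa curve with realistic noise, fitted back
curve = synth.simulate_force_curve(1.0, seed=42)
fit = forcecurves.fit_sneddon(curve)
print(f"fitted E = {fit.e_kpa:.3f} kPa (r^2 = {fit.r_squared:.4f})")

# a chronic-fibrosis specimen: one full force map, then the fingerprint
tissue = synth.STAGE_MECHANICS["chronic_d21"]
fmap = synth.simulate_force_map(tissue, seed=0)          # 16x16 curves
emap = forcecurves.analyze_map(fmap)                     # QC-masked moduli
print(f"map: {emap.n_pass}/256 pixels pass QC")

spec = spectra.pool_specimen(
    [forcecurves.analyze_map(synth.simulate_force_map(tissue, seed=s))
     for s in range(15)])                                # pooled n = 3840
s = spectra.decompose_peaks(spec)
print(f"LEP {s.lep_mode:.2f} kPa ({s.lep_weight:.2f}), "
      f"HEP {s.hep_mode:.2f} kPa ({s.hep_weight:.2f}), "
      f"CV% {s.cv_percent:.1f}, IQR {s.iqr:.2f} kPa")
```

This prints:

```
fitted E = 1.002 kPa (r^2 = 0.9992)
map: 256/256 pixels pass QC
LEP 1.82 kPa (0.60), HEP 29.59 kPa (0.40), CV% 129.7, IQR 23.48 kPa
```

The 1 kPa curve is recovered within 0.2% under default noise.  The
fingerprint recovers the generating mixture (true LEP 1.8 kPa, HEP 30 kPa,
weight 0.40) from fitted, QC-masked curves end to end: the HEP near 30 kPa
is the collagen signature that is absent in control-stage specimens, and the
large CV% and IQR are the heterogeneity excess typical of fibrotic tissue.
The small-cohort correlation statistic:

```python
r = stats.spearman_exact([1, 2, 3, 4, 5, 6], [2, 1, 3, 5, 4, 6])
print(f"rho = {r.rho:.3f}, p = {r.p_two_sided:.4f}")   # rho = 0.886, p = 0.0333
```

is exact: all 720 rank permutations are enumerated.

An end-to-end run (simulate → fit → spectra → collagen → stats → classify →
report) is available as a library call or CLI:

```
fibromech all --outdir run1 --seed 7        # writes CSV tables + report.md
```

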