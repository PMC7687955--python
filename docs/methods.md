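# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `somspec`. It is the
place where design decisions that were genuinely open are recorded.

## The synthetic study

The generator (`somspec.synthetic`) emulates a three-arm murine
injury study measured by Raman map microspectroscopy:

* **Design.** 3 groups (sham, moderate TBI, severe TBI) × 6 mice × 2
  retinae, each sample a 20×20 map (400 spectra, 1.5 µm pitch) on a
  605–1715 cm⁻¹ axis at 1 cm⁻¹ spacing — 4800 spectra per group,
  14,400 in total. The brain preset (`brain_config`) has one map per
  mouse (7,200 spectra) and a stronger baseline, emulating hemoglobin
  absorption at a hemorrhagic injury site.
* **Signal.** Seven tissue bands (850, 1003, 1098, 1266, 1337, 1447,
  1660 cm⁻¹) with amplitudes 0.4–1.0 and FWHM 8–26 cm⁻¹; the sharp
  1003 cm⁻¹ phenylalanine line is Lorentzian, the broad mixed
  protein/lipid bands Gaussian. Group effects are multiplicative:
  severe injury raises 850/1098/1337 by 15% and lowers 1003/1266/1660
  by 15%; moderate injury applies ±7%. Sham is the exact null.
* **Heterogeneity.** Each mouse draws one multiplicative factor per
  band, N(1, CV) with CV 0.05 (sham, severe) and 0.10 (moderate),
  shared by both eyes. This makes moderate injury the most
  heterogeneous arm, which is what drives its confusion with sham in
  the classifier — an ordering built in by design, not estimated from
  data.
* **Baseline.** One random positive cubic shape per map (fluorescence
  varies slowly over a 30 µm map), with amplitude varying across the
  grid as a smooth random quadratic field (sd 5% — focus/topography
  drift). Retina maps use baseline scale 0.5, brain maps 2.0, relative
  to band amplitudes ≈ 1. Spatially white per-spectrum baselines were
  rejected: they would make grid neighbours invalid references for
  cosmic-ray repair, which is not how fluorescence behaves.
* **Noise and spikes.** Additive Gaussian noise, σ = 0.05 (≈ 5% of the
  strongest band), intensities clipped at zero. Cosmic rays are
  single-channel spikes, Poisson-distributed per map (mean 3), with
  amplitude 20× the map's 95th intensity percentile; their coordinates
  are recorded in the map provenance as a test oracle.

Where the study design fixes a number (counts, axis, grid, schedule),
the defaults reproduce it exactly. Where it does not (effect sizes,
SNR, baseline scale, spike rate), the values above were chosen once as
plausible for dried-tissue maps at short acquisition times and are
plain configuration fields — they are stand-ins, not estimates.

What passing tests on this generator do **not** show: performance on
real tissue, where band overlap, instrument drift, focus errors and
biological covariates are richer than multiplicative band scaling; the
generator's separability ordering is guaranteed by construction, so
tests verify that the pipeline *recovers* the built-in structure, not
that the structure exists in nature.

## Preprocessing

* **Cosmic-ray repair.** For each spectrum the channelwise median of
  its 4-connected grid neighbours is a clean reference (spikes are
  single-acquisition events, so spatial neighbours are unaffected).
  Channels whose positive residual exceeds `cosmic_k` (default 8)
  robust deviations are replaced by the reference; the robust deviation
  is 1.4826 × the median absolute deviation of that spectrum's
  residuals, the Gaussian-consistent robust sd. Detection is one-sided
  because spikes are strictly positive.
* **Baseline.** Iterative lower-envelope cubic spline with 11 nodes:
  node windows are spaced evenly over the axis, node positions/values
  start at the window minima, and points of the working signal below
  the current spline are raised onto it before the node minima are
  recomputed — this de-biases the noise minima upward. Iteration stops
  when node values move less than 1e-6 of the data range (a relative
  tolerance, so baseline subtraction commutes exactly with positive
  scaling) or after `baseline_max_iter` (100) passes. Output is not
  clipped; slightly negative residuals are information, not errors. On
  a pure cubic the 11-node spline is exact; with the default band set,
  every ~100 cm⁻¹ window contains baseline-only points, and recovered
  peak heights are within 5% (typically < 3%).
* **Normalization.** Unit Euclidean norm before SOM training. The BMU
  metric is cosine similarity, so classification is scale-free either
  way; normalization only stabilizes the weight updates. It is a flag
  (`PreprocessConfig.normalize`) rather than hard-wired, since some
  workflows train on raw counts.
* **Split.** Stratified 80/20 with exactly round(0.2·n_g) spectra per
  group in the test set, deterministic under `split_seed`.

## The supervised SOM

Hexagonal rows×cols layout (odd rows offset 0.5, rows √3/2 apart),
weights initialized from random training spectra plus jitter
(sd 1e-3 × data RMS) and unit-normalized. Training draws a fresh
seeded shuffle each epoch; 5 epochs of the 11,520-spectrum training
split gives the 57,600-presentation schedule. Defaults: learning rate
0.2 → 0.01 linearly, neighbourhood σ from ⅔·max(rows, cols) → 1.0
linearly. A neighbourhood "maintained at ⅔ the edge length" can also
be read as constant throughout training; both readings are available
(`nbh_decay="constant"`), the decaying one is the default because it is
the conventional SOM regime and converges to a finer map. Exponential
decay is available for both schedules. Neighbourhood updates below
1e-6 are skipped (a pure speed cutoff; at σ ≥ 1 it touches nothing
within ~5σ). BMU ties break to the lowest neuron index; everything is
bit-reproducible under a fixed seed.

Supervision attaches hit counts after (not during) weight updates, so
labels never influence the embedding. The discriminant index
contrasts each neuron's share of class-k activations against the mean
share over the other classes and weights the neuron spectra
accordingly; variant normalizations of such discriminant indices exist,
and the hit-share contrast above is this package's single, documented
definition (alternatives are pluggable). Classification takes the majority class at the BMU; a
never-hit BMU falls back to the nearest hit neuron in layout distance
(with 400 neurons and 3 classes some neurons are inevitably empty).
Ties break by declared class order. Evaluation retrains from
`repeats` different initializations (seed + r) and averages
row-normalized percentage confusions, reporting the per-repeat sd of
the diagonal; cross-validation is stratified k-fold (default 10).

## Unmixing and group comparison

Average per-sample spectra and library components are linearly
resampled onto 1200–1714 cm⁻¹ at 1 cm⁻¹ (515 points; linear, not
spline, to avoid ringing at sharp bands), and coefficients solve
min‖y − Dc‖₂, c ≥ 0 by the Lawson–Hanson active-set method
(`scipy.optimize.nnls`); tests assert the KKT conditions (|gradient| <
1e-8 on active coordinates, gradient ≥ −1e-8 on zero ones) and
recovery of constructed mixtures. No intercept column is included by
default since inputs are baseline-subtracted. The shipped component
library is **synthetic** — idealized cardiolipin-like (1266 +
1660 cm⁻¹ dominated), cholesterol-, sphingomyelin- and
cytochrome-c-like profiles — because the measured libraries are not
redistributable; real libraries load from a delimited table.

Group comparison uses the two-pass between/within mean-square F (the
one-pass formula cancels catastrophically when within-group variance is
near zero) with the F distribution for p, plus Welch t-tests of each
injury group against sham. The post-hoc procedure behind "compared to
sham" p-values is a genuinely open choice, so both raw and
Holm-adjusted values are reported and neither is privileged.

## Ratio maps and rendering

The band statistic behind ratio images is the window maximum over
±8 cm⁻¹ (robust to small calibration shifts); trapezoidal area is
available by flag. Pixels with near-zero denominator (< 1e-9) are
flagged invalid and kept, preserving the grid. Hit maps mix class
colors by hit proportion (sham black, moderate purple, severe orange
by default); empty neurons render grey.

## Problem sizes used in tests and the acceptance script

Full-scale training (57,600 presentations × 1111 channels × 400
neurons) is supported but slow; the shipped experiments use the
package's reduced study design — 3 mice per group, 2 eyes, 10×10 maps,
a 10×10 neuron grid, 5 epochs — which preserves the group structure,
the stratified split ratios and the schedule semantics while keeping a
full classification experiment to a few seconds. The discriminant-sign
experiment keeps the study's 6 mice per group (two-class, sham vs
severe): band-level signs rely on mouse-level factors and per-map
baseline residuals averaging out across animals, and 3 animals per arm
are genuinely not enough for that — which is itself a faithful property
of small-n designs. The unmixing experiment uses 6 mice per group
(18 samples), matching the design the ANOVA needs.

## Known limitations

* The generator's noise is signal-independent Gaussian; Poisson shot
  noise is not modelled (downstream methods assume no noise family).
* No optics: the eye's optical path, laser-safety constraints and
  deoxyhemoglobin absorption physics are out of scope; only the
  baseline consequence of the latter is emulated.
* The lower-envelope spline is a documented stand-in for proprietary
  vendor baseline routines; node count matches (11) but outputs will
  differ from vendor software.
* Fitted unmixing coefficients are proportional to component
  contributions only up to the library's completeness; coefficient
  changes must not be read as concentrations of a single molecule.
* The proprietary instrument file format is not read; export spectra
  to two-column text first.
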