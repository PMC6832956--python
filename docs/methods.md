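# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data generators do and do not
emulate.

## Signal model of the synthetic spectra

Each synthetic Raman spectrum is generated as

```
s = a · Σ_k A_k exp(−(ν − c_k)² / 2σ_k²)  +  P(ν̃)  +  w_c · W(ν)  +  ε  +  spikes
```

- **Bands**: Gaussian profiles at the positions that discriminate pollen
  biochemistry (783, 1004, 1065, 1173, 1209, 1263, 1304, 1441, 1590, 1610,
  1637, 1660, 1750 and 2851 cm⁻¹), widths 7–16 cm⁻¹, unit-order amplitudes.
  Gaussian shape is a deliberate simplification (real Raman bands are closer
  to Voigt); the peak function is pluggable.
- **Multiplicative scatter** `a ~ N(1, 0.1²)`, truncated at 0.05, emulating
  sampling-volume and focus variation. This is exactly the term EMSC's *b*
  coefficient must absorb.
- **Fluorescence baseline** `P`: per-class quadratic on the axis rescaled to
  [−1, 1], coefficients of order 2/−0.6/−0.3. Kept at most quadratic by
  construction so that the EMSC basis is *sufficient*: on noise-free data
  correction is exact, which the tests exploit as a closed-loop oracle.
- **Water background** `W`: a deterministic analytic curve (OH bend at
  1640 cm⁻¹ plus the low-wavenumber tail of the OH stretch at ~3250 cm⁻¹,
  small flat offset), weighted ~0.5 per class. Implemented as a function of
  the axis rather than a stored table so every module shares one curve.
- **Noise** ε: i.i.d. Gaussian, default sd 0.02 on unit-amplitude bands.
  Real shot noise is signal-dependent (Poisson); the additive approximation
  is adequate for exercising the pipeline but understates noise on strong
  bands.
- **Cosmic spikes**: Poisson-count (default rate 0.05/spectrum) one-channel
  deltas of 10–100× the spectrum's maximum amplitude.

Every component is stored alongside the spectrum (`GeneratedSpectrum`), and
the generator contract `signal + baseline + water + noise + spikes ==
intensities` holds exactly, so tests can close the loop against ground truth
rather than against re-implementations.

**Axis**: 600–3100 cm⁻¹ in 1200 channels (≈2.1 cm⁻¹/channel), covering the
fingerprint region (758–1800 cm⁻¹) and the CH-stretch band at 2851 cm⁻¹. The
channel count is a stand-in; no instrument grid is implied.

**Taxonomy panel**: 37 taxa in four growth habits (16 grass / 5 herb /
5 shrub / 11 tree; 18 families; 36 genera — two taxa share the genus
*Artemisia*). Class identity is a per-class multiplicative pattern over the
band pool drawn once from a CRC-seeded stream (stable across sessions), with
a habit-level bias so taxa of one habit are spectrally closer to each other
— the structure the HCA screen is supposed to find. The
`separable_profiles` generator instead uses a common backbone with a
controlled amplitude offset rotating through the band pool, so between-class
contrast is a single number (used for the parameter-recovery sweep).

**Bright-field frames**: transmitted-light polarity — background near the
top of the 8-bit range (230), grains as dark disks (60), an optional central
bright void (30% of grains) to exercise hole filling, optional linear
illumination ramp, Gaussian pixel noise. Particle placement is rejection
sampling under a minimum-separation constraint with a bounded retry budget
(`PlacementError` on infeasible packings). Real pollen texture, diffraction
rings and debris are *not* modelled: passing detection tests shows the
chain's logic is correct on its stated contract (disk-like dark particles,
bimodal histogram), not that it is robust to arbitrary field conditions.

## Localization chain

Order: grayscale → threshold → size filter → fill/dilate → blob analysis.

- **Grayscale**: luminance weighting for RGB, then min–max rescale to
  [0, 255]; a constant image maps to zeros.
- **Threshold**: Otsu's between-class-variance criterion on the 256-bin
  histogram, computed directly from cumulative moments; ties resolve to the
  lowest threshold. Foreground is the *dark* class (`value ≤ t`).
- **Size filter**: 8-connected components outside the area band are removed.
  Default band: disk-equivalent areas of 10–100 µm diameter at the
  configured pixel size — the plausible pollen-grain range.
- **Fill/dilate**: the fill stage is an iterated 3×3 morphological closing
  (k dilations then k erosions with the outside treated as foreground), which
  closes voids up to ~k px radius and never shrinks the input; the dilate
  stage is a plain iterated 3×3 dilation. Defaults: fill 3, dilate 1.
- **Blob analysis**: per-component unweighted pixel-mean centroid, area and
  bounding box; x = column, y = row, origin top-left, 0-based.
- **Stage mapping**: affine `stage = A·pixel + offset` plus the frame's
  raster offset (`col·pitch_x`, `row·pitch_y`); the linear part must be
  invertible.
- **Autofocus**: Gaussian + constant offset least-squares fit of a focus
  metric over z; the fitted center is best focus, and a center outside the
  sampled range or a non-peaked metric is a failure, not a result. The
  synthetic focus metric is variance-of-Laplacian.
- **Tilt**: least-squares plane z = a·x + b·y + c over ≥3 non-collinear
  points.

## Preprocessing chain

Fixed stage order — wavenumber calibration, intensity calibration, spike
removal, EMSC, area normalization — recorded in a provenance log together
with per-stage parameters, per-spectrum spike counts and any drops with
reasons (counts in = counts out + logged drops is asserted, never silent).
Reordering normalization before EMSC would change results (normalizing a
spectrum that still contains additive background couples the background into
the scale factor), so the order is enforced by construction and visible in
the log.

- **Wavenumber calibration**: local maxima of the standard's spectrum,
  refined to sub-pixel position by three-point quadratic interpolation,
  paired to the literature peak table (order-based, then
  nearest-within-tolerance after an initial fit; default tolerance
  25 cm⁻¹), least-squares polynomial fit (default degree 3) with a
  strict-monotonicity check. The 4-acetaminophenol shift table bundled as
  `ACETAMINOPHENOL_PEAKS_CM1` carries the standard reference values; tests
  use synthetic surrogate tables so no literature value gates correctness.
  After calibration, spectra are linearly interpolated onto a uniform grid
  (EMSC needs a shared basis).
- **Intensity calibration**: per-channel factors certified/measured, masked
  where the measured lamp is nonpositive; >20% nonpositive channels voids
  the calibration. Optional box smoothing (off by default so the round-trip
  is exact).
- **Spike removal**: residual from a running median (window
  `max(21, 4·width+3)` channels — wide relative to genuine bands so a band
  appears as a *wide* residual feature) thresholded at 8× a robust scale
  (1.4826·MAD, floored at 0.1% of the intensity range so noise-free spectra
  are not over-flagged). A triggered feature's width is its contiguous
  half-trigger support; features narrower than 3 channels are replaced by
  linear interpolation. Unflagged channels are bit-identical to the input.
- **EMSC**: basis [r, w, 1, ν̃, ν̃²] with ν̃ the axis rescaled to [−1, 1] for
  conditioning; ordinary least squares per spectrum; rank-deficiency is an
  error. Correction divides by *b*; |b| below 1e−6 is degenerate and drops
  the spectrum (logged). The default reference is the dataset's
  spike-removed median, detrended by its own least-squares quadratic and
  shifted to a zero floor — the detrend alone leaves exactly zero net area
  (the residual is orthogonal to the constant basis function), which would
  make area normalization degenerate. A user-supplied reference overrides
  this.
- **Area normalization**: division by the plain channel sum over the region
  (full axis by default); the region sum is exactly 1 afterwards.
  Trapezoidal weighting would differ only by a constant on a uniform grid
  and is absorbed by the normalization itself.

## Chemometrics

- **HCA**: Minkowski exponent 5, average linkage (scipy), on per-species
  mean spectra of the fingerprint region. The cophenetic correlation
  coefficient is the Pearson correlation between original pairwise distances
  and first-merge heights; it is exactly 1 on ultrametric inputs and is
  reported as 1 for the two-item case (where the sample correlation is
  formally undefined but the cophenetic distance is exact). Flat 4-group
  cut; each cluster maps to its majority true habit, ties to the
  lexicographically first label.
- **PCA**: full SVD solver; 9 components by default, cumulative explained
  variance reported.
- **SVM**: k(k−1)/2 binary Gaussian-kernel learners (one per genus pair),
  C = 1. Kernel scale defaults to the per-learner median heuristic
  (γ = 1/(2·median²) of the pair's pairwise training distances); a global
  scale can be supplied. Decoding aggregates one-vs-one votes, which for the
  one-vs-one code matrix is equivalent to minimum-Hamming ECOC decoding;
  ties resolve to the lowest label in sorted order.
- **Training design**: 100 samples per class drawn without replacement
  (seeded); the rest is the held-out test set. A class smaller than the
  quota contributes all its samples with a logged warning (or errors in
  strict mode). Train/test disjointness is kept by explicit index
  bookkeeping. Cross-validation is stratified 10-fold over the training
  scores (fold sizes differ by at most one), reporting mean held-out
  misclassification.
- **t-SNE**: Barnes–Hut, angle 0.5, perplexity 30 (clamped to feasibility
  for small groups), PCA initialization, 1000 iterations, seeded.
  Visualization only; the embedding never feeds classification.

## Parameter-recovery study

The end-to-end check generates four classes whose distinguishing band
amplitudes differ by `contrast × noise_sd`, runs the full chain
(generate → preprocess → PCA-SVM), and measures held-out accuracy. At
contrast 5× the noise the chain recovers the generating labels essentially
perfectly; mean accuracy over 10 seeds per point is non-increasing across
the sweep 5, 1, 0.5, 0.35, 0.25. The sweep points were placed to straddle
the accuracy transition (from ceiling to near the 4-class chance level of
25%) so the monotone trend is resolved well above seed noise; at 130
spectra per class each sweep point aggregates 1 200 test predictions.

## Problem sizes

Tests and the acceptance script run at desk scale: 600–1200 channel axes,
25–150 spectra per class, 100 ground-truthed frames for detection, oracle
equivalence up to 12 clustered items (the brute-force oracle is O(n³)), 20
seeds for the chance-level check. These sizes make every statistical
contract measurable with comfortable margins while keeping a full run in
minutes on one CPU.

## Known limitations

- Gaussian bands, additive Gaussian noise and an exactly quadratic
  fluorescence baseline make EMSC's basis sufficient by construction; real
  backgrounds leave model-mismatch residuals the tests do not probe.
- The generator renders featureless disks; detection robustness to texture,
  clumping and debris is out of scope.
- The wavenumber-calibration peak matcher assumes the standard's bands are
  all detectable and unambiguous after the initial order-based pairing;
  heavily contaminated standards would need manual peak tables.
- Hardware control (stages, autofocus loops, spectrograph I/O) is out of
  scope; the stage-geometry code handles coordinates only.
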