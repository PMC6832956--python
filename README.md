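# pollenraman

Computational workflow for **label-free pollen identification by
high-throughput Raman spectroscopy**. An automated screening platform scans a
slide as a raster of bright-field frames, localizes individual pollen grains,
drives the stage to each grain and records a Raman spectrum. This package
implements everything downstream of the camera and spectrograph:

- **Bright-field localization** — 8-bit grayscale conversion, histogram
  (Otsu) thresholding with the grains as the dark class, particle-size
  filtering, hole filling and dilation, blob analysis, pixel→stage coordinate
  conversion, plus autofocus Gaussian fitting and slide-tilt plane estimation.
- **Spectral preprocessing** — wavenumber calibration against a Raman-shift
  standard (4-acetaminophenol), intensity calibration against a certified
  white lamp, cosmic spike removal, extended multiplicative signal correction
  (EMSC), and area normalization.
- **Chemometrics** — growth-habit screening by hierarchical cluster analysis
  (HCA) of per-taxon mean spectra, and per-habit genus identification by
  PCA + one-vs-one Gaussian-kernel SVM with ten-fold cross-validation,
  confusion-matrix scoring and Barnes–Hut t-SNE visualization.
- **Synthetic data** — ground-truthed generators for every input: a
  37-taxon spectral panel (grass/herb/shrub/tree growth habits, 18 families,
  36 genera), bright-field frames with known particle layout, and calibration
  surrogates with known mappings. No measured data ships with the package;
  every analysis is exercised end-to-end on synthetic ground truth.

It is aimed at spectroscopists and palynologists prototyping automated
Raman screening pipelines, and at anyone who needs a tested, self-contained
reference implementation of this preprocessing/chemometrics stack.

## The methods in brief

**EMSC.** Each spectrum *s(ν)* is decomposed by ordinary least squares as

```
s(ν) ≈ b·r(ν) + c_w·w(ν) + p0 + p1·ν̃ + p2·ν̃²
```

with *r* a reference pollen spectrum, *w* a water background, and a quadratic
polynomial in the rescaled axis ν̃ ∈ [−1, 1] absorbing fluorescence. The
corrected spectrum is `(s − c_w·w − p0 − p1·ν̃ − p2·ν̃²)/b`, which removes both
additive backgrounds and multiplicative throughput variation in one step.

**Habit screening.** Per-species mean spectra of the fingerprint region
(758–1800 cm⁻¹) are clustered with average linkage over the Minkowski
distance `(Σ|xᵢ−yᵢ|⁵)^(1/5)`; dendrogram fidelity is reported as the
cophenetic correlation coefficient and the tree is cut into four groups
(grass, herb, shrub, tree).

**Taxonomy.** Within each habit, spectra (fingerprint + high-wavenumber
region, 2800–3045 cm⁻¹) are reduced to 9 principal components; 100 score sets
per genus train k(k−1)/2 one-vs-one Gaussian-kernel SVMs decoded by
error-correcting output codes; performance is estimated by stratified
ten-fold cross-validation and by a held-out confusion matrix with per-class
sensitivity and positive predictive value.

## Worked example

`examples/04_genus_taxonomy_svm.py` generates four spectrally distinct herb
classes (150 spectra each, 10% multiplicative scatter, noise, cosmic
spikes), preprocesses them and runs the per-habit classifier:

```
genera: SynthGenus00, SynthGenus01, SynthGenus02, SynthGenus03
cumulative variance of 9 PCs: 68.56%
one-vs-one binary learners: 6
10-fold CV misclassification: 0.00%
held-out test accuracy: 100.0% (200 spectra)
  SynthGenus00: sensitivity 100.0%, PPV 100.0%
  ...
```

The CV misclassification is estimated inside the 100-per-class training
design; the test accuracy comes from the 50 spectra per class the model never
saw. `examples/03_habit_screening_hca.py` runs the 37-taxon screen and
prints, e.g.:

```
cophenetic correlation coefficient: 0.8289
4-group screening accuracy: 100.0%
```

The other examples cover particle localization (sub-pixel centroid errors on
ground-truthed frames), the preprocessing provenance log, and calibration
round-trips.

## Command line

A thin CLI wraps the library for shell use:

```bash
pollenraman config init                 # dump the default YAML config
pollenraman simulate  -o run            # synthetic spectra + frames + truth
pollenraman detect    --images-dir run -o det
pollenraman analyze   --spectra run/spectra.csv --manifest run/manifest.csv -o out
```

`analyze` writes a full report (HCA screen, per-habit CV rates, confusion
matrices, t-SNE coordinates) plus the effective config and a stage-tagged run
log, so every number is reproducible from config + seed alone.

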