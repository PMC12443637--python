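# Methods

`replicamap` implements the computational workflow for DESI mass-spectrometry
imaging (DESI-MSI) of tissue sections and their nanoneedle *molecular
replicas*: biomolecular imprints of a tissue surface collected on a
nanoneedle substrate and imaged in place of the tissue. The package covers
preprocessing into a common representation, tissue segmentation, region
mapping, section–replica concordance, glioma grade classification,
longitudinal treatment-response screening, and a synthetic phantom generator
that provides ground-truthed study conditions for all of the above.

## Preprocessing model

A raw MSI sample is a raster of pixels, each with one spectrum (m/z,
intensity). The chain applied by `standard_preprocess` is

1. **Lockmass alignment** — each spectrum is recalibrated by a constant
   additive m/z shift placing the most intense local maximum within
   ±0.1 m/z of the reference (m/z 885.5498, the PI 38:4 ion, abundant
   across brain tissue) exactly on the reference. An additive shift (rather
   than resampling) preserves intensities exactly; spectra without a
   detectable lockmass peak (background pixels) are left unshifted and
   counted. For centroided spectra, samples more than 0.05 m/z apart are
   treated as separate peaks when testing for a local maximum.
2. **Quantization** — intensities are summed into uniform half-open bins
   `[lo, hi)`. The default axis spans m/z 600–900 (the lipid range) at
   0.0125 width — half the nominal m/z resolution of a 20,000
   resolving-power time-of-flight in this range — i.e. exactly 24,000 bins.
   A value exactly at the upper edge is dropped; in-range total intensity is
   conserved exactly. Alternatively `pick_peaks` builds a peaks-mode
   representation: local maxima of the cohort-mean binned spectrum whose
   excess over the local median baseline exceeds `snr_threshold` × the local
   noise (1.4826 × sliding-window MAD), retained when present in at least
   `min_fraction` of samples; per-pixel values are sums within ± half the
   expected peak width (m/z / resolving power / 2). This is an explicit
   surrogate for vendor peak identification.
3. **TIC normalization** — each pixel's intensities are divided by their sum
   (total ion current), making them relative abundances. Zero-TIC pixels
   are flagged, never divided. Idempotent up to rounding.
4. **Tissue segmentation** — a representative image is accumulated from
   three channels chosen to be strong across all tissue (defaults 794.55,
   834.53, 886.60); pixels strictly above the image mean are tissue, then a
   3×3 median filter removes salt-and-pepper noise. The filter acts on the
   boolean mask (strict majority of in-bounds neighbours; exact ties go to
   background), which is deterministic and invariant to global intensity
   scaling; filtering the image before thresholding is available as an
   option. The strict `>` rule means a perfectly uniform image yields an
   empty mask — a documented tie-break, not an accident.
5. **Background correction** — every feature is z-scored against its
   background-pixel population (mean/s.d. over non-tissue pixels). By
   construction, background features become standard normal; features with
   zero background s.d. are mean-shifted only and flagged. Applied after
   TIC normalization; the published order is not stated, and correcting on
   the relative-abundance scale keeps the two steps commutative with
   segmentation.

Analyses that compare abundances (correlation, volcano fold changes,
longitudinal series) use the TIC scale; analyses that need comparable
feature scales across samples (clustering, classification) use the
background-corrected scale.

### Working bin width

The pixel-level analyses in the tests, examples and acceptance script run on
a 0.5-m/z binned axis (600 features over m/z 600–900) rather than the
24,000-bin default. This mirrors the role of a peak-picked representation
(one feature ≈ one lipid species, a few hundred features) while keeping
whole-cohort matrices at desk scale; the 24,000-bin property of the default
axis is verified directly on spectra. The bin width is a parameter
everywhere.

## Region mapping

Tissue pixels are clustered by agglomerative hierarchical clustering (Ward
linkage, Euclidean distance) on background-corrected features, cutting the
dendrogram at *k* clusters; above a 20,000-pixel budget a seeded uniform
subsample is clustered and remaining pixels join the nearest centroid.
Clusters are interpreted as regions (grey matter GM, white matter WM,
tumour T, infiltrated I, necrosis N) by marker concordance: the cluster with
the highest mean m/z 888.62 (SHexCer 42:2;O2) is WM, highest 834.53
(PS 40:6) is GM, highest 682.59/736.65 (ceramides) is T; the marker table is
configurable.

Differential abundance between two pixel groups is a per-feature two-tailed
Student's t-test with log2 fold change log2((mean_b + ε)/(mean_a + ε)),
ε = smallest positive matrix value × 10⁻³. The default significance rule is
−log10(p) > 5 together with |log2FC| > 1 (0.5 for the looser variant); no
multiple-testing correction is applied — the rule is a ranking device for
visual confirmation, and it is fully configurable. Features with zero
variance in both groups receive p = 1 and a `flat` flag.

Region areas are pixel counts × (pixel size/1000)² in mm². Axis profiles
bin pixels by their projection on the long side of a rectangle at one-pixel
resolution, averaging across the short side, with distances in mm from the
box edge.

## Section–replica matching

Concordance between a replica and a section is the Pearson correlation of
their *mean tissue spectra* (per-feature mean over tissue pixels on the TIC
scale, before z-scoring). Mean spectra are well defined across differing
pixel counts and yield one value per sample pair; pooled pixel-level
correlation and a log10(x + ε) transform are options. Per replica, the rank
of its own reference section within its correlation row (descending r,
competition ranking for ties, ties flagged) summarizes identifiability; the
random baseline for "rank ≤ k among n candidates" is k/n (0.04 and 0.2 for
k = 1, 5 at n = 25), optionally verified by Monte-Carlo.

## Grade classification

Classification is single-spectrum: each tissue pixel (features m/z 600–900)
is one instance labelled with its sample's grade. Cross-validation is
**leave-one-batch-and-patient-out**: one fold per sample, training rows
exclude every pixel sharing the test sample's patient *or* imaging session.
A programmatic audit asserts the exclusion on every split. The reference
model is L2-regularized, class-weighted logistic regression (C = 1 by
default); decision trees and gradient boosting (XGBoost when installed) are
optional variants, and a seeded random search over a declared grid
(optimizing group-aware validation AUC inside the training fold) replaces
external hyperparameter-optimization frameworks.

Performance is the ROC AUC over pooled held-out pixels, repeated across
seeds (100 by default; 10 in the scaled-down acceptance conditions);
per-sample grade calls are mean predicted probability over the sample's
pixels, thresholded at 0.5. Cross-inference fits per seed on all rows of one
specimen kind and scores all rows of the other; the spec of the published
analysis does not state whether cross-inference was per-fold, and the
full-train variant is the direct reading of "trained on sections, tested on
replicas". Significance uses a sample-level label permutation test
(p = (1 + #{perm median AUC ≥ observed}) / (n_perm + 1)).

Feature importance for the logistic model is exact additive attribution:
contribution of feature j on row x is w_j (x_j − mean_j) with mean_j the
training-set feature mean; contributions plus baseline reproduce the model
logit to machine precision (local accuracy), positive values push toward
high grade. This is the closed form of Shapley attribution for a linear
model with independent features; non-linear models fall back to permutation
importance, explicitly labelled.

Two statistical behaviours worth knowing:

* Leave-one-group-out CV is **pessimistically biased on null data** (pooled
  AUC well below 0.5 at small n): excluding a patient shifts its class mean
  away from it. Null checks therefore use label permutations on the full
  cohort, where the bias is mild, and average over ≥ 20 permutations —
  a single permutation's AUC swings with its accidental overlap with the
  true labels.
* With a strongly learnable signal, permuted-label AUCs are wide; the mean
  over permutations, not any single draw, is the null summary.

## Longitudinal ΔT screen

Live tumour-bearing slices are sampled at day 0 and day 5; arm T1 is
treated from day 3, T0 is control. Per species, abundance is the mean over
tumour-classified pixels (TIC scale), one value per (brain, timepoint, arm).

* **Time effect** (untreated arm): per species, ANOVA on the univariate
  regression of abundance on time (D0 = 0, D5 = 1), brains as observations;
  significant when P < 0.01 and |log2(D5T0/D0T0)| > 2 (pseudocount ε as
  above). Species undetectable at D5 are a separate category, not an
  infinite fold change.
* **Treatment effect**: ΔT0 = [D5T0] − [D0T0], ΔT1 = [D5T1] − [D0T1],
  ΔT = ΔT1 − ΔT0, computed per brain and averaged (each slice is a sample);
  z(ΔT) standardizes ΔT over the species universe (species detected at D0
  in both arms in every brain). Arm-independent drift cancels exactly.
  Significance requires the ANOVA p of the treatment-associated model term
  < 0.01 and |z(ΔT)| > 0.5.

The default model term is the **time × treatment interaction** in
`abundance ~ time + treatment + time:treatment`. The treatment main effect
in the additive model is also emitted (`mode="base"`), but it cannot carry a
day-5-only effect at this design size: with three brains the main-effect
partial F saturates at F = 9 (the unmodelled interaction dominates the
residual), i.e. p ≥ 0.0149 regardless of effect size — a treatment that
starts between the timepoints is, by construction, an interaction. A
`paired` mode adds brain indicator terms to the interaction model; the
interaction and paired calls are checked for concordance on planted
effects. ANOVA p-values come from a partial F-test computed directly
(numpy least squares) for speed across hundreds of species; equivalence
with `statsmodels.anova_lm` is asserted in the test suite. Zero-residual
designs are kept finite by a 10⁻¹² variance floor and flagged.

## Synthetic phantoms

The generator produces the statistical structure the pipeline assumes,
not instrument physics (no isotope patterns, no desorption modelling,
centroid rendering by default with an optional Gaussian-profile mode).

* **Geometry**: regions are ellipses, bands or annuli in mm; the default
  three-region layout is a GM disc, a WM annulus and a tumour ellipse on a
  64×64 grid of 100-µm pixels. Region priority is list order.
* **Library**: 600 species over m/z 600–900 (the scale of a typical
  common-lipid list). Named marker ions carry the canonical contrasts
  (834.53 GM, 888.62/844.64/860.64 WM, 682.59/716.52/736.65/692.45 T,
  680.54 N, 600.51 GM/I, 788.55/885.55 high grade, 790.55/834.53 low
  grade, 794.55/886.60 pan-tissue segmentation channels). Ten designated
  discriminants carry an 8-fold GM-vs-T contrast; all remaining species are
  nulls with no region contrast. Species occupy distinct 0.5-m/z slots so
  that one analysis feature corresponds to one species (nulls may share a
  slot with each other; sharing is recorded, and planted effects go only on
  exclusive-slot, well-detected species — a fold change of a species at the
  background floor or summed with an unaffected co-resident is unrecoverable
  by design).
* **Noise**: per pixel × species multiplicative log-normal (σ = 0.4 within
  tissue by default) over an additive exponential background floor
  (scale 0.02). "SNR 10" segmentation conditions set the floor scale to 0.1,
  one tenth of the unit species signal. Optional per-spectrum calibration
  drift (uniform, ±range) exercises lockmass alignment.
* **Replicas**: replica abundance = gain × (fidelity × section abundance +
  (1 − fidelity) × independent redraw around the same region means), then an
  integer-pixel misregistration shift. Fidelity 1 with unit gain and no
  shift reproduces the section spectra verbatim. Because matched pairs share
  their patient-specific region means, mean-spectrum correlation stays high
  even at low fidelity; what fidelity controls is the correlation of the
  *deviations* around the expected profile.
* **Grading cohort**: 23 patients (one section + one replica each, 16×16
  grids), alternating grades, patient-specific per-species log-normal
  profile variation (σ = 0.4), sessions assigned by a seeded permutation so
  both grades appear in every session (a single-grade session would
  confound batch with grade), per-session per-species log-normal gain
  vectors (σ = 0.15; a scalar session gain would vanish under TIC
  normalization). Grade effects multiply four marker means by 6, keeping
  each marker's grade shift ≈ 4.5 patient-s.d. on the log scale — a
  deliberately strong planted signal, as a positive-control cohort should
  be.
* **Longitudinal design**: 3 brains × {D0, D5} × {T0, T1} on 48×48 grids.
  Day-5 geometry rescales areas (GM ×1.15, WM ×0.8, tumour ×1.1 untreated /
  ×0.5 treated). Time effects multiply 8 species by 8 and 19 species by 0.1
  at D5 in both arms; treatment effects multiply tumour means in treated D5
  only (692.45 → 0, seven more × 0.25, three × 4).

Everything is deterministic given spec + seed, and ground-truth tables
(masks, labels, per-pixel abundances, effective libraries, effect tables)
are sufficient to compute every downstream expectation without re-reading
spectra.

### What passing on phantoms does and does not show

The phantoms validate the *mechanics and statistics* of the pipeline:
conservation and standardization properties, leak-proof cross-validation,
exact attribution, drift cancellation, and recovery of planted effects under
realistic noise. They do not emulate peak-shape interferences, isotope
envelopes, matrix effects, spatial intensity gradients, or the biological
overlap between real glioma grades — so recovery rates here are upper bounds
on what identical settings achieve on instrument data, and the published
cohort-level performance figures are not reproducible from synthetic
conditions.

## Problem sizes and numerical choices

Tests and the acceptance script use scaled study conditions chosen as the
package's defaults: 64×64 phantoms, 0.5-m/z analysis bins, 23-patient
cohorts at 16×16, 10 evaluation seeds, 20 null permutations, 100,000
Monte-Carlo rank draws. Tolerances: TIC row sums and quantization
conservation at 10⁻¹² relative; background standardization at 10⁻⁹;
attribution local accuracy at 10⁻⁸; p-values floored at 10⁻³⁰⁰; variance
floors at 10⁻¹². Seeds derive from a single master seed by SHA-256 over a
stage tag (`derive_seed`), keeping stages independently reproducible.

## Known limitations

* imzML interchange relies on pyimzml, which cannot encode zero-length
  spectra or zero-spectrum files; empty spectra round-trip through a
  documented sentinel and empty datasets through a stripped-down document.
* `pick_peaks` is a surrogate for vendor peak identification; apex
  positions are bin centres, not fitted centroids.
* The HCA subsampling path makes large-image clustering deterministic but
  budget-dependent; results above the pixel budget depend on the subsample
  seed parameter.
* Cross-inference uses full-cohort training (see above); a per-fold variant
  would be stricter and slightly lower.
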