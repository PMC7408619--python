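# Methods

## Problem and pipeline

`seraspec` implements an analysis pipeline for serum attenuated-total-
reflection Fourier-transform infrared (ATR-FTIR) spectroscopy aimed at
stratifying brain-tumour classes (glioblastoma, primary CNS lymphoma,
meningioma, brain metastasis) against each other and against healthy
controls. A dried serum film's mid-IR absorbance in the fingerprint
region (1800–900 cm⁻¹) superimposes protein (Amide I/II/III), lipid,
carbohydrate/glycogen and nucleic-acid phosphate bands; disease-related
shifts in serum composition perturb their relative intensities.

Because no patient-level spectral data is distributed with this package,
every stage is exercised on synthetic cohorts with *known* class
effects. The synthetic generator is first-class, tested code: it defines
the study conditions under which the pipeline's statistical behaviour is
demonstrated.

## Synthetic cohorts

Spectra are sums of Lorentzian bands `L(ν) = h·γ²/((ν−c)²+γ²)` with
(center c, height h, half-width-at-half-maximum γ) — the same
parameterisation the deconvolution module fits, so generator truth and
fitted parameters are directly comparable. The shipped base template has
21 bands spanning 1750–1012 cm⁻¹ with heights of order 0.04–0.42
absorbance units, dominated by Amide I (seven secondary-structure
sub-bands in 1615–1690 cm⁻¹) and Amide II.

The acquisition model mirrors the 3-well × 3-replicate design (nine
spectra per patient) with four nested noise sources:

| knob           | default | meaning                                             |
|----------------|---------|-----------------------------------------------------|
| `band_sd`      | 0.08    | lognormal relative SD of band heights across patients (shared by a patient's nine spectra) |
| `scatter_sd`   | 0.06    | SD of the log multiplicative per-well gain (film-thickness scatter; what EMSC removes) |
| `replicate_sd` | 0.02    | per-spectrum lognormal height jitter                 |
| `baseline`     | (0.02, 0.01, 0.005) | fixed quadratic baseline on the axis rescaled to [−1, 1] |
| `drift_sd`     | 0.004   | SD of random per-spectrum perturbations of the baseline coefficients |
| `noise_sd`     | 0.0015  | additive white-noise SD, absorbance units            |

No quantitative within- vs between-patient variance decomposition is
available for real serum cohorts of this kind; these defaults were
chosen once to give realistic-looking spectra (patient heterogeneity an
order of magnitude above replicate jitter, baseline drift comparable to
weak bands) and are exposed as calibration knobs, not empirical claims.
Lognormal height factors keep absorbance non-negative by construction.

Class templates multiply base band heights: GBM lowers β-sheet bands
(1637, 1615 cm⁻¹; ×0.80/0.85) and raises α-helix (1658, 1650; ×1.15/1.10),
PCNSL the reverse, metastasis raises the carbohydrate/phosphate cluster
(1012–1080 cm⁻¹; ×1.15–1.30), meningioma gets mild protein shifts. The
*directions* follow reported serum findings for these groups; the
magnitudes are simulation choices.

What the generator does **not** emulate: ATR penetration-depth optics,
water-vapour/CO₂ artefacts, Mie scattering, band-shape asymmetry, or
correlated biological covariation across distant bands. Passing tests
therefore demonstrate that the *pipeline* behaves correctly under its
stated noise model, not that real cohorts would reach any particular
accuracy.

## Preprocessing

Two fixed recipes:

* **Exploration** (`pca_recipe`): cut 1800–900 → rubberband → vector
  normalisation. The rubberband baseline is the lower convex hull of
  (ν, A) between the first and last points (monotone-chain construction,
  piecewise-linear interpolation through hull vertices); the corrected
  spectrum is ≥ 0 and zero at hull contacts, and the operation is
  idempotent.
* **Classification** (`clf_recipe`): EMSC → cut 1800–1000 → min–max to
  [0, 1] → bin 8. The cut interval is closed (801 points on a 1 cm⁻¹
  axis); binning averages non-overlapping groups of 8 (axis and
  absorbance alike) and drops a trailing remainder, giving 100 features.
  Min–max precedes binning, following the listed step order.

EMSC regresses each spectrum on the reference plus a polynomial of
degree 2 (standard order; a recipe parameter) in the axis rescaled to
[−1, 1], via `numpy.linalg.lstsq`, and returns `(A − Σ aₖtᵏ)/b`. The
reference is a fixed input. In the evaluation protocol it is the mean of
the *training-partition* spectra (a `reference_class` option restricts it
to one class when a pooled-serum class exists); it is frozen before any
test spectrum is scored. Spectra with fitted gain |b| < 1e-8 or a
rank-deficient design are rejected.

Savitzky–Golay filtering uses a 7-point window with a cubic local
polynomial — the minimal order that supports a smoothed second
derivative. Derivatives are scaled by the axis spacing
(absorbance·cm^deriv); edge positions whose window leaves the data are
dropped rather than padded, so output axes shrink by 3 points per side.

## Amide I deconvolution

Per class: preprocess each spectrum (rubberband + vector norm by
default — the upstream choice is configurable since class means could
equally be built from the classification recipe), average pointwise,
cut to 1590–1720 cm⁻¹. Sub-band positions are the negative local minima
of the Savitzky–Golay second derivative whose depth exceeds 5% of the
global minimum's depth (`prominence_frac`, small enough to keep genuine
shoulders). Starting heights invert the analytic relation d²L/dν²(c) =
−2h/γ² at γ₀ = 8 cm⁻¹ — a typical Amide I sub-band half-width — with a
1e-6 floor for shallow artefacts.

The fit is bounded trust-region least squares over (c, h, γ) per band:
centers within ±4 cm⁻¹ of initialisation, γ ∈ [3, 30] cm⁻¹, h ≥ 0.
These bounds keep components identifiable in a crowded 130 cm⁻¹ window;
the optimiser never increases the residual of its starting point, and a
hit iteration cap returns the best iterate flagged `converged=False`.
Band count is data-driven through minima detection, not fixed per class.

Structure assignment maps fitted centers through ordered intervals
(first match wins, shared boundaries to the higher interval):
[1682, 1700] β-sheet, (1666, 1682) turn, (1648, 1666] α-helix,
(1642, 1648] disordered, [1600, 1642] β-sheet. The boundaries are
approximate literature values and user-overridable. Fractions are
Lorentzian areas (π·h·γ) per structure over total area; they form a
probability vector by construction.

## Classification and evaluation

Three binary discriminators, each exposing a score whose threshold
reproduces the hard prediction: PLS-DA (PLS regression of the 0/1
response on uncentred-scale features, `scale=False`; positive iff
predicted response ≥ 0.5 — the pipeline's probability threshold), random
forest (500 Gini-split trees grown to purity, mtry = ⌊√p⌋; score =
vote fraction, threshold 0.5; tree count and mtry are community defaults
for spectral work, not tuned), and linear SVM (soft margin; signed
decision value, threshold 0 — this package's analogue of the 0.5
probability threshold). Class imbalance is handled by up-sampling,
down-sampling or SMOTE (k = 5, the technique's canonical default);
synthetic/duplicated rows inherit their seed row's patient id so
patient-grouped operations stay well defined.

The evaluation protocol per resample iteration:

1. stratified patient-level 70/30 split (per-class train count =
   round(0.7·n), all nine spectra of a patient on one side);
2. EMSC reference from training spectra only; classification recipe
   applied to both partitions with that frozen reference;
3. training-row balancing;
4. hyperparameter tuning (PLS-DA ncomp over 1..20, SVM C over
   {0.01, 0.1, 1, 10, 100}) by 5-fold cross-validation maximising mean
   spectrum-level Cohen's κ; folds partition *patients* — the nine
   replicate spectra are pseudo-replicates and must not straddle folds;
   ties go to the simplest grid point;
5. final fit, per-spectrum scoring of test spectra, per-patient majority
   vote (an even-count tie is broken by the patient's mean score against
   the model threshold);
6. patient-level sensitivity (positive class), specificity (negative
   class) and balanced accuracy.

Summaries are means ± sample SD (ddof 1) over iterations. Patient-level
ROC scores are the mean per-spectrum score over a patient's test
spectra, pooled across iterations (each patient contributes one point
per iteration in which it fell in the test set); the AUC is trapezoidal
and equals the normalised Mann–Whitney U statistic. Seeding: the master
seed spawns per-iteration child seeds with the iteration index mixed
into the spawn key, so any single iteration is independently
reproducible. An iteration that raises is skipped and recorded; a run
aborts when more than 10% fail.

## Numerical and degenerate-input choices

* Axes are canonically ascending; descending files are reversed on read.
* Rubberband clamps floating-point residue at hull contacts to exactly 0.
* Vector/min–max normalisation reject zero-norm/constant spectra
  (tolerance 1e-12).
* Single-point spectra are legal in memory (a full-width bin produces
  one); files require ≥ 2 axis rows.
* Cohen's κ is defined as 1.0 when both marginals are degenerate and
  agreement is perfect, 0.0 when degenerate and imperfect.
* A constant-score ROC degenerates to the single diagonal step (AUC 0.5).

## Problem sizes used in the shipped checks

The test suite and the acceptance script demonstrate the protocol at
desk scale, chosen as the smallest sizes at which each property is
statistically unambiguous: the structural cohort check uses the full 641
patients (5769 spectra); preprocessing oracles use 200 random spectra;
deconvolution recovery uses a 3-band phantom noiselessly and across 20
noise seeds; protocol calibration uses a 60+60-patient cohort with a
single-band effect ~6× the within-class height SD, 25 resamples for the
real and the patient-permuted null labelling. Headline classification
accuracies reported for real cohorts of this design are not reproducible
here — the patient data is not distributed — so the shipped checks
validate protocol structure and calibration (strong effect ⇒ BA ≥ 90%,
null ⇒ BA ≈ 50%), not clinical performance.

## Known limitations

* Multi-class tournaments are out of scope; every comparison is binary.
* Deconvolution operates on class means, not per patient, and its band
  count depends on the second-derivative noise level.
* PLS-DA "probabilities" are raw predicted responses clipped to [0, 1];
  no Platt scaling or calibration is applied.
* The samplers equalise counts exactly and assume a binary task.
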