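# Methods

This note documents the models, the preprocessing chain, the synthetic-cohort
generator, the numerical conventions and the open design choices behind
`specdiscrim`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

Spectra live in a `SpectrumSet`: one strictly increasing wavenumber axis
(cm⁻¹) shared by an n×m intensity matrix, with per-row spectrum ids, sample
ids and replicate indices. Raman maps (nx × ny × m cubes) unfold to spectrum
sets in row-major order (y fastest within x); unfold/refold is an exact
inverse pair. The unfolding order is a convention only — every downstream
result is invariant to it because spectra are treated exchangeably within a
sample. Per-sample mean spectra (the "MPS" test set) are arithmetic means
over replicates.

Sample metadata uses closed vocabularies: Berden class
{focal, crescentic, sclerotic, mixed}, normal-glomeruli grade {N0 (>25%),
N1 (10–25%), N2 (<10%)}, IFTA grade {T0 (≤25%), T1 (>25%)}, four boolean
lesion flags (necrotising, infiltrate, arteritis, vessel necrosis) and ANCA
serotype {MPO, PR3, negative}. Classification schemes map metadata to binary
labels; samples outside a scheme are excluded and counted (e.g. crescentic
biopsies under focal-vs-mixed, ANCA-negative samples under the serotype
scheme, which compares MPO vs PR3 among seropositives).

CSV is the canonical carrier (wavenumber first column, one column per
spectrum; metadata a separate CSV keyed by sample id). Reading uses
round-trip float parsing so write→read is bit-exact.

## Preprocessing

Fixed stage order: **cut → Savitzky–Golay derivative → vector normalization →
mean-centering.**

- *Cut*: closed interval, default 800–1800 cm⁻¹ (1001 points on a 1 cm⁻¹
  grid). Cutting before filtering keeps out-of-window intensity from leaking
  into the filter edges.
- *Savitzky–Golay*: default 2nd derivative, 51-point window, 2nd-order
  polynomial, requiring a uniform axis (relative tolerance 1e-6). Output is
  scaled by the axis spacing to the power of the derivative order, i.e.
  values are per (cm⁻¹)²; unit-norm scaling afterwards makes this convention
  immaterial, but it is fixed and documented. Edges are handled by evaluating
  the local polynomial fit at off-centre positions (`scipy.signal.savgol_filter`
  with `mode="interp"`), so the length is preserved; the filter reproduces
  polynomials up to its order exactly, hence any constant or low-order
  baseline vanishes identically.
- *Vector normalization*: unit Euclidean norm per spectrum — the conventional
  meaning of "vector normalization" in chemometrics — cancelling
  multiplicative acquisition differences (laser power drift, focus, section
  thickness) exactly.
- *Mean-centering*: column means are **fitted on the training spectra only**
  and subtracted from any later set. Pooled (train+test) centering is
  available behind `center_on="pooled"` for fidelity experiments but leaks
  test statistics and is logged as such.

The whole chain is deterministic; repeated runs are bit-identical.

## Models

All classifiers follow the Model/Results convention: construct with data,
`fit()` returns a results object with `predict`, `decision_scores` and
`summary`. All schemes are two-class.

**PLS-DA.** Single-response NIPALS PLS (PLS1) on a centered 0/1 class code
(the lexicographically second class is coded 1). For one response the weight
step is closed-form (w ∝ Xᵀy per deflation step); score vectors are mutually
orthogonal, and at full rank the predictions coincide with ordinary least
squares (both verified against independent oracles). The latent-variable
count is chosen by leave-one-out CV minimizing misclassification, ties broken
toward the smaller count. The decision threshold is the midpoint of the two
training-class mean predicted responses; a score exactly at the threshold
goes to the class coded 1. Weights carry a deterministic sign convention
(largest-magnitude element positive) so fits are bit-reproducible. The
coefficient vector over wavenumbers is the biomarker readout: `top_peaks`
ranks local maxima of |β| subject to a minimum mutual separation (default
used in studies: 20 cm⁻¹).

**PCA-LDA.** PCA by SVD of the centered matrix (same sign convention;
explained-variance fractions sum to 1 over all components). The LDA consumes
PCA scores; the component count defaults to the smallest k reaching 95%
cumulative explained variance, capped at n − K − 1 so the pooled covariance
stays estimable. LDA is the non-Bayesian pooled-covariance form: class means
x̄ₖ, pooled covariance C = Σₖ (nₖ−1)Sₖ / (n−K), classification by minimum
squared Mahalanobis distance. Priors are ignored; class imbalance enters
only through the means and pooled covariance. Distance ties break toward the
lexicographically first class label. A near-singular pooled covariance is
ridge-regularized with λ = 1e-8·trace(C)/d and logged. Raw-spectrum LDA is
refused when the dimension reaches the sample count.

**GA-LDA.** Chromosomes are binary masks over wavenumber variables with a
popcount bound (defaults 2–30). The cost of a mask is
G = (1/N_V) Σₙ gₙ with gₙ = r²(xₙ, m_own) / min over wrong classes of
r²(xₙ, m_wrong), using class statistics from the training rows restricted to
the mask; fitness is 1/G, capped at 1e12 when perfect separation drives G
below 1e-12 (logged, so the search can proceed past degenerate separability).
Validation rows come from an internal Venetian-blinds split (k = 3) of the
training rows, averaged over the three folds — the held-out test set never
influences selection. Operators: tournament selection (size 2), single-point
crossover (p = 0.60), bitwise mutation, repair to the popcount bounds by
random add/drop, elitism 1 (so the best-fitness history is non-decreasing).
The 10% mutation probability is interpreted as a **per-chromosome expected
flip budget**: the per-bit rate is p·popcount/m, giving p·popcount expected
flips. A literal 10% per-bit rate over ~1000 wavenumbers would randomize
every chromosome each generation, which cannot be the intended operator.

**RBF-SVM.** Soft-margin dual with kernel k(x, z) = exp(−γ‖x−z‖²), γ = 1 by
default; the box constraint C defaults to 1 and an optional internal
validation split tunes it over {0.1, 1, 10}. The solver is libsvm (through
scikit-learn) with a tightened stopping tolerance (1e-7) so KKT conditions
hold to ~1e-6; the fitted model exposes support vectors, dual weights αᵢyᵢ
(which sum to zero) and the bias.

## Validation protocol and metrics

`evaluate_protocol` reports three blocks per experiment, mirroring the
clinical-report layout:

- **Training: TPS** — resubstitution on all replicate spectra;
- **CV: TPS** — Venetian blinds (row i → fold i mod k; default k = 10,
  configurable) or leave-one-out, with folds assigned at the *sample* level
  so replicates of one sample never straddle folds (spectrum-level folding is
  available behind a flag but leaks replicate information);
- **Test: MPS** — the model fitted on all replicate spectra predicts the
  per-sample mean spectra.

Because the mean spectra are means *of the training samples*, the default
Test block is optimistically biased by construction; it reproduces the
reference protocol faithfully, and the zero-effect studies quantify the bias
(≈88% null "Test" accuracy vs chance-level CV). For honest held-out
validation, `holdout_samples` removes chosen samples from the Training/CV
blocks entirely and tests on their mean spectra.

Metrics from confusion counts (positive class = the lesion-present /
higher-grade label): accuracy, sensitivity, specificity in percent;
F-score = 2·SENS·SPEC/(SENS+SPEC), the harmonic mean of sensitivity and
specificity (this field's convention — not the precision/recall F1);
G-score = √(SENS·SPEC), the geometric mean. A literal product form
(SENS·SPEC/100) is retained behind a flag for comparison, but it reproduces
none of the reference report's 39 printed rows, whereas the geometric mean
reproduces all of them — the basis for implementing G as the geometric mean.
Integer reporting rounds half away from zero, which also matches every
printed row. Sensitivity (specificity) with no positive (negative) samples
evaluated is flagged missing, never silently zero. ROC curves sweep unique
score thresholds; AUC is trapezoidal and equals the Mann–Whitney
pair-counting statistic, ties counting one half.

The reference report is ambiguous about whether its CV rows used Venetian
blinds or leave-one-out (both are named in different sections); both schemes
are implemented and selectable, and no attempt is made to resolve the
ambiguity.

## Synthetic cohorts

The generator emulates the acquisition geometry of the reference study:
tissue — 27 samples × 3 map-region spectra (81 spectra, 27 means) with label
frequencies Berden 15 focal / 3 crescentic / 9 mixed, normal glomeruli
21/2/4 (N0/N1/N2), IFTA 20/7 (T0/T1), necrotising 16, infiltrate 10,
arteritis 5, vessel necrosis 4, ANCA 12/12/3 (MPO/PR3/negative); urine — 10
samples × 10 point spectra (100 spectra, 10 means) with the paired-subgroup
frequencies (3 necrotising, 3 infiltrate, 3 T1, 5 focal / 4 mixed /
1 crescentic, 4 MPO / 5 PR3 / 1 negative). Marginal counts are exact; the
joint assignment across attributes is a seeded permutation (the true joint
distribution is unknown).

A spectrum is gain · (baseline + Σ peaks) + Gaussian noise on a 400–2000 cm⁻¹
axis at 1 cm⁻¹ steps. Peaks are Lorentzian by default (the typical Raman line
shape; Gaussian available). The baseline is a cubic polynomial plus one broad
Gaussian hump emulating tissue fluorescence — removed exactly by the
second-derivative filter, by construction. Defaults: per-point noise sd 0.01
(≈1% of a unit-amplitude band), per-replicate lognormal gain σ = 0.2
(the "physical difference between samples" that normalization removes),
per-sample per-peak lognormal amplitude jitter σ = 0.05 (biological
variability between patients).

Class effects are amplitude multipliers (more analyte → stronger band;
optional band shifts exist but default to 0) on fixed marker bands:
tissue — necrotising 1680/1443/1539 cm⁻¹, IFTA 891.92 cm⁻¹, infiltrate
1309/1631/1692 cm⁻¹; urine — necrotising 1716/1316/800 cm⁻¹, IFTA
1247/1175/932/1607 cm⁻¹, infiltrate 1458/911 cm⁻¹. The default multiplier is
1.6; the high-SNR variant used by recovery studies is 2.5 with reduced noise
and jitter; the zero-effect variant (multiplier 1.0) is the null.

Two design points deserve emphasis:

- *Identifiability.* Marker bands are deliberately moderate-amplitude
  constituents of the base template (0.25–0.5 against a 0.9 amide-I band).
  On unit-norm spectra, strengthening one band necessarily depresses the
  relative intensity of all others ("closure"), concentrating compensating
  coefficient weight on the strongest bands; if a planted marker were itself
  the dominant band, the compensations could outrank weaker planted markers
  and the ground truth would not be recoverable even in principle. Disease
  markers as minority constituents is also the realistic regime.
- *What passing does not show.* The generator has independent noise across
  wavenumbers (no instrument line-spread correlation), no cosmic-ray spikes
  (an optional concern the reference acquisition already handled), no
  spatial correlation between map regions, and within- vs between-sample
  variance ratios that are stated, not estimated from the real cohort.
  Recovery of planted effects therefore validates the pipeline's mechanics
  and statistics, not its performance on real tissue.

## Validation studies (problem sizes)

- *PLS-DA peak recovery*: 20 seeded high-SNR tissue cohorts per scheme;
  success = every planted center lies within ±5 cm⁻¹ of a top coefficient
  peak, where the top list allows 2 peaks beyond the planted count (the
  closure compensations described above are real structure, not failures)
  with 20 cm⁻¹ minimum separation. A single-planted-band cohort localizes the
  top peak to ±2 cm⁻¹.
- *GA-LDA variable recovery*: two-class Gaussian matrices, n = 160 samples,
  m = 500 variables, 5 planted variables shifted by 3 within-class sd;
  GA population 100 × 40 generations (scaled down from the 200 × 100
  defaults), max 12 features; success = the best chromosome contains ≥4 of
  the 5 planted variables. At small n this criterion is unattainable for any
  search procedure: the Mahalanobis-ratio cost genuinely prefers masks mixing
  a few planted variables with variables whose sample mean difference is
  lucky *in that dataset* (the GA's best mask then beats the all-planted
  mask's own fitness), and the internal validation folds reuse the same
  finite sample, so the luck persists across folds. n = 160 puts the planted
  optimum back on top. Under label permutation, overlap with the planted set
  falls to the hypergeometric chance level.
- *Null behaviour*: zero-effect cohorts, PLS-DA with 3 LVs, 10 seeds. CV
  accuracy sits at chance; chance for a midpoint-threshold classifier is 50%
  (not the majority rate — the threshold is class-symmetric), and the
  binomial interval is computed at the sample level (27 samples), since
  replicate predictions within a sample are correlated.

## Numerical conventions

- Deterministic sign conventions for PCA loadings and PLS weights; all
  stochastic components (generator, GA) consume explicit integer seeds
  through `numpy.random.default_rng`.
- Ridge regularization of near-singular pooled covariances
  (λ = 1e-8·trace/d, logged); GA fitness capped at 1e12 on cost underflow
  (logged); gₙ with a zero wrong-class distance returns +inf (logged).
- Tie rules: LDA distance ties → lexicographically first class; PLS-DA score
  at threshold → class coded 1; LV-count ties → fewest LVs;
  `top_peaks` excludes zero plateaus and breaks magnitude ties by scan order.
- Degenerate inputs raise informative errors: zero-norm spectra, non-uniform
  axes under SG filtering, zero-variance responses, singleton classes,
  schemes with fewer than two samples per class.

## Known limitations

- Binary schemes only (the reference tasks are all two-group after merging);
  no multi-class PLS-DA or SVM.
- No despiking, resampling, or baseline methods beyond derivative filtering;
  instrument-specific file formats are out of scope (CSV in, CSV/JSON out).
- The real cohort's spectra are not public, so the reference report's
  classification numbers are checkable only at the level of metric
  arithmetic and protocol shape, not re-derivable from raw data; model
  rankings on real data are likewise out of reach.
- The GA's latent overfitting at small n (above) is a property of the
  selection cost itself; treat GA-LDA variable lists from small cohorts as
  hypotheses, not biomarkers.
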