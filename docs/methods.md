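# Methods

`eegprognosis` implements an analysis protocol for estimating one-year
seizure-recurrence risk from routine scalp EEG: computational markers are
extracted per 10-s epoch and channel, classifiers are evaluated at the EEG
level under patient-grouped nested cross-validation, and the resulting
predictions feed subgroup, per-marker and survival post-hoc analyses. A
synthetic-cohort generator with known ground truth makes every stage
testable without clinical data. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
studies do and do not demonstrate.

## Preprocessing

Recordings (19 channels, 10-20 placement, 200 Hz, microvolts) are high-pass
filtered at 0.75 Hz and notch filtered at 60 Hz with linear-phase
Hamming-window FIR kernels applied with zero net delay (`mode='same'`
convolution). The high-pass transition band is 0.75 Hz wide and centered on
the cutoff; the notch is 2 Hz wide. Signals are then converted to the
average reference (per-sample across-channel mean subtracted).

Ten-second epochs are cut at protocol time points: every montage change,
every 15 s during hyperventilation, every 15 s for 2 min after it, every
photic-stimulation train, and every eye opening/closure. Epochs that would
overrun the recording are skipped; epoch counts are a deterministic
function of the annotation schedule.

Artifact handling uses per-channel peak-to-peak thresholds tuned by k-fold
cross-validation over epochs (default k=5): for each candidate threshold
(40 log-spaced values between the 10th and 99.9th percentile of the
observed peak-to-peak amplitudes) the mean of retained training epochs is
compared by RMSE to the pointwise median of validation epochs; the
candidate with the lowest mean loss wins, ties going to the smallest
candidate. One threshold map is fitted per recording. Channel-epochs above
threshold are re-estimated by Perrin-style spherical-spline interpolation
(stiffness 4, 50 Legendre terms, regularization 1e-5, unit-sphere
electrode positions fitted to the standard 10-20 montage). Epochs with more
than 30% of channels bad are dropped — a bounded-interpolation-error rule,
since no published drop criterion exists for this protocol.

## Markers

Per epoch and channel, ten univariate markers are computed. Band power (BP)
integrates a DPSS multitaper PSD (time-bandwidth 4, 7 tapers) by Simpson's
rule over ten bands (low/high delta, theta, alpha, beta, gamma:
1-2, 2-4, 4-6, 6-8, 8-10, 10-13, 13-20, 20-40, 40-75, 75-100 Hz), reported
as log10 power with a 1e-12 uV^2 floor; a band-pass-prefiltered variant is
available but the multitaper integral is the default. Peak alpha frequency
(PAF) is the PSD argmax in 8-13 Hz after FIR band-passing; exact ties go to
the lower frequency, and alpha-free input still returns an argmax (logged
at low prominence). The remaining markers are computed on each of the six
Sym5 wavelet detail levels (periodized transform; at 200 Hz the levels
nominally cover 100-50 down to 3.125-1.56 Hz):

* Hurst exponent by rescaled range: R/S averaged over non-overlapping
  windows at ~10 log-spaced sizes from 10 points to half the series, slope
  of log R/S vs log size. Uncorrected R/S is biased toward 0.5 at these
  lengths (simulated fractional Gaussian noise with H=0.3 is recovered
  near 0.39, H=0.7 near 0.7); the estimates stay within the +/-0.15 band
  the validation study checks.
* Line length: sum of absolute successive differences.
* Correlation dimension (Grassberger-Procaccia): Chebyshev delay embedding
  (m=3, tau=5), correlation sum at 20 log-spaced radii between the 5th and
  50th percentile of pairwise distances, least-squares slope of log C vs
  log rho. For long series the distance set is deterministically strided
  to at most 50k pairs before the radii and counts are computed.
* Approximate, sample, fuzzy, permutation and spectral entropy with the
  shared parameters m=3, r=0.25 (fraction of series SD), tau=5, fuzzy
  exponent n=2, ordinal order k=3. ApEn follows Pincus (self-matches,
  Phi_m over N-(m-1)tau templates); SampEn follows Richman-Moorman (both
  dimensions over the same N - m*tau templates, no self-matches); FuzzEn
  uses baseline-removed templates with membership exp(-(d/r)^n) over the
  SampEn template range; PermEn is normalized by log k! and breaks rank
  ties by order of occurrence; SpecEn is the Shannon entropy of the
  multitaper PSD (DC excluded) over log of the bin count. The quadratic
  template-matching statistics run in one fused numba pass per series and
  are verified against independent brute-force references to 1e-10.

Degenerate rules: a constant series scores 0 for every entropy and 0 line
length; Hurst and correlation dimension are flagged missing there; series
shorter than the embedding requires are flagged missing. The lowest two
wavelet levels of a 10-s epoch hold only 63 and 32 coefficients, so their
template-based entropies are frequently missing by construction — this is
the main source of missingness the imputation step handles. A 2000-sample
epoch is not divisible by 2^6, so the periodized wavelet transform pads odd
lengths; energy is conserved to ~1e-4 there and to 1e-8 on commensurate
lengths (the conservation study uses 2048 samples).

Entropy parameters can be re-selected on calibration recordings by
maximizing the ratio of between-recording variance of per-epoch entropies
to the mean within-recording variance, averaged over channels and the four
embedded entropy kinds (computed on one wavelet level, default level 3, or
on the raw series); the shipped defaults are the protocol values above.

Missing values are imputed by chained ridge regressions
(IterativeImputer(Ridge), tolerance 1e-3, at most 10 sweeps, column-mean
initialization, all-missing columns filled with 0 and logged). The imputer
is always fitted on the training side of a split and applied unchanged to
the held-out side; within the nested CV it is fitted per outer-training
fold and reused across that fold's inner loop.

## Evaluation

Epochs are the learning observations; every split keeps all epochs of a
patient on one side (patients are shuffled by seed and dealt round-robin
into folds balanced by patient count). The classifier stack per training
fold is: standardization, L1-regularized linear-SVM feature selection
(columns with nonzero coefficients; if none survive, all are retained with
a warning), then one of four algorithms — L1/L2 logistic regression (liblinear),
RBF-SVM with Platt probabilities, random forest, or LightGBM — with
inverse-prevalence class weights by default. The inner grouped CV (10-fold
by default) selects the selection strength and hyperparameters by
EEG-level aggregated AUC; the outer 5-fold grouped CV scores held-out
epochs, which are aggregated per EEG at a quantile (median by default;
0.1-0.9 supported, linear interpolation).

The cross-validated AUC is the mean of per-fold EEG-level Mann-Whitney
AUCs (midranks; ties count one half). Its variance combines the fold-wise
empirical variances of the AUC influence values (cases: placement among
controls; controls: placement among cases) plus the second-order
U-statistic kernel term auc(1-auc)/(n1 n0) per fold, giving a LeDell-style
normal 95% CI truncated to [0, 1] and a two-sided z test against
AUC = 0.5. The second-order term is asymptotically negligible but
material when a fold holds only a few EEGs per class (without it the
variance is underestimated by ~20% at 12-EEG folds). When the minority
class averages fewer than 8 EEGs per fold the variance is additionally
floored by the Nadeau-Bengio corrected between-fold variance,
(1/K + 1/(K-1))·var(fold AUCs): fold AUCs are positively correlated
through their shared training data, which no within-fold variance can
see, and which dominates in small cohorts. With both refinements the CI's
measured coverage is ~0.95 both in the 60-patient permutation regime and
at n = 200.
An outer fold with a single class triggers refolding with a shifted seed
(up to 10 attempts). The temporally shifted holdout protocol selects
hyperparameters by grouped CV on the training split alone, refits on all
training data, scores the held-out split once per EEG, and reports a
DeLong CI (structural-component variance) plus sensitivity, specificity,
PPV and NPV at a 0.5 threshold with exact binomial intervals; overlapping
patients between splits are an error. p-values are reported unadjusted,
with an optional Bonferroni switch in the run configuration.

Model variants: age interactions (scaled age appended plus age x feature
products, statistics fitted on the training rows) and two-step clinical
rules (EEGs flagged IED-positive or lesion-positive score 1.0, the rest
keep the model score).

## Post-hoc analyses

Subgroup AUCs recompute the LeDell interval within strata of age group
(18-40, 40-60, >60), sex, focal lesion, IED status, slowing, ASM count
(0, 1, >=2) and epilepsy type, using the existing fold assignment; strata
with fewer than 5 EEGs per class are reported as not estimable (an explicit
reproducible cutoff; the source protocol reports such strata as unreliable
without naming one). Per-marker comparison repeats the nested CV per marker
subset with an injected, shared outer-fold assignment whose hash is logged
with every run. Predicted risk is dichotomized at the cohort mean (strict
inequality; median available as a switch) and related to the censored
time-to-recurrence outcome with a Cox proportional-hazards model (lifelines,
Efron ties) controlled for z-scored age, sex and ASM count; separation
triggers a ridge (1e-3) refit, and proportionality is screened with the
scaled-residual trend test (violations logged, not fatal — at the nominal
5% level about one covariate in twenty flags spuriously). Kaplan-Meier
curves with Greenwood CIs and the logrank test describe the groups, with
one-year survival read at 52 weeks.

## Synthetic cohorts

The generator emulates the statistical structure the analysis exploits,
not scalp physiology. Per channel the background is unit-SD pink (1/f)
noise mixed with a fixed 25% AR(0.95) share, scaled to 10 uV. A shared
alpha source (Gaussian spectral bump, bandwidth 1.5 Hz, posterior-weighted,
8 uV at the strongest channel) carries the class effects: its log10 power
shifts by 0.2 per unit of standardized band-power effect times the
patient's latent risk (about one within-class SD of epoch-level log10
alpha power per unit), and its center frequency moves from 10.5 Hz by the
configured PAF effect in Hz (clipped to 8.2-12.8; because the marker takes
an argmax inside 8-13 Hz, injected shifts beyond ~-1.5 Hz are compressed
at the band edge — a -2 Hz injection is recovered as about -1.7 Hz).
The regularity (entropy) contrast is carried by a risk-scaled
quasi-periodic fronto-temporal beta component (17-21 Hz sine, 7 uV per
unit effect at the strongest channel): a near-periodic oscillation makes
the beta-band wavelet coefficients more predictable, lowering ordinal and
fuzzy entropy and the correlation dimension there by roughly one SD per
unit. (Re-coloring Gaussian noise through an AR mixing weight was tried
first and measurably cannot move band-limited entropies; spatially uniform
components are likewise nulled by the average reference, so every injected
component has a non-uniform scalp profile.) A separate constructed family,
`bp_contrast`, adds a fixed-power narrowband beta source whose center
frequency slides from ~21 Hz toward low beta with risk while staying inside
one wavelet level: band powers flip between the low- and high-beta bands
while level energies and the unimodal within-level spectral shape stay
flat, yielding a contrast carried almost exclusively by the band-power
marker (used by the marker-ranking study, where an alpha-power shift would
leak into line length and spectral entropy).

Spike-wave transients (70 ms triangular spike plus 300 ms half-sine slow
wave, 3x background SD, focal weighting over four neighboring channels)
are inserted at a Poisson rate interpolating between the class-specific
IED rates; boxcar artifacts (10x SD, 0.5-2 s, 1-3 channels) exercise the
peak-to-peak rejection. The annotation schedule mimics a rotating-montage
routine EEG at reduced duration (montage change every 150 s, one 90-s
hyperventilation, photic trains 4-22 Hz, eye events every 60 s), fully
configurable.

Clinical covariates (age, sex, ASM count, IED status, lesion, slowing,
epilepsy type) are drawn with class-dependent frequencies shaped like a
routine-EEG referral population. The one-year recurrence indicator is
Bernoulli at the configured prevalence; the latent risk is that indicator
plus N(0, 0.25) noise, so recurring patients sit near risk 1 and the
others near 0. Censored event times are drawn *conditionally* on the
indicator from the exponential-hazard model (hazard lambda0 exp(beta *
risk)); cases get a truncated exponential inside [0, min(52, follow-up)]
weeks and non-cases either a post-52-week event or censoring, so the
prevalence contract and the outcome/time/censoring invariants hold exactly.
Follow-up is uniform on 26-156 weeks. When the baseline hazard is left
unset it is calibrated by quadrature and root finding so the expected
observed one-year recurrence equals the prevalence. The unconditional
generator (`simulate_outcomes`) keeps the pure exponential model for
survival-recovery studies.

What passing the synthetic studies shows: the estimators agree with
independent references, the CV machinery is leak-free and honestly
calibrated, injected effects of known size and sign are recovered, and the
pipeline is deterministic. What it does not show: performance on real EEG,
where volume conduction, non-stationarity, sleep structure, medication
effects and label noise are all absent from this generator; the headline
clinical accuracies of the source cohort are not reproducible without its
private data.

## Validation-study sizes

The built-in studies (driven by `scripts/acceptance.py` and the acceptance
test module) run at desk scale, chosen once as the package's own
configuration: entropy oracles on ~12 series of length 40-100; marker
sanity at length 2000-2048 with 30 seeds; null calibration with 20
repetitions of a 10-inner/5-outer nested CV, each on a freshly drawn
60-patient cohort (4 epochs each, PAF features, small logistic grid) with
zero injected effects and equal spike-wave rates so the label permutation
is an exact null — a shared cohort would make the repetitions co-vary
through its chance structure, and class-dependent generation would leak
signal into permuted labels via their overlap with the true ones;
effect recovery on 40 patients x 3 epochs with all three families injected
at 1.5 standardized units and reduced hyperparameter grids (logistic, SVM,
random forest, LightGBM); marker ranking over 10 simulation seeds of
24 patients x 2 epochs on a 10-channel montage with the band-power-only
sliding-beta contrast; AUC-inference
coverage with 500 replicates at n=200; survival recovery with 200
replicates at n=500 (true hazard ratio 2) and 200 Kaplan-Meier replicates
against the closed-form exponential; and a 16-patient end-to-end pipeline
run executed twice for bitwise determinism. Cohort draws that violate the
nested-CV precondition (fewer patients in a class than outer folds) are
redrawn with a shifted seed before any signal synthesis.

## Known limitations

* The EDF layer implements the 16-bit EDF/EDF+C subset this pipeline needs
  (1-s records, one annotation channel); it is not a general EDF library.
* R/S Hurst is used uncorrected (no Anis-Lloyd small-sample adjustment).
* PAF is an argmax: without an alpha peak it returns in-band noise.
* The cross-validated-AUC CI is a normal approximation; the second-order
  and between-fold corrections restore near-nominal coverage at tens of
  EEGs, but below ~5 EEGs per class per fold no standard estimator is
  reliable (the subgroup analyses therefore refuse such strata).
* The inner CV reuses the outer-training imputation fit rather than
  re-imputing per inner fold (a deliberate cost/benefit choice; the
  train/held-out contract is preserved at every outer and holdout split).
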