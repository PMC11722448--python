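# Methods

`swaykit` implements a complete analysis pipeline for smartphone
accelerometer tests of postural control: a standing-balance ("postural
sway") test in three stances and an outstretched-hand ("pronator
drift") test for each hand. The pipeline turns raw 50 Hz tri-axial
recordings into named digital biomarkers, filters them by test-retest
reliability, screens them against clinical and imaging outcomes, and
aggregates them into regularized linear models of neurological
disability. Because no patient-level recordings ship with the package,
a synthetic cohort generator with planted, configurable effect sizes
plays the role of the study data; every downstream stage is validated
against what the generator planted.

## Signal model of the synthetic generator

Each trial is ~9.5 s of tri-axial acceleration at 50 Hz. Horizontal
body sway is modelled as a sum of 2–4 randomly damped sinusoids with
frequencies below ~3 Hz plus AR(1) noise, normalized to unit standard
deviation and scaled by a trial amplitude

    amp = base · stance · exp(a·(age−45)) · exp(k·d) · exp(b_subj + w_trial)

with `base = 0.03 m/s²` (a plausible quiet-stance horizontal
acceleration SD for a young healthy adult), stance difficulty factors
1.0 / 1.35 / 1.9 for eyes-open-feet-apart, eyes-open-feet-together and
eyes-closed-feet-together (ordered by sensory challenge), age
coefficient `a = 0.022 /yr`, disability coefficient `k = 0.28` acting
on the latent disability `d`, and Gaussian log-amplitude effects
`b_subj ~ N(0, 0.35²)` per subject and `w_trial ~ N(0, 0.35²)` per
trial. The between/within split fixes the true test-retest ICC of
log-amplitude biomarkers at σ_b²/(σ_b²+σ_w²); the defaults give 0.5,
the retention boundary, so reliability estimates spread realistically
to both sides of the cutoff. Drift trials add a narrowband 4–8 Hz
tremor whose amplitude scales with the subject's per-hand cerebellar
panel score, and a 1.15× non-dominant-hand amplitude factor.

The signal is embedded in a device frame tilted by a fixed per-subject
rotation within ±15° of nominal mounting (so the calibration stage does
real work), gravity (9.81 m/s²) is carried on the vertical axis, and
white sensor noise (SD 0.01 m/s²) is added to all three axes.

Latent disability is 0 for healthy volunteers and gamma-distributed
per diagnosis elsewhere (means 0.3–3.6 from radiologically isolated
syndrome up to primary-progressive MS). Clinical scales (EDSS 0–10 in
0.5 steps, CombiWISE 0–100, a continuous exam-app total) are bounded
logistic transforms of latent disability plus Gaussian noise whose
variance is set so each scale correlates with the latent truth at a
configurable target (default r ≈ 0.9); exam panel scores and
semiquantitative MRI grades (0–4) are independent noisy monotone
functions of the same latent. What the generator deliberately does
not emulate: biomechanically faithful inverted-pendulum dynamics,
realistic EDSS step distributions, correlated missingness, device
dropout, or learning effects across trials — so green tests establish
the correctness and calibration of the *analysis*, not clinical
performance on real patients.

The default diagnosis mix follows the emulated study composition
(13 HV, 21 NIND, 13 OIND, 68 RRMS, 21 SPMS, 23 PPMS, 4 CIS, 1 RIS out
of 164).

## Calibration

Trials are trimmed to their first 9 s (450 samples) — the first-window
rule is deterministic and uses the guaranteed-complete part of the
record. Gravity direction is estimated as the trial-mean acceleration
vector; the frame is rotated by the minimal rotation carrying that
vector onto vertical; the gravity magnitude is subtracted from the
vertical channel; and the two horizontal channels, demeaned per trial,
become the medio-lateral (M-L) and antero-posterior (A-P) series under
the nominal mounting orientation. Per-trial demeaning (rather than
high-pass filtering) was chosen as the simpler, fully deterministic
option and is exposed as a flag. The pointwise radial series
`net_i = sqrt(ml_i² + ap_i²)` is invariant to rotations about the
vertical, which is why hand-held drift trials — whose yaw orientation
is uncontrolled — contribute only Net features.

## Biomarkers

Four measurements per series: RMS `sqrt((1/N)Σa_i²)`; Jerk
`∫(dAcc/dt)² dt` (central differences, trapezoidal integration; Net
Jerk is half the sum of the M-L and A-P integrands); and the first two
spectral moments of the one-sided periodogram — spectral centroid
SC = Σf_k S_k / ΣS_k and spectral spread SS = Σ(f_k−SC)² S_k / ΣS_k.
SS is reported as the variance (Hz²), exactly as the moment formula
defines it. The PSD is a single-taper periodogram of the mean-removed
9 s series (density scaling, Parseval-consistent); 450 samples are too
few for Welch averaging without destroying the 0.1–1 Hz resolution
that sway analysis needs. Analysis bands default to 0.15–10 Hz (sway)
and 0.15–15 Hz (drift): the lower edge excludes DC leakage, the upper
edges cover the sway and tremor bands; both are configurable.

Sway: 4 measurements × 3 directions × (3 stances + 2 cross-stance
ratios) = 60 features. Ratios (eyes-closed:eyes-open feet-together,
i.e. the Romberg ratio, and feet-together:feet-apart) are formed on raw
values; since every feature is then log10-transformed, the ratio
features equal differences of the per-stance log features, making the
before/after-log question moot. Drift: 4 Net measurements ×
{dominant, non-dominant, sum, difference} = 16 features. Raw values
are floored at 1e-12 before log10. The dominant-minus-non-dominant
difference is sign-indefinite, where a plain log is undefined, so it
uses the order-preserving signed transform `sgn(x)·log10(1+|x|/1e-3)`,
recorded as such in the feature dictionary.

## Reliability and outliers

ICC(2,1) — single-measure, absolute-agreement, from the two-way ANOVA
with subjects and trials crossed — is computed over each subject's
first two trials; features with ICC ≤ 0.5 are dropped. The literature
sometimes calls this form "two-way mixed"; the implemented formula is
the canonical two-way-random absolute-agreement one,
`(MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`. A matrix
with zero total variance returns NaN, which the retention filter treats
as not-retained rather than propagating. Outliers of retained features
are masked (set missing, subject kept) beyond the Tukey fences
Q1 − 1.5·IQR / Q3 + 1.5·IQR, with type-7 (linear-interpolation)
quantiles; masking follows the ICC computation, matching the order the
stages are defined in, and both choices are configurable. Masking the
cell rather than dropping the subject preserves cohort size, and the
Tukey mask is invariant to affine rescaling of a feature.

## Association analyses

Pearson correlations between subject-level features (mean over trials,
missing-aware) and outcomes use pairwise-complete deletion — outlier
masking punches holes that listwise deletion would amplify — with
Benjamini-Hochberg FDR adjustment applied once per screen. Binary sex
enters as 0/1 Pearson (point-biserial equivalent). The normative age
model regresses a feature on age over healthy volunteers only and
draws the standard two-sided 95% OLS prediction interval for a new
observation; a subject is flagged abnormal only above the upper bound,
because disability increases sway amplitude — so in-distribution HV
are flagged at the one-sided 2.5% rate, and a group shifted by +3
residual SD is flagged at the normal-tail rate Φ(3 − 1.96) ≈ 85%.
Group differences use two-sided Wilcoxon rank-sum tests for all
diagnosis pairs, BH-adjusted over the pairs.

## Predictive modeling

Subjects are split 80/20 at subject level, stratified by diagnosis,
before any statistic is computed; every training-side artifact is a
pure function of training subjects plus the configured seed, which the
test suite verifies by deleting the validation subjects from the input
and replaying the training stages to byte-identical artifacts.

Features enter a model only if ICC-retained *and* BH-significant
against at least one relevant outcome (test-specific subpanels, the
three global disability scales, and an infratentorial MRI aggregate by
default). Six candidates are fitted per outcome: {ridge, lasso,
elastic net} × {raw standardized features, PCA scores retaining 95%
variance}. Regularization strength is chosen by 5-fold CV over an
11-point log grid from 1e-3 to 1e2 (elastic-net mixing over
{0.1, 0.5, 0.9}), and the tournament winner is the candidate with the
highest cross-validated R² — cross-validated rather than in-sample,
which would trivially favor the weakest penalty. The winner is refit
on the complete training cohort and evaluated on the validation cohort
with Pearson r, R² (1 − SS_res/SS_tot) and Lin's concordance
correlation coefficient, side by side with a univariate regression on
the best single feature (best cross-validated univariate R² on
training). Combined-test models rerun the same tournament on the
union of the independently gated sway and drift blocks for each global
scale. In simulation tests, "support recovery" by a lasso-family
winner means the features with |standardized coefficient| above 10% of
the largest match the planted support exactly; CV-chosen penalties
optimize prediction, not exact sparsity, so an absolute-zero criterion
would measure the penalty grid rather than the selection behavior.

On very small demo cohorts the two gates can pass fewer than two
features; the pipeline then falls back to the ICC ranking and records
the relaxation in the model report, so toy runs stay executable
without silently changing the protocol at realistic sizes.

## Problem sizes and numerical choices

Default test and demonstration runs use cohorts of 16–164 subjects
with 2 trials each; Monte Carlo checks use up to 2000 subjects (ICC
recovery), 10⁵ draws (closed-form CCC and Tukey-rate checks), and 50
replicates for model-selection behavior. Degenerate inputs are
contract errors, not silent results: empty series, short trials,
zero-magnitude gravity estimates, all-zero spectra in the analysis
band, constant outcome vectors, and train/validation overlap all raise
with the offending stage named. Ties and floating-point edge cases are
pinned by convention: type-7 quantiles, first-window trimming, NaN
ICC for zero-variance matrices, and a fixed KFold shuffle seed from
the pipeline configuration.

## Known limitations

Reported validation metrics describe the synthetic cohort, whose
signal-to-noise is set by generator defaults, not by patients; absolute
R²/CCC values should not be read as clinical performance. The M-L/A-P
axis assignment is nominal (the minimal tilt rotation leaves yaw
unresolved), which is immaterial for Net features and for the
generator's axis-exchangeable sway, but real mounted-phone data with
asymmetric sway would need a yaw convention. The exam-app panel
internals, EDSS/CombiWISE scoring algorithms and MRI grading are taken
as given scores, generated, not derived.
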