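# swaykit

Analysis pipeline for smartphone-accelerometer tests of postural
control: a standing-balance (**postural sway**) test recorded in three
stances — eyes open feet apart (EO-FA), eyes open feet together
(EO-FT), eyes closed feet together (EC-FT) — and an outstretched-hand
(**pronator drift**) test for each hand. It is aimed at digital-health
and clinical-research groups who need a tested, reproducible path from
raw 50 Hz tri-axial recordings to disability-relevant digital
biomarkers, without shipping patient data: a synthetic cohort
generator with planted effect sizes stands in for study recordings.

## What it computes

From each calibrated trial (gravity removed via the minimal tilt
rotation, trimmed to 9 s, split into medio-lateral M-L,
antero-posterior A-P, and radial Net series), four measurements:

- **RMS** = √((1/N) Σ aᵢ²) — sway amplitude (m/s²)
- **Jerk** = ∫ (dAcc/dt)² dt — sway jerkiness; Net Jerk averages the
  M-L and A-P integrands
- **SC** = μ₁ = Σ f·S(f) / Σ S(f) — spectral centroid (Hz) of the
  periodogram
- **SS** = μ₂ = Σ (f−μ₁)²·S(f) / Σ S(f) — spectral spread (Hz²)

Sway: 4 measurements × {M-L, A-P, Net} × {3 stances, Romberg ratio
EC-FT:EO-FT, stance ratio EO-FT:EO-FA} = **60 biomarkers**. Drift:
4 Net measurements × {dominant, non-dominant, sum, difference} =
**16 biomarkers**. All are log₁₀-transformed.

Downstream, the pipeline:

1. filters biomarkers by test-retest reliability — ICC(2,1) over each
   subject's first two trials, retention cutoff 0.5 — and masks
   1.5×IQR Tukey outliers;
2. screens Pearson correlations against clinical scales (EDSS,
   CombiWISE, exam-app totals and subpanels) and semiquantitative MRI
   grades with Benjamini-Hochberg FDR adjustment;
3. fits a healthy-volunteer age model with a 95% prediction interval
   and flags abnormally elevated sway, plus pairwise Wilcoxon
   rank-sum tests between diagnostic groups;
4. runs a six-candidate model tournament per outcome — {ridge, lasso,
   elastic net} × {raw features, PCA scores} with 5-fold
   cross-validated R² selection — and evaluates the winner on a
   held-out 20% validation cohort with Pearson r, R², and Lin's
   concordance correlation coefficient (CCC), against the best single
   biomarker.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from swaykit import generate_cohort, calibrate_trial, extract_sway_features
from swaykit.synthetic import SWAY_STANCES

subjects, trials = generate_cohort(
    20, {"HV": 0.5, "PPMS": 0.5}, n_trials=2, seed=7
)
first = subjects[0]
stance_series = {
    t.test: calibrate_trial(t)
    for t in trials
    if t.subject_id == first.subject_id and t.trial_index == 1
    and t.test in SWAY_STANCES
}
vec = extract_sway_features(stance_series)
print(len(vec.values))
print(round(vec.values["RMS_Net_EC-FT"], 3))
print(round(vec.values["RMS_Net_Romberg"], 3))
```

prints

```
60
-1.445
0.125
```

i.e. this healthy subject's eyes-closed radial sway amplitude is
10^-1.445 ≈ 0.036 m/s², and closing the eyes raises the amplitude
10^0.125 ≈ 1.33-fold over the same stance with eyes open (the Romberg
ratio on the log scale).

The full pipeline, from the shell:

```bash
swaykit run-all --seed 1 --n-subjects 60 --out runs/demo
```

writes the cohort table, the 60/16-column feature matrices,
reliability and correlation-screen CSVs, model reports (JSON) and a
manifest with the config hash, all reproducible byte-for-byte under
the same seed.

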