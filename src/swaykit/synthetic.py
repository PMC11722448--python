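"""Synthetic cohort and accelerometer-trial generator.

Emulates a smartphone balance/drift study: subjects with neurological
diagnoses spanning healthy volunteers (HV) to progressive multiple
sclerosis, each contributing repeated 50 Hz tri-axial accelerometer
recordings for three standing-balance stances (eyes open feet apart,
eyes open feet together, eyes closed feet together) and two
outstretched-hand pronator-drift tests.

The generator is the ground-truth side of the analysis pipeline: it
plants known effect sizes (stance difficulty, age, disability, hand
tremor) and a configurable between/within-subject variance split so the
downstream reliability and modeling stages can be validated against the
planted structure.  Every draw is a pure function of ``(seed, subject,
test, trial)`` so identical seeds reproduce cohorts byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation
from scipy.special import expit

SWAY_STANCES = ("EO-FA", "EO-FT", "EC-FT")
DRIFT_TESTS = ("drift_left", "drift_right")
ALL_TESTS = SWAY_STANCES + DRIFT_TESTS

DIAGNOSES = ("HV", "NIND", "OIND", "RRMS", "SPMS", "PPMS", "CIS", "RIS")

#: Mean disease-severity component of ``latent_disability`` per diagnosis.
#: HV is exactly 0 (healthy reference); progressive MS forms are highest.
SEVERITY_MEANS = {
    "HV": 0.0,
    "RIS": 0.3,
    "CIS": 0.6,
    "NIND": 1.2,
    "OIND": 1.4,
    "RRMS": 1.8,
    "SPMS": 3.2,
    "PPMS": 3.6,
}

MRI_REGIONS = ("brainstem", "cerebellum", "medulla_upper_cspine")
MRI_MODALITIES = ("atrophy", "lesion_load")

#: NeurEx-style panel keys supplied per subject.  Panels 7 (spasticity),
#: 8 (muscle strength), 10 (reflexes), 12 (cerebellar) and 14
#: (proprioceptive) are per-hand; 12 and 14 also have lower-extremity
#: scores; 16 is stance & gait.
PANEL_KEYS = tuple(
    [f"panel{p}_{h}" for p in (7, 8, 10, 12, 14) for h in ("left", "right")]
    + ["panel12_lower", "panel14_lower", "panel16"]
)


@dataclass(frozen=True)
class SubjectRecord:
    """One study subject: demographics, diagnosis, clinical and imaging scores.

    ``latent_disability`` is the synthetic ground truth the clinical
    scales are noisy functions of; it must never be used by analysis
    stages (they only see the observable fields).
    """

    subject_id: str
    age: float
    sex: str
    height: float
    weight: float
    dominant_hand: str
    diagnosis: str
    edss: float
    combiwise: float
    neurex_total: float
    neurex_panel_scores: Mapping[str, float]
    mri_scores: Mapping[str, float]
    latent_disability: float

    def __post_init__(self) -> None:
        if not (18.0 <= self.age <= 90.0):
            raise ValueError(f"age {self.age} outside [18, 90]")
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        if abs(self.edss * 2 - round(self.edss * 2)) > 1e-9:
            raise ValueError("edss must be quantized to 0.5")
        if self.latent_disability < 0:
            raise ValueError("latent_disability must be >= 0")
        if any(v < 0 for v in self.neurex_panel_scores.values()):
            raise ValueError("panel scores must be >= 0")
        if any(v < 0 for v in self.mri_scores.values()):
            raise ValueError("MRI grades must be >= 0")


@dataclass(frozen=True)
class RawTrial:
    """One ~9.5 s tri-axial accelerometer record for one test condition."""

    subject_id: str
    test: str
    trial_index: int
    sampling_hz: float
    samples: np.ndarray  # (n, 3) in m/s^2

    def __post_init__(self) -> None:
        if self.test not in ALL_TESTS:
            raise ValueError(f"unknown test {self.test!r}")
        if self.sampling_hz != 50:
            raise ValueError("sampling_hz must be 50")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if self.samples.shape[0] / self.sampling_hz < 9.0:
            raise ValueError("trial shorter than 9 s")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study.

    Amplitudes are horizontal-acceleration standard deviations in m/s^2.
    ``between_subject_sd`` / ``within_subject_sd`` act on log amplitude
    and jointly set the true test-retest ICC of amplitude biomarkers
    (ICC ~ sd_b^2 / (sd_b^2 + sd_w^2)).  ``clinical_r_target`` is the
    Pearson correlation each clinical scale should have with the latent
    disability that generated it.
    """

    sampling_hz: float = 50.0
    duration_s: float = 9.5
    gravity: float = 9.81
    base_sway_amp: float = 0.03
    stance_factors: dict = field(
        default_factory=lambda: {"EO-FA": 1.0, "EO-FT": 1.35, "EC-FT": 1.9}
    )
    age_coef: float = 0.022  # per year of age, multiplicative on amplitude
    disability_coef: float = 0.28  # exp(coef * latent_disability)
    between_subject_sd: float = 0.35  # log-amplitude, across subjects
    within_subject_sd: float = 0.35  # log-amplitude, across trials (inter-day)
    sensor_noise_sd: float = 0.01  # white accelerometer noise, m/s^2
    tilt_deg: float = 15.0  # max random mounting tilt per subject
    tremor_coef: float = 0.012  # tremor amplitude per unit cerebellar score
    tremor_band: tuple = (4.0, 8.0)
    ndom_factor: float = 1.15  # non-dominant-hand amplitude asymmetry
    clinical_r_target: float = 0.9

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic child generator for a (seed, key...) path."""
    h = zlib.crc32("|".join(str(k) for k in keys).encode("utf8"))
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, h])


def _subject_tilt(subject: SubjectRecord, seed: int, tilt_deg: float) -> Rotation:
    """Per-subject phone-mounting misalignment, within +/- tilt_deg of nominal."""
    rng = _rng(seed, "tilt", subject.subject_id)
    angles = np.deg2rad(rng.uniform(-tilt_deg, tilt_deg, size=2))
    return Rotation.from_euler("xy", angles)


def _band_limited_sway(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD sway-like process: damped sinusoids (<3 Hz) plus AR(1) noise."""
    t = np.arange(n) / fs
    sig = np.zeros(n)
    for _ in range(int(rng.integers(2, 5))):
        f = rng.uniform(0.2, 2.8)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        damp = rng.uniform(0.0, 0.15)
        amp = rng.uniform(0.5, 1.0)
        sig += amp * np.exp(-damp * t) * np.sin(2.0 * np.pi * f * t + phase)
    ar = lfilter([1.0], [1.0, -0.9], rng.standard_normal(n))
    sig = sig / max(np.std(sig), 1e-12) + 0.6 * ar / max(np.std(ar), 1e-12)
    return sig / max(np.std(sig), 1e-12)


def _embed(
    ml: np.ndarray,
    ap: np.ndarray,
    subject: SubjectRecord,
    seed: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Embed horizontal sway in a gravity-bearing, tilted device frame."""
    n = ml.size
    body = np.column_stack([ml, ap, np.full(n, config.gravity)])
    tilt = _subject_tilt(subject, seed, config.tilt_deg)
    device = tilt.inv().apply(body)
    if config.sensor_noise_sd > 0:
        device = device + rng.normal(0.0, config.sensor_noise_sd, size=(n, 3))
    return device


def _amplitude(
    subject: SubjectRecord,
    stance_factor: float,
    trial_index: int,
    seed: int,
    config: GeneratorConfig,
) -> float:
    """Trial horizontal-acceleration SD: planted multiplicative effects."""
    subj_effect = _rng(seed, "subj_amp", subject.subject_id).normal(
        0.0, config.between_subject_sd
    )
    trial_effect = _rng(seed, "trial_amp", subject.subject_id, trial_index).normal(
        0.0, config.within_subject_sd
    )
    return (
        config.base_sway_amp
        * stance_factor
        * np.exp(config.age_coef * (subject.age - 45.0))
        * np.exp(config.disability_coef * subject.latent_disability)
        * np.exp(subj_effect + trial_effect)
    )


def simulate_sway_trial(
    subject: SubjectRecord,
    stance: str,
    trial_index: int,
    seed: int,
    config: GeneratorConfig | None = None,
) -> RawTrial:
    """Simulate one standing-balance accelerometer trial.

    Horizontal sway SD scales multiplicatively with the stance
    difficulty factor (EO-FA < EO-FT < EC-FT), an age factor, and
    exp(disability_coef * latent_disability); gravity plus a fixed
    per-subject tilt is embedded in the raw axes and white sensor noise
    added on top.
    """
    config = config or GeneratorConfig()
    if stance not in SWAY_STANCES:
        raise ValueError(f"unknown stance {stance!r}")
    n = int(round(config.duration_s * config.sampling_hz))
    rng = _rng(seed, "sway", subject.subject_id, stance, trial_index)
    amp = _amplitude(subject, config.stance_factors[stance], trial_index, seed, config)
    ml = amp * _band_limited_sway(n, config.sampling_hz, rng)
    ap = amp * _band_limited_sway(n, config.sampling_hz, rng)
    samples = _embed(ml, ap, subject, seed, config, rng)
    return RawTrial(subject.subject_id, stance, trial_index, config.sampling_hz, samples)


def cerebellar_score(subject: SubjectRecord, hand: str) -> float:
    """Per-hand cerebellar dysfunction score driving drift-test tremor."""
    side = "left" if hand == "drift_left" else "right"
    return float(subject.neurex_panel_scores[f"panel12_{side}"])


def simulate_drift_trial(
    subject: SubjectRecord,
    hand: str,
    trial_index: int,
    seed: int,
    config: GeneratorConfig | None = None,
) -> RawTrial:
    """Simulate one pronator-drift (outstretched hand) trial.

    Like a sway trial but with a narrowband 4-8 Hz tremor component
    whose amplitude scales with the subject's per-hand cerebellar score,
    and a configurable dominant/non-dominant asymmetry.
    """
    config = config or GeneratorConfig()
    if hand not in DRIFT_TESTS:
        raise ValueError(f"unknown hand {hand!r}")
    n = int(round(config.duration_s * config.sampling_hz))
    rng = _rng(seed, "drift", subject.subject_id, hand, trial_index)
    amp = _amplitude(subject, 1.0, trial_index, seed, config)
    side = "left" if hand == "drift_left" else "right"
    if side != subject.dominant_hand:
        amp *= config.ndom_factor
    ml = amp * _band_limited_sway(n, config.sampling_hz, rng)
    ap = amp * _band_limited_sway(n, config.sampling_hz, rng)
    tremor_amp = config.tremor_coef * cerebellar_score(subject, hand)
    if tremor_amp > 0:
        t = np.arange(n) / config.sampling_hz
        f = rng.uniform(*config.tremor_band)
        ml = ml + tremor_amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        ap = ap + tremor_amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    samples = _embed(ml, ap, subject, seed, config, rng)
    return RawTrial(subject.subject_id, hand, trial_index, config.sampling_hz, samples)


def _diagnosis_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n subjects to the diagnosis mix."""
    unknown = set(mix) - set(DIAGNOSES)
    if unknown:
        raise ValueError(f"unknown diagnoses in mix: {sorted(unknown)}")
    total = float(sum(mix.values()))
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"diagnosis proportions sum to {total}, expected 1")
    quotas = {d: n * p for d, p in mix.items()}
    counts = {d: int(np.floor(q)) for d, q in quotas.items()}
    short = n - sum(counts.values())
    for d in sorted(quotas, key=lambda d: quotas[d] - counts[d], reverse=True)[:short]:
        counts[d] += 1
    return {d: c for d, c in counts.items() if c > 0}


def _clinical_scales(
    latent: np.ndarray, rng: np.random.Generator, r_target: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EDSS / CombiWISE / NeurEx totals: bounded logistic transforms of
    latent disability plus Gaussian noise scaled to hit ``r_target``."""

    def scale(maximum: float, loc: float, width: float) -> np.ndarray:
        signal = maximum * expit((latent - loc) / width)
        sd = np.std(signal)
        noise_sd = sd * np.sqrt(max(1.0 / r_target**2 - 1.0, 0.0)) if sd > 0 else 0.0
        return np.clip(signal + rng.normal(0.0, noise_sd, latent.size), 0.0, maximum)

    edss = np.round(scale(10.0, 3.0, 1.2) * 2.0) / 2.0
    combiwise = scale(100.0, 3.0, 1.4)
    neurex = scale(400.0, 3.2, 1.5)
    return edss, combiwise, neurex


def generate_cohort(
    n_subjects: int,
    diagnosis_mix: Mapping[str, float],
    n_trials: int = 2,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> tuple[list[SubjectRecord], list[RawTrial]]:
    """Generate a full synthetic cohort with complete trial sets.

    Each subject receives ``n_trials`` complete sets of all five tests
    (three sway stances + two hands).  Clinical outcomes are monotone
    noisy functions of ``latent_disability``; identical seeds give
    identical output.
    """
    config = config or GeneratorConfig()
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if n_trials < 2:
        raise ValueError("need at least 2 trials per subject (test-retest)")
    counts = _diagnosis_counts(n_subjects, diagnosis_mix)
    rng = _rng(seed, "cohort")
    diagnoses = [d for d, c in counts.items() for _ in range(c)]
    rng.shuffle(diagnoses)

    latents = np.empty(n_subjects)
    subjects: list[SubjectRecord] = []
    raw: list[dict] = []
    for i, diag in enumerate(diagnoses):
        srng = _rng(seed, "subject", i)
        mean_sev = SEVERITY_MEANS[diag]
        latent = 0.0 if mean_sev == 0.0 else float(srng.gamma(2.0, mean_sev / 2.0))
        latents[i] = latent
        sex = "F" if srng.random() < 0.6 else "M"
        height = srng.normal(163.0 if sex == "F" else 177.0, 7.0)
        weight = srng.normal(68.0 if sex == "F" else 82.0, 12.0)
        panels = {}
        for key in PANEL_KEYS:
            prng = _rng(seed, "panel", i, key)
            panels[key] = float(max(0.0, 0.8 * latent + prng.normal(0.0, 0.5 * (latent + 0.2))))
        mri = {}
        for region in MRI_REGIONS:
            for mod in MRI_MODALITIES:
                mrng = _rng(seed, "mri", i, region, mod)
                grade = round(latent / 1.2 + mrng.normal(0.0, 0.6))
                mri[f"{region}_{mod}"] = float(np.clip(grade, 0, 4))
        raw.append(
            dict(
                subject_id=f"S{i:04d}",
                age=float(np.clip(srng.uniform(20.0, 75.0), 18.0, 90.0)),
                sex=sex,
                height=float(np.clip(height, 140.0, 210.0)),
                weight=float(np.clip(weight, 40.0, 160.0)),
                dominant_hand="right" if srng.random() < 0.9 else "left",
                diagnosis=diag,
                neurex_panel_scores=panels,
                mri_scores=mri,
                latent_disability=latent,
            )
        )

    edss, combiwise, neurex = _clinical_scales(
        latents, _rng(seed, "clinical"), config.clinical_r_target
    )
    for i, rec in enumerate(raw):
        subjects.append(
            SubjectRecord(
                edss=float(edss[i]),
                combiwise=float(combiwise[i]),
                neurex_total=float(neurex[i]),
                **rec,
            )
        )

    trials: list[RawTrial] = []
    for subject in subjects:
        for trial_index in range(1, n_trials + 1):
            for stance in SWAY_STANCES:
                trials.append(
                    simulate_sway_trial(subject, stance, trial_index, seed, config)
                )
            for hand in DRIFT_TESTS:
                trials.append(
                    simulate_drift_trial(subject, hand, trial_index, seed, config)
                )
    return subjects, trials


# ---------------------------------------------------------------------------
# CSV / JSON round-trip


def cohort_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records (panel and MRI maps become columns)."""
    rows = []
    for s in subjects:
        row = {
            k: getattr(s, k)
            for k in (
                "subject_id",
                "age",
                "sex",
                "height",
                "weight",
                "dominant_hand",
                "diagnosis",
                "edss",
                "combiwise",
                "neurex_total",
                "latent_disability",
            )
        }
        row.update(s.neurex_panel_scores)
        row.update({f"mri_{k}": v for k, v in s.mri_scores.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(frame: pd.DataFrame) -> list[SubjectRecord]:
    subjects = []
    for _, row in frame.iterrows():
        panels = {k: float(row[k]) for k in PANEL_KEYS}
        mri = {
            f"{r}_{m}": float(row[f"mri_{r}_{m}"])
            for r in MRI_REGIONS
            for m in MRI_MODALITIES
        }
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                height=float(row["height"]),
                weight=float(row["weight"]),
                dominant_hand=str(row["dominant_hand"]),
                diagnosis=str(row["diagnosis"]),
                edss=float(row["edss"]),
                combiwise=float(row["combiwise"]),
                neurex_total=float(row["neurex_total"]),
                neurex_panel_scores=panels,
                mri_scores=mri,
                latent_disability=float(row.get("latent_disability", 0.0)),
            )
        )
    return subjects


def trials_to_frame(trials: Sequence[RawTrial]) -> pd.DataFrame:
    """Long-format trial table: (subject_id, test, trial_index, t, ax, ay, az)."""
    parts = []
    for tr in trials:
        n = tr.samples.shape[0]
        parts.append(
            pd.DataFrame(
                {
                    "subject_id": tr.subject_id,
                    "test": tr.test,
                    "trial_index": tr.trial_index,
                    "t": np.arange(n) / tr.sampling_hz,
                    "ax": tr.samples[:, 0],
                    "ay": tr.samples[:, 1],
                    "az": tr.samples[:, 2],
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def frame_to_trials(frame: pd.DataFrame, sampling_hz: float = 50.0) -> list[RawTrial]:
    trials = []
    for (sid, test, idx), grp in frame.groupby(
        ["subject_id", "test", "trial_index"], sort=True
    ):
        grp = grp.sort_values("t")
        samples = grp[["ax", "ay", "az"]].to_numpy(float)
        trials.append(RawTrial(str(sid), str(test), int(idx), sampling_hz, samples))
    return trials


def write_cohort(
    subjects: Sequence[SubjectRecord],
    trials: Sequence[RawTrial],
    cohort_path,
    trials_path,
    meta_path=None,
    seed: int | None = None,
    config: GeneratorConfig | None = None,
) -> None:
    cohort_to_frame(subjects).to_csv(cohort_path, index=False)
    trials_to_frame(trials).to_csv(trials_path, index=False)
    if meta_path is not None:
        meta = {
            "seed": seed,
            "n_subjects": len(subjects),
            "generator": (config or GeneratorConfig()).to_dict(),
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
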