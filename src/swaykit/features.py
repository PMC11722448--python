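"""Digital biomarkers of postural sway and pronator drift.

Four base measurements are computed from calibrated acceleration series:

* ``RMS``  — root-mean-square acceleration, sqrt((1/N) * sum a_i^2): the
  sway amplitude measure (m/s^2).
* ``Jerk`` — time-integrated squared derivative of acceleration,
  integral (dAcc/dt)^2 dt: sway "jerkiness" ((m/s^3)^2 * s).  The Net
  variant averages the M-L and A-P integrands:
  NetJerk = 1/2 * integral [(dAcc_ML/dt)^2 + (dAcc_AP/dt)^2] dt.
* ``SC``   — spectral centroid, the PSD-weighted mean frequency
  mu1 = sum f_k S_k / sum S_k (Hz).
* ``SS``   — spectral spread, the PSD-weighted variance of frequency
  mu2 = sum (f_k - mu1)^2 S_k / sum S_k (Hz^2).

For the three-stance balance test every measurement is computed for the
M-L, A-P and Net directions in each stance, plus two cross-stance
ratios (eyes-closed:eyes-open feet together — the Romberg ratio — and
feet-together:feet-apart with eyes open), for 4 x 3 x 5 = 60 features.
For the two-hand drift test only orientation-invariant Net measurements
are used, labelled by hand dominance, plus their sum and difference:
4 x 4 = 16 features.  All features are log10 transformed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.signal import periodogram

from .calibration import CalibratedSeries

MEASUREMENTS = ("RMS", "Jerk", "SC", "SS")
DIRECTIONS = ("ML", "AP", "Net")
STANCES = ("EO-FA", "EO-FT", "EC-FT")
#: Cross-stance ratio conditions: Romberg = EC-FT : EO-FT (visual
#: contribution); Stance = EO-FT : EO-FA (base-of-support contribution).
RATIO_CONDITIONS = {"Romberg": ("EC-FT", "EO-FT"), "Stance": ("EO-FT", "EO-FA")}
SWAY_CONDITIONS = STANCES + tuple(RATIO_CONDITIONS)
HAND_CONDITIONS = ("Dom", "Ndom", "Sum", "Diff")

SWAY_BAND = (0.15, 10.0)
DRIFT_BAND = (0.15, 15.0)

LOG_FLOOR = 1e-12
DIFF_SCALE = 1e-3  # scale of the signed log transform for Diff features


def sway_feature_names() -> list[str]:
    return [
        f"{m}_{d}_{c}" for m in MEASUREMENTS for d in DIRECTIONS for c in SWAY_CONDITIONS
    ]


def drift_feature_names() -> list[str]:
    return [f"{m}_Net_{c}" for m in MEASUREMENTS for c in HAND_CONDITIONS]


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided PSD restricted to an analysis band."""

    freqs: np.ndarray
    psd: np.ndarray
    band: tuple

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.psd < 0):
            raise ValueError("PSD must be nonnegative")


@dataclass(frozen=True)
class BiomarkerVector:
    """Named, log10-transformed feature values for one subject-trial."""

    subject_id: str
    trial_index: int
    kind: str  # "sway" | "drift"
    values: Mapping[str, float]


def rms(series: np.ndarray) -> float:
    """Root-mean-square of an acceleration series."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return float(np.sqrt(np.mean(x * x)))


def jerk(series: np.ndarray, dt: float) -> float:
    """Integrated squared acceleration derivative over the trial.

    Central differences in the interior, one-sided at the ends;
    trapezoidal integration.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    d = np.gradient(x, dt)
    return float(np.trapezoid(d * d, dx=dt))


def net_jerk(ml: np.ndarray, ap: np.ndarray, dt: float) -> float:
    """Half the summed M-L and A-P squared-derivative integrals."""
    ml = np.asarray(ml, dtype=float)
    ap = np.asarray(ap, dtype=float)
    if ml.shape != ap.shape:
        raise ValueError("M-L and A-P series must have equal length")
    if ml.size < 2:
        raise ValueError("need at least 2 samples")
    dml = np.gradient(ml, dt)
    dap = np.gradient(ap, dt)
    return float(0.5 * np.trapezoid(dml * dml + dap * dap, dx=dt))


def power_spectrum(series: np.ndarray, fs: float, band: tuple) -> PowerSpectrum:
    """Mean-removed single-taper periodogram restricted to ``band``.

    Density scaling, so sum(psd) * df approximates the series variance
    (Parseval).  No segment averaging: a 9 s record is too short to
    split without destroying low-frequency resolution.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    low, high = band
    if not (0 < low < high <= fs / 2):
        raise ValueError(f"band {band} outside (0, {fs / 2}]")
    freqs, psd = periodogram(np.asarray(series, dtype=float), fs=fs, detrend="constant")
    mask = (freqs >= low) & (freqs <= high)
    return PowerSpectrum(freqs=freqs[mask], psd=psd[mask], band=(low, high))


def spectral_moments(spec: PowerSpectrum) -> tuple[float, float]:
    """(SC, SS): PSD-weighted mean and variance of frequency in the band."""
    total = float(np.sum(spec.psd))
    if total <= 0:
        raise ValueError("all-zero spectrum in band; moments undefined")
    sc = float(np.sum(spec.freqs * spec.psd) / total)
    ss = float(np.sum((spec.freqs - sc) ** 2 * spec.psd) / total)
    return sc, ss


def log10_transform(value: float) -> float:
    """log10 with a small positive floor (raw features are nonnegative)."""
    return float(np.log10(max(value, LOG_FLOOR)))


def signed_log10(value: float, scale: float = DIFF_SCALE) -> float:
    """Order-preserving symmetric log for sign-indefinite features.

    Dominant-minus-non-dominant differences can be negative, where a
    plain log10 is undefined; sgn(x) * log10(1 + |x|/scale) preserves
    ordering and is ~linear near zero.
    """
    return float(np.sign(value) * np.log10(1.0 + abs(value) / scale))


def _raw_measurements(series: CalibratedSeries, band: tuple) -> dict[str, float]:
    """The 12 raw (pre-log) measurement x direction values for one trial."""
    fs = 1.0 / series.dt
    out: dict[str, float] = {}
    for direction, x in (("ML", series.ml), ("AP", series.ap), ("Net", series.net)):
        out[f"RMS_{direction}"] = rms(x)
        sc, ss = spectral_moments(power_spectrum(x, fs, band))
        out[f"SC_{direction}"] = sc
        out[f"SS_{direction}"] = ss
    out["Jerk_ML"] = jerk(series.ml, series.dt)
    out["Jerk_AP"] = jerk(series.ap, series.dt)
    out["Jerk_Net"] = net_jerk(series.ml, series.ap, series.dt)
    return out


def extract_sway_features(
    trials: Mapping[str, CalibratedSeries], band: tuple = SWAY_BAND
) -> BiomarkerVector:
    """All 60 balance biomarkers from one trial's three stances.

    Per-stance values are computed first; the Romberg and stance ratios
    are formed on the raw (pre-log) values; every emitted feature is
    then log10 transformed.
    """
    missing = [s for s in STANCES if s not in trials]
    if missing:
        raise ValueError(f"missing stance(s): {missing}")
    ref = trials[STANCES[0]]
    raw = {s: _raw_measurements(trials[s], band) for s in STANCES}
    values: dict[str, float] = {}
    for m in MEASUREMENTS:
        for d in DIRECTIONS:
            key = f"{m}_{d}"
            for s in STANCES:
                values[f"{key}_{s}"] = log10_transform(raw[s][key])
            for cond, (num, den) in RATIO_CONDITIONS.items():
                ratio = raw[num][key] / max(raw[den][key], LOG_FLOOR)
                values[f"{key}_{cond}"] = log10_transform(ratio)
    return BiomarkerVector(ref.subject_id, ref.trial_index, "sway", values)


def extract_drift_features(
    left: CalibratedSeries,
    right: CalibratedSeries,
    dominant_hand: str,
    band: tuple = DRIFT_BAND,
) -> BiomarkerVector:
    """All 16 drift biomarkers from one trial's two hands.

    Only orientation-invariant Net measurements are used (hand-held
    phone orientation is uncontrolled).  Hands are relabelled dominant /
    non-dominant; Sum and Diff are formed on raw values (Diff = Dom -
    Ndom) before transformation.  Diff uses a signed log since it can
    be negative.
    """
    if dominant_hand not in ("left", "right"):
        raise ValueError(f"dominant_hand must be left/right, got {dominant_hand!r}")
    by_side = {"left": left, "right": right}
    for side, series in by_side.items():
        if series is None:
            raise ValueError(f"missing {side} hand trial")
    dom = by_side[dominant_hand]
    ndom = by_side["left" if dominant_hand == "right" else "right"]
    raw: dict[str, float] = {}
    for label, series in (("Dom", dom), ("Ndom", ndom)):
        meas = _raw_measurements(series, band)
        for m in MEASUREMENTS:
            raw[f"{m}_Net_{label}"] = meas[f"{m}_Net"]
    values: dict[str, float] = {}
    for m in MEASUREMENTS:
        d, n = raw[f"{m}_Net_Dom"], raw[f"{m}_Net_Ndom"]
        values[f"{m}_Net_Dom"] = log10_transform(d)
        values[f"{m}_Net_Ndom"] = log10_transform(n)
        values[f"{m}_Net_Sum"] = log10_transform(d + n)
        values[f"{m}_Net_Diff"] = signed_log10(d - n)
    return BiomarkerVector(dom.subject_id, dom.trial_index, "drift", values)


def feature_dictionary() -> dict[str, dict]:
    """Machine-readable documentation of every feature name."""
    formulas = {
        "RMS": "sqrt((1/N) sum a_i^2)",
        "Jerk": "integral (dAcc/dt)^2 dt (Net: half-sum of ML and AP integrands)",
        "SC": "sum f_k S_k / sum S_k",
        "SS": "sum (f_k - SC)^2 S_k / sum S_k",
    }
    units = {"RMS": "m/s^2", "Jerk": "(m/s^3)^2*s", "SC": "Hz", "SS": "Hz^2"}
    out = {}
    for name in sway_feature_names() + drift_feature_names():
        m, d, c = name.split("_")
        transform = "signed_log10" if c == "Diff" else "log10"
        out[name] = {
            "measurement": m,
            "direction": d,
            "condition": c,
            "formula": formulas[m],
            "raw_units": units[m],
            "transform": transform,
        }
    return out
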