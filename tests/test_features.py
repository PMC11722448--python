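"""Biomarker oracles: analytic signals, algebraic identities, the
60/16 feature grammar, and scaling laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swaykit.calibration import CalibratedSeries
from swaykit.features import (
    drift_feature_names,
    extract_drift_features,
    extract_sway_features,
    feature_dictionary,
    jerk,
    net_jerk,
    power_spectrum,
    rms,
    signed_log10,
    spectral_moments,
    sway_feature_names,
    PowerSpectrum,
)

FS = 50.0
DT = 1.0 / FS


def _series(ml, ap, subject="F0", test="EO-FA", idx=1):
    ml = np.asarray(ml, dtype=float)
    ap = np.asarray(ap, dtype=float)
    return CalibratedSeries(subject, test, idx, DT, ml, ap, np.hypot(ml, ap))


def _noise_series(rng, n=450, amp=0.05, **kw):
    return _series(amp * rng.standard_normal(n), amp * rng.standard_normal(n), **kw)


# ---------------------------------------------------------------- rms / jerk


@pytest.mark.parametrize(
    "series,expected",
    [
        (np.full(100, 2.0), 2.0),
        (np.array([3.0, -4.0]), np.sqrt(12.5)),
    ],
)
def test_rms_exact_cases(series, expected):
    assert rms(series) == pytest.approx(expected, abs=1e-12)


def test_rms_sinusoid_limit():
    t = np.arange(450) / FS
    x = np.sin(2 * np.pi * 1.0 * t[: 9 * 50])  # integer number of cycles over 9 s
    assert rms(x) == pytest.approx(1 / np.sqrt(2), abs=1e-3)


def test_rms_empty_rejected():
    with pytest.raises(ValueError):
        rms(np.array([]))


def test_jerk_constant_is_zero():
    assert jerk(np.full(450, 3.3), DT) == 0.0


def test_jerk_linear_ramp_analytic():
    t = np.arange(450) / FS
    assert jerk(2.0 * t, DT) == pytest.approx(4.0 * 9.0, rel=0.01)


def test_jerk_quadratic_homogeneity(rng):
    x = rng.standard_normal(300)
    assert jerk(2 * x, DT) == pytest.approx(4 * jerk(x, DT), rel=1e-12)


def test_net_jerk_identities(rng):
    x = rng.standard_normal(200)
    y = rng.standard_normal(200)
    assert net_jerk(x, x, DT) == pytest.approx(jerk(x, DT), rel=1e-12)
    assert net_jerk(x, np.full(200, 1.0), DT) == pytest.approx(jerk(x, DT) / 2, rel=1e-12)
    assert net_jerk(x, y, DT) == pytest.approx((jerk(x, DT) + jerk(y, DT)) / 2, rel=1e-12)
    with pytest.raises(ValueError):
        net_jerk(x, y[:-1], DT)


# ------------------------------------------------------------------ spectra


def test_pure_tone_dominates_one_bin():
    t = np.arange(450) / FS
    spec = power_spectrum(np.sin(2 * np.pi * 3.0 * t), FS, (0.15, 10.0))
    df = spec.freqs[1] - spec.freqs[0]
    assert abs(spec.freqs[np.argmax(spec.psd)] - 3.0) <= df


def test_parseval_normalization(rng):
    x = rng.standard_normal(4500)
    spec = power_spectrum(x, FS, (0.01, 25.0))
    df = spec.freqs[1] - spec.freqs[0]
    assert np.sum(spec.psd) * df == pytest.approx(np.var(x), rel=0.05)


def test_white_noise_flatness(rng):
    """Averaged periodograms of white noise flatten out across bins."""
    psds = []
    for _ in range(200):
        spec = power_spectrum(rng.standard_normal(450), FS, (0.15, 24.0))
        psds.append(spec.psd)
    mean_psd = np.mean(psds, axis=0)
    assert np.std(mean_psd) / np.mean(mean_psd) < 0.15


def test_zero_series_and_band_guards():
    spec = power_spectrum(np.zeros(450), FS, (0.15, 10.0))
    assert np.all(spec.psd == 0)
    with pytest.raises(ValueError):
        power_spectrum(np.zeros(450), FS, (0.15, 30.0))  # beyond Nyquist
    with pytest.raises(ValueError):
        spectral_moments(spec)  # all-zero spectrum: moments undefined


@pytest.mark.parametrize(
    "freqs,psd,expected_sc,expected_ss",
    [
        (np.array([1.0, 2.0, 3.0]), np.array([0.0, 5.0, 0.0]), 2.0, 0.0),
        (np.array([1.0, 3.0]), np.array([2.0, 2.0]), 2.0, 1.0),
    ],
)
def test_spectral_moments_hand_cases(freqs, psd, expected_sc, expected_ss):
    sc, ss = spectral_moments(PowerSpectrum(freqs, psd, (0.5, 4.0)))
    assert sc == pytest.approx(expected_sc, abs=1e-12)
    assert ss == pytest.approx(expected_ss, abs=1e-12)


def test_flat_spectrum_centroid_is_band_center():
    freqs = np.linspace(0.5, 4.5, 41)
    sc, _ = spectral_moments(PowerSpectrum(freqs, np.ones_like(freqs), (0.5, 4.5)))
    assert sc == pytest.approx(2.5, abs=0.1)


# -------------------------------------------------------------- sway vector


def test_sway_vector_has_exactly_60_named_features(rng):
    trials = {s: _noise_series(rng, test=s) for s in ("EO-FA", "EO-FT", "EC-FT")}
    vec = extract_sway_features(trials)
    assert set(vec.values) == set(sway_feature_names())
    assert len(vec.values) == 60


def test_missing_stance_rejected(rng):
    with pytest.raises(ValueError, match="missing stance"):
        extract_sway_features({"EO-FA": _noise_series(rng)})


def test_romberg_of_identical_trials_is_zero(rng):
    base = _noise_series(rng)
    trials = {
        "EO-FA": _noise_series(rng, test="EO-FA"),
        "EO-FT": base,
        "EC-FT": _series(base.ml, base.ap, test="EC-FT"),
    }
    vec = extract_sway_features(trials)
    for name, value in vec.values.items():
        if name.endswith("_Romberg"):
            assert value == pytest.approx(0.0, abs=1e-9)


def test_ratio_equals_log_difference(rng):
    trials = {s: _noise_series(rng, test=s) for s in ("EO-FA", "EO-FT", "EC-FT")}
    vec = extract_sway_features(trials)
    for m in ("RMS", "Jerk", "SC", "SS"):
        for d in ("ML", "AP", "Net"):
            assert vec.values[f"{m}_{d}_Romberg"] == pytest.approx(
                vec.values[f"{m}_{d}_EC-FT"] - vec.values[f"{m}_{d}_EO-FT"], abs=1e-9
            )
            assert vec.values[f"{m}_{d}_Stance"] == pytest.approx(
                vec.values[f"{m}_{d}_EO-FT"] - vec.values[f"{m}_{d}_EO-FA"], abs=1e-9
            )


def test_radial_rms_identity_and_netjerk_identity(rng):
    """Net RMS^2 = ML RMS^2 + AP RMS^2 and NetJerk = (JerkML+JerkAP)/2
    on a batch of random trials (tight algebraic tolerance)."""
    for _ in range(50):
        s = _noise_series(rng)
        assert rms(s.net) ** 2 == pytest.approx(rms(s.ml) ** 2 + rms(s.ap) ** 2, rel=1e-10)
        assert net_jerk(s.ml, s.ap, DT) == pytest.approx(
            (jerk(s.ml, DT) + jerk(s.ap, DT)) / 2, rel=1e-10
        )


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.floats(min_value=0.1, max_value=10.0))
def test_scaling_laws(c):
    """Scaling a series by c shifts log10 RMS by log10(c), log10 Jerk by
    2 log10(c), and leaves SC/SS unchanged."""
    rng = np.random.default_rng(99)
    trials = {s: _noise_series(rng, test=s) for s in ("EO-FA", "EO-FT", "EC-FT")}
    scaled = {
        s: _series(c * t.ml, c * t.ap, test=s) for s, t in trials.items()
    }
    v0 = extract_sway_features(trials).values
    v1 = extract_sway_features(scaled).values
    for stance in ("EO-FA", "EO-FT", "EC-FT"):
        assert v1[f"RMS_Net_{stance}"] - v0[f"RMS_Net_{stance}"] == pytest.approx(np.log10(c), abs=1e-9)
        assert v1[f"Jerk_ML_{stance}"] - v0[f"Jerk_ML_{stance}"] == pytest.approx(2 * np.log10(c), abs=1e-9)
        assert v1[f"SC_AP_{stance}"] == pytest.approx(v0[f"SC_AP_{stance}"], abs=1e-9)
        assert v1[f"SS_AP_{stance}"] == pytest.approx(v0[f"SS_AP_{stance}"], abs=1e-9)


# ------------------------------------------------------------- drift vector


def test_drift_vector_has_exactly_16_named_features(rng):
    left = _noise_series(rng, test="drift_left")
    right = _noise_series(rng, test="drift_right")
    vec = extract_drift_features(left, right, "right")
    assert set(vec.values) == set(drift_feature_names())
    assert len(vec.values) == 16


def test_identical_hands_give_zero_diff(rng):
    left = _noise_series(rng, test="drift_left")
    right = _series(left.ml, left.ap, test="drift_right")
    vec = extract_drift_features(left, right, "left")
    for name, value in vec.values.items():
        if name.endswith("_Diff"):
            assert value == pytest.approx(0.0, abs=1e-9)


def test_sum_is_dom_plus_ndom_raw(rng):
    left = _noise_series(rng, test="drift_left")
    right = _noise_series(rng, test="drift_right")
    vec = extract_drift_features(left, right, "right")
    for m in ("RMS", "Jerk", "SC", "SS"):
        raw_sum = 10 ** vec.values[f"{m}_Net_Dom"] + 10 ** vec.values[f"{m}_Net_Ndom"]
        assert vec.values[f"{m}_Net_Sum"] == pytest.approx(np.log10(raw_sum), abs=1e-9)


def test_missing_hand_and_bad_dominance(rng):
    s = _noise_series(rng)
    with pytest.raises(ValueError):
        extract_drift_features(None, s, "right")
    with pytest.raises(ValueError):
        extract_drift_features(s, s, "ambidextrous")


def test_signed_log_preserves_order_and_sign():
    xs = np.array([-2.0, -0.1, 0.0, 0.1, 2.0])
    ys = [signed_log10(x) for x in xs]
    assert all(np.diff(ys) > 0)
    assert signed_log10(0.0) == 0.0
    assert signed_log10(-1.5) == -signed_log10(1.5)


def test_feature_dictionary_covers_grammar():
    fdict = feature_dictionary()
    assert len(fdict) == 76
    assert fdict["RMS_Net_EC-FT"]["raw_units"] == "m/s^2"
    assert fdict["RMS_Net_Diff"]["transform"] == "signed_log10"
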