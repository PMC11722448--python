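"""Tilt correction: raw tri-axial trials -> M-L / A-P / Net series.

A phone worn in a neck harness (or held in an outstretched hand) is
never perfectly aligned with the body axes, so the gravity vector shows
up partly in the "horizontal" channels.  The standard remedy for
trunk-accelerometer sway work is applied here: estimate gravity as the
trial-mean acceleration vector, rotate the frame by the minimal rotation
taking that vector onto the vertical axis, subtract the gravity
magnitude from the vertical channel, and demean the two horizontal
channels, which become antero-posterior (A-P) and medio-lateral (M-L)
series.  The pointwise radial combination sqrt(ml^2 + ap^2) is the Net
series; it is invariant to the (unknown) rotation of the phone about
the vertical, which is why only Net features are used for the
hand-held drift test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .synthetic import RawTrial

TRIM_SECONDS = 9.0


@dataclass(frozen=True)
class CalibratedSeries:
    """Gravity-removed body-axis acceleration series, trimmed to 9 s."""

    subject_id: str
    test: str
    trial_index: int
    dt: float
    ml: np.ndarray
    ap: np.ndarray
    net: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.ml.size


def _minimal_rotation_to_vertical(g: np.ndarray) -> Rotation:
    """Minimal rotation carrying unit vector g onto +z."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(np.dot(g, z), -1.0, 1.0))
    axis = np.cross(g, z)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        if c > 0:  # already vertical
            return Rotation.identity()
        # antiparallel: rotate pi about any horizontal axis
        return Rotation.from_rotvec(np.pi * np.array([1.0, 0.0, 0.0]))
    return Rotation.from_rotvec(axis / norm * np.arccos(c))


def calibrate_trial(
    raw: RawTrial, demean: bool = True, trim_seconds: float = TRIM_SECONDS
) -> CalibratedSeries:
    """Calibrate one raw trial into M-L / A-P / Net series.

    Trims to the first ``trim_seconds`` of the record, orients the mean
    acceleration vector to vertical, removes gravity, and labels the
    rotated x/y horizontals as M-L/A-P per the nominal device mounting.

    Raises ``ValueError`` when fewer than 9 s of samples are available
    or the mean acceleration vector is (numerically) zero, in which
    case the frame cannot be oriented.
    """
    n_keep = int(round(trim_seconds * raw.sampling_hz))
    if raw.samples.shape[0] < n_keep:
        raise ValueError(
            f"trial has {raw.samples.shape[0]} samples, need {n_keep} for {trim_seconds} s"
        )
    a = np.asarray(raw.samples, dtype=float)[:n_keep]
    g = a.mean(axis=0)
    g_mag = float(np.linalg.norm(g))
    if g_mag < 1e-9:
        raise ValueError("zero-magnitude mean acceleration; cannot orient frame")
    rot = _minimal_rotation_to_vertical(g / g_mag)
    body = rot.apply(a)
    ml = body[:, 0]
    ap = body[:, 1]
    if demean:
        ml = ml - ml.mean()
        ap = ap - ap.mean()
    net = np.hypot(ml, ap)
    return CalibratedSeries(
        subject_id=raw.subject_id,
        test=raw.test,
        trial_index=raw.trial_index,
        dt=1.0 / raw.sampling_hz,
        ml=ml,
        ap=ap,
        net=net,
    )


def series_to_frame(series: CalibratedSeries):
    """Calibrated series as a tidy table (t, ml, ap, net)."""
    import pandas as pd

    t = np.arange(series.n_samples) * series.dt
    return pd.DataFrame(
        {"t": t, "ml": series.ml, "ap": series.ap, "net": series.net}
    )
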