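"""Test-retest reliability and outlier masking.

Repeated trials of the same subject on different days should agree for
a biomarker to be useful.  Agreement is quantified with the single-
measure absolute-agreement intraclass correlation ICC(2,1), computed
from a two-way ANOVA with subjects and trials as crossed factors over
each subject's first two trials; features with ICC <= 0.5 are dropped.
Values of the retained features outside the Tukey fences (1.5 x IQR
beyond the quartiles) are masked as missing, keeping the subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ICC_THRESHOLD = 0.5
IQR_MULTIPLIER = 1.5

ID_COLUMNS = ("subject_id", "trial_index")


@dataclass
class ReliabilityReport:
    """Per-feature ICCs, retention decisions, and the outlier mask."""

    icc_table: pd.DataFrame  # columns: feature, icc, retained, n_subjects_used
    threshold: float
    outlier_mask: pd.DataFrame | None = None  # True where masked; same shape as data
    retained: list = field(init=False)

    def __post_init__(self) -> None:
        self.retained = list(
            self.icc_table.loc[self.icc_table["retained"], "feature"]
        )


def icc_2_1(data: np.ndarray) -> float:
    """ICC(2,1): single-measure absolute agreement, two-way random ANOVA.

    ``data`` is a subjects x trials matrix (rows with any missing cell
    are dropped).  With n subjects, k trials, row/column/error mean
    squares MS_R / MS_C / MS_E:

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    Returns NaN (flagged, not propagated: callers treat it as
    not-retained) when the matrix has zero total variance.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a subjects x trials matrix with >= 2 trials")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 2:
        raise ValueError("need >= 2 complete subjects")
    grand = x.mean()
    if np.allclose(x, grand):
        return float("nan")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        return float("nan")
    return float((ms_r - ms_e) / denom)


def _trial_matrix(features: pd.DataFrame, feature: str) -> np.ndarray:
    """Subjects x first-2-trials matrix for one feature."""
    sub = features[features["trial_index"].isin((1, 2))]
    wide = sub.pivot_table(
        index="subject_id", columns="trial_index", values=feature, aggfunc="first"
    )
    if wide.shape[1] < 2:
        raise ValueError(f"feature {feature!r}: need trials 1 and 2")
    return wide[[1, 2]].to_numpy(float)


def filter_reliable(
    features: pd.DataFrame, threshold: float = ICC_THRESHOLD
) -> ReliabilityReport:
    """Compute ICC(2,1) per feature over the first two trials and retain
    features with ICC strictly above ``threshold``.

    ``features`` is long over trials: one row per subject-trial with
    ``subject_id``/``trial_index`` columns plus feature columns.
    """
    cols = [c for c in features.columns if c not in ID_COLUMNS]
    if not cols:
        raise ValueError("empty feature matrix")
    rows = []
    for feature in cols:
        mat = _trial_matrix(features, feature)
        complete = mat[~np.isnan(mat).any(axis=1)]
        icc = icc_2_1(mat) if complete.shape[0] >= 2 else float("nan")
        rows.append(
            {
                "feature": feature,
                "icc": icc,
                "retained": bool(np.isfinite(icc) and icc > threshold),
                "n_subjects_used": int(complete.shape[0]),
            }
        )
    return ReliabilityReport(icc_table=pd.DataFrame(rows), threshold=threshold)


def flag_outliers(values: np.ndarray, multiplier: float = IQR_MULTIPLIER) -> np.ndarray:
    """Tukey-fence mask: True where value is beyond quartile +/- 1.5*IQR.

    Quartiles use linear interpolation (type 7).  NaNs are never
    flagged.  Requires >= 4 finite values.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 4:
        raise ValueError("need >= 4 values to estimate quartiles")
    q1, q3 = np.quantile(finite, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    with np.errstate(invalid="ignore"):
        return np.isfinite(x) & ((x < lo) | (x > hi))


def mask_outliers(
    features: pd.DataFrame,
    feature_names: list[str] | None = None,
    multiplier: float = IQR_MULTIPLIER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask per-feature Tukey outliers as NaN; subjects are kept.

    Returns (masked copy, boolean mask frame aligned with the input).
    """
    feature_names = feature_names or [
        c for c in features.columns if c not in ID_COLUMNS
    ]
    masked = features.copy()
    mask = pd.DataFrame(False, index=features.index, columns=feature_names)
    for feature in feature_names:
        flags = flag_outliers(features[feature].to_numpy(float), multiplier)
        mask[feature] = flags
        masked.loc[flags, feature] = np.nan
    return masked, mask
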