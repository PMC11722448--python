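"""Association analyses: correlation screens, normative age bands,
pairwise group tests.

Three analyses mirror the standard digital-biomarker workup:

* a Pearson correlation screen of every (feature, outcome) pair with
  Benjamini-Hochberg false-discovery-rate adjustment within the screen;
* a healthy-volunteer normative age model: OLS of a feature on age over
  HV only, with a two-sided 95% prediction interval for a new
  observation; a subject is flagged abnormal when their value exceeds
  the upper bound at their age (disability only increases sway, so
  flagging is one-sided);
* pairwise two-sided Wilcoxon rank-sum tests between diagnostic
  groups, BH-adjusted over all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def correlation_screen(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Pearson r and BH-adjusted p for every (feature, outcome) pair.

    Inputs are aligned on index (subject).  Missing/masked cells are
    excluded pairwise; pairs with fewer than 3 complete observations or
    a constant series get a flagged row (NaN r/p) and are excluded from
    the BH family.
    """
    rows = []
    for feature in features.columns:
        fv = features[feature].to_numpy(float)
        for outcome in outcomes.columns:
            ov = outcomes[outcome].to_numpy(float)
            ok = np.isfinite(fv) & np.isfinite(ov)
            n = int(ok.sum())
            if n < 3 or np.std(fv[ok]) == 0 or np.std(ov[ok]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(fv[ok], ov[ok])
            rows.append(
                {"feature": feature, "outcome": outcome, "pearson_r": r, "p_value": p, "n": n}
            )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    table["significant"] = table["p_adjusted"] < alpha
    return table


@dataclass
class AgeModelResult:
    """HV normative age regression and per-subject abnormality flags."""

    feature: str
    slope: float
    intercept: float
    r_squared: float
    level: float
    fitted: object  # statsmodels results, for band evaluation
    flags: pd.DataFrame  # subject_id, diagnosis, age, value, pi_lower, pi_upper, abnormal
    abnormal_fraction_by_diagnosis: dict

    def prediction_band(self, ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) prediction bounds for new observations at ``ages``."""
        exog = sm.add_constant(np.asarray(ages, dtype=float), has_constant="add")
        frame = self.fitted.get_prediction(exog).summary_frame(alpha=1 - self.level)
        return frame["obs_ci_lower"].to_numpy(), frame["obs_ci_upper"].to_numpy()


def hv_age_prediction_interval(
    subjects: pd.DataFrame,
    feature: str,
    level: float = 0.95,
    hv_label: str = "HV",
) -> AgeModelResult:
    """Fit feature ~ age on healthy volunteers; flag elevated subjects.

    ``subjects`` needs columns subject_id, diagnosis, age and the
    feature.  The band is the standard two-sided OLS prediction interval
    for a new observation; flags are one-sided (value above the upper
    bound at the subject's age).
    """
    data = subjects.dropna(subset=["age", feature])
    hv = data[data["diagnosis"] == hv_label]
    if len(hv) < 10:
        raise ValueError(f"need >= 10 HV subjects with age and {feature!r}, got {len(hv)}")
    if np.std(hv["age"].to_numpy(float)) == 0:
        raise ValueError("zero age variance in HV cohort")
    exog = sm.add_constant(hv["age"].to_numpy(float))
    fit = sm.OLS(hv[feature].to_numpy(float), exog).fit()

    all_exog = sm.add_constant(data["age"].to_numpy(float), has_constant="add")
    band = fit.get_prediction(all_exog).summary_frame(alpha=1 - level)
    flags = pd.DataFrame(
        {
            "subject_id": data["subject_id"].to_numpy(),
            "diagnosis": data["diagnosis"].to_numpy(),
            "age": data["age"].to_numpy(float),
            "value": data[feature].to_numpy(float),
            "pi_lower": band["obs_ci_lower"].to_numpy(),
            "pi_upper": band["obs_ci_upper"].to_numpy(),
        }
    )
    flags["abnormal"] = flags["value"] > flags["pi_upper"]
    fractions = flags.groupby("diagnosis")["abnormal"].mean().to_dict()
    return AgeModelResult(
        feature=feature,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        level=level,
        fitted=fit,
        flags=flags,
        abnormal_fraction_by_diagnosis=fractions,
    )


def pairwise_group_tests(
    groups: Mapping[str, Sequence[float]], alpha: float = ALPHA
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per group pair, BH-adjusted.

    Returns one row per unordered pair with significance stars at
    0.05 (*) and 0.01 (**).
    """
    clean = {}
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 3:
            raise ValueError(f"group {name!r} has fewer than 3 values")
        clean[name] = v
    if len(clean) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for a, b in combinations(sorted(clean), 2):
        stat, p = stats.mannwhitneyu(clean[a], clean[b], alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "statistic": float(stat), "p_value": float(p)})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    table["stars"] = [
        "**" if p <= 0.01 else "*" if p <= alpha else "" for p in table["p_adjusted"]
    ]
    return table
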