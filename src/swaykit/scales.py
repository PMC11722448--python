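"""Composite clinical subpanels for balance and drift.

The neurological-exam app records per-panel dysfunction scores; two
composites target the subsystems each smartphone test exercises:

* postural-sway subpanel: sqrt(stance&gait + lower-extremity cerebellar
  + lower-extremity proprioceptive) — the square root compresses the
  right tail of the summed score;
* pronator-drift subpanel: per hand, motoric (muscle strength panel 8 +
  reflexes panel 10 + spasticity panel 7) + cerebellar + proprioceptive,
  summed over both hands.

Panel scores arrive as already-computed nonnegative reals; the exam
app's internal scoring is out of scope.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import pandas as pd

HANDS = ("left", "right")


def neurex_postural_sway(
    stance_gait: float, cerebellar_le: float, proprioceptive_le: float
) -> float:
    """sqrt of the summed stance/gait + lower-extremity cerebellar and
    proprioceptive panel scores."""
    parts = (stance_gait, cerebellar_le, proprioceptive_le)
    if any(p < 0 for p in parts):
        raise ValueError("panel scores must be nonnegative")
    return math.sqrt(sum(parts))


def hand_motoric(panel8: float, panel10: float, panel7: float) -> float:
    """Upper-extremity motoric dysfunction: strength + reflexes + spasticity."""
    if min(panel8, panel10, panel7) < 0:
        raise ValueError("panel scores must be nonnegative")
    return panel8 + panel10 + panel7


def neurex_pronator_drift(per_hand: Mapping[str, Sequence[float]]) -> float:
    """Sum over both hands of (motoric + cerebellar + proprioceptive)."""
    missing = [h for h in HANDS if h not in per_hand]
    if missing:
        raise ValueError(f"missing hand(s): {missing}")
    total = 0.0
    for hand in HANDS:
        motoric, cerebellar, proprioceptive = per_hand[hand]
        if min(motoric, cerebellar, proprioceptive) < 0:
            raise ValueError("subsystem scores must be nonnegative")
        total += motoric + cerebellar + proprioceptive
    return total


def add_subpanels(cohort: pd.DataFrame) -> pd.DataFrame:
    """Extend a flattened cohort table with the composite subpanel columns.

    Adds ``neurex_postural_sway``, ``neurex_pronator_drift``, per-hand
    ``cerebellar_dom``/``cerebellar_ndom`` and an ``mri_infratentorial``
    aggregate (sum of atrophy + lesion-load grades over brainstem,
    cerebellum, medulla/upper cervical spine).
    """
    out = cohort.copy()
    out["neurex_postural_sway"] = [
        neurex_postural_sway(r["panel16"], r["panel12_lower"], r["panel14_lower"])
        for _, r in cohort.iterrows()
    ]
    out["neurex_pronator_drift"] = [
        neurex_pronator_drift(
            {
                h: (
                    hand_motoric(r[f"panel8_{h}"], r[f"panel10_{h}"], r[f"panel7_{h}"]),
                    r[f"panel12_{h}"],
                    r[f"panel14_{h}"],
                )
                for h in HANDS
            }
        )
        for _, r in cohort.iterrows()
    ]
    dom = cohort["dominant_hand"]
    out["cerebellar_dom"] = [
        r[f"panel12_{d}"] for (_, r), d in zip(cohort.iterrows(), dom)
    ]
    out["cerebellar_ndom"] = [
        r["panel12_left" if d == "right" else "panel12_right"]
        for (_, r), d in zip(cohort.iterrows(), dom)
    ]
    mri_cols = [c for c in cohort.columns if c.startswith("mri_")]
    out["mri_infratentorial"] = cohort[mri_cols].sum(axis=1)
    return out
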