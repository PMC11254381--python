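"""Behavioral asymmetry: per-side accuracy and response time summaries, the
BA index, and the winning-model regression with BA as the response."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .glm import ModelFitResult, fit_ols
from .laterality import behavioral_asymmetry


def summarize_behavior(trials: pd.DataFrame,
                       rt_correct_only: bool = True) -> pd.DataFrame:
    """Per-subject behavioral summary split by attended (cued) side.

    Accuracy per side is correct/total; RT per side is the mean over correct
    trials by default (``rt_correct_only=False`` averages all trials).
    BA = (right - left)/(right + left) for both metrics.  Raises when a
    subject lacks trials (or, for accuracy, correct responses) on a side.
    """
    required = {"subject_id", "cue_side", "correct", "rt"}
    if not required <= set(trials.columns):
        raise ValueError(f"behavior table needs columns {sorted(required)}")
    rows = []
    for subj, g in trials.groupby("subject_id", sort=False):
        per_side = {}
        for side in ("left", "right"):
            gs = g[g["cue_side"] == side]
            if len(gs) == 0:
                raise ValueError(f"subject {subj}: no trials with cue {side}")
            acc = float(gs["correct"].mean())
            rt_pool = gs[gs["correct"] == 1] if rt_correct_only else gs
            if len(rt_pool) == 0:
                raise ValueError(
                    f"subject {subj}: no correct trials with cue {side}")
            per_side[side] = (acc, float(rt_pool["rt"].mean()), len(gs))
        acc_l, rt_l, n_l = per_side["left"]
        acc_r, rt_r, n_r = per_side["right"]
        if acc_l <= 0 or acc_r <= 0:
            raise ValueError(f"subject {subj}: zero accuracy on one side")
        rows.append({
            "subject_id": subj,
            "n_left": n_l, "n_right": n_r,
            "acc_left": acc_l, "acc_right": acc_r,
            "rt_left": rt_l, "rt_right": rt_r,
            "ba_acc": behavioral_asymmetry(acc_r, acc_l),
            "ba_rt": behavioral_asymmetry(rt_r, rt_l),
        })
    return pd.DataFrame(rows).set_index("subject_id")


def fit_behavior_glm(ba, lv_matrix: pd.DataFrame,
                     structures=("Th", "CN", "GP")) -> ModelFitResult:
    """Refit the winning structural model with a behavioral asymmetry as the
    response (run separately for BA in accuracy and in RT)."""
    missing = [s for s in structures if s not in lv_matrix.columns]
    if missing:
        raise ValueError(f"LV matrix lacks structures: {missing}")
    return fit_ols(lv_matrix[list(structures)], np.asarray(ba, dtype=float))
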