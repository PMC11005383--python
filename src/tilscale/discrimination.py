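"""Known-groups validity: ROC curves, AUC and optimal thresholds.

The discrimination question is whether a treatment-intensity score
separates patients who experienced refractory intracranial hypertension
from those who did not, and whether the daily score flags days of
surgical ICP control.  AUC is computed as the Mann-Whitney pairwise
probability (ties credited 0.5): the probability that a randomly
selected positive patient has a higher score than a randomly selected
negative one.

Thresholds are reported in ">= t" form, with t at midpoints between
adjacent distinct score values, so half-integer cut-offs on
median-based summaries (e.g. a weekly-median threshold of 7.5) are
representable.  The selected threshold maximizes sensitivity +
specificity; ties break toward the lower threshold (the more sensitive
rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import scales

__all__ = ["ROCResult", "roc", "best_threshold", "surgical_day_detection"]


@dataclass(frozen=True)
class ROCResult:
    """Full threshold grid for one score against one binary label."""

    score_name: str
    label_name: str
    thresholds: np.ndarray  # ascending; rule is "positive if score >= t"
    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "score": self.score_name,
                "label": self.label_name,
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy,
                "auc": self.auc,
            }
        )


def roc(scores, labels, score_name: str = "score", label_name: str = "label") -> ROCResult:
    """ROC analysis of a score against a binary label.

    Complete pairs only; both classes must be present.  AUC uses the
    rank (Mann-Whitney) formulation with ties counted half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    keep = ~(np.isnan(s) | np.isnan(y))
    s, y = s[keep], y[keep].astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"ROC needs both classes: {n_pos} positive, {n_neg} negative"
        )
    ranks = stats.rankdata(s)  # average ranks credit ties 0.5
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[0]], mids, [distinct[-1] + 1.0]])
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    acc = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        sens[i] = tp / n_pos
        spec[i] = tn / n_neg
        acc[i] = (tp + tn) / (n_pos + n_neg)
    return ROCResult(
        score_name=score_name,
        label_name=label_name,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        auc=float(auc),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def best_threshold(result: ROCResult) -> dict:
    """The threshold maximizing sensitivity + specificity.

    Exhaustive over the full grid; ties break toward the lower (more
    sensitive) threshold.
    """
    j = result.sensitivity + result.specificity
    i = int(np.argmax(j))  # argmax returns the first (lowest-threshold) maximum
    return {
        "threshold": float(result.thresholds[i]),
        "sensitivity": float(result.sensitivity[i]),
        "specificity": float(result.specificity[i]),
        "accuracy": float(result.accuracy[i]),
        "youden_sum": float(j[i]),
    }


def surgical_day_detection(
    daily_scores: pd.DataFrame, therapy: pd.DataFrame, carry_forward: bool = True
) -> ROCResult:
    """ROC of the daily TIL score against days of surgical ICP control.

    A patient-day counts as surgical ICP control when an intracranial
    operation or decompressive craniectomy is recorded; with
    ``carry_forward`` (the default), every day after a last-resort
    craniectomy also counts.  ``daily_scores`` must hold one scale's
    daily values (patient_id, day, value).
    """
    ther = scales.apply_dc_carryforward(therapy) if carry_forward else therapy
    lab = ther[["patient_id", "day"]].copy()
    lab["surgical"] = (
        (ther["intracranial_op"].fillna(0).astype(int) == 1)
        | (ther["dc"].fillna(0).astype(int) == 1)
    ).astype(int)
    merged = daily_scores.merge(lab, on=["patient_id", "day"], how="inner")
    merged = merged[merged["value"].notna()]
    return roc(
        merged["value"].to_numpy(dtype=float),
        merged["surgical"].to_numpy(),
        score_name="TIL_24",
        label_name="surgical_icp_control",
    )
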