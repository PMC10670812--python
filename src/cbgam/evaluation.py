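"""ROC-based performance assessment of the averaged model.

The whole-cohort ROC curve of the averaged-model scores carries the
trapezoidal AUC and the Youden index J = max(TPR - FPR); the AUC spread is
reported as mean +/- sd of the per-iteration out-of-bag AUCs.  Per
molecular subtype (luminal A/B, Her-2 enriched, triple negative) the AUC
and the accuracy at the global Youden-optimal threshold are reported, with
single-class subtypes flagged undefined rather than silently scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics

__all__ = ["RocCurve", "SubtypePerformance", "roc_curve", "youden",
           "evaluate_ensemble", "EvaluationResult"]


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    youden_j: float
    youden_threshold: float
    auc_spread: tuple | None = None  # (mean, sd) of bootstrap out-of-bag AUCs

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        ).to_csv(path, index=False)


def roc_curve(labels, scores) -> RocCurve:
    """ROC over all distinct score thresholds; trapezoidal AUC.

    Ties in scores move TPR and FPR simultaneously (diagonal segments), so
    the trapezoidal area equals the tie-adjusted Mann-Whitney concordance.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = metrics.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    jmax = float(j.max())
    # smallest optimizing threshold on ties; sklearn thresholds descend
    ties = np.flatnonzero(j == jmax)
    thr_opt = float(thr[ties[-1]])
    return RocCurve(
        thresholds=thr, fpr=fpr, tpr=tpr, auc=auc,
        youden_j=jmax, youden_threshold=thr_opt,
    )


def youden(curve: RocCurve) -> tuple[float, float]:
    """(J, optimizing threshold) of a fitted ROC curve."""
    return curve.youden_j, curve.youden_threshold


@dataclass
class SubtypePerformance:
    """Per-subtype sample size, CB prevalence, AUC and thresholded accuracy."""

    table: pd.DataFrame  # subtype, n, prevalence, auc, accuracy, defined

    def to_json(self, path=None) -> str:
        doc = json.dumps(self.table.to_dict(orient="records"), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc


@dataclass
class EvaluationResult:
    roc: RocCurve
    subtypes: SubtypePerformance
    in_sample_auc: float = field(init=False)

    def __post_init__(self):
        self.in_sample_auc = self.roc.auc

    def summary(self) -> dict:
        return {
            "auc_in_sample": self.roc.auc,
            "auc_oob_mean": None if self.roc.auc_spread is None
            else self.roc.auc_spread[0],
            "auc_oob_sd": None if self.roc.auc_spread is None
            else self.roc.auc_spread[1],
            "youden_j": self.roc.youden_j,
            "youden_threshold": self.roc.youden_threshold,
            "subtypes": self.subtypes.table.to_dict(orient="records"),
        }


def evaluate_ensemble(ensemble, X: pd.DataFrame, y, subtypes) -> EvaluationResult:
    """Whole-cohort ROC of the averaged model plus per-subtype performance.

    The AUC spread (mean +/- sd across the ensemble's out-of-bag records)
    quantifies out-of-sample variability; the curve itself is in-sample.
    Accuracy is computed at the global Youden-optimal probability threshold.
    """
    y = np.asarray(y)
    scores = ensemble.predict_proba(X)[:, 1]
    curve = roc_curve(y, scores)
    if hasattr(ensemble, "oob_auc_mean_"):
        curve.auc_spread = (ensemble.oob_auc_mean_, ensemble.oob_auc_sd_)

    rows = []
    thr = curve.youden_threshold
    for subtype in sorted(pd.unique(np.asarray(subtypes))):
        mask = np.asarray(subtypes) == subtype
        ys, ss = y[mask], scores[mask]
        defined = len(np.unique(ys)) == 2
        rows.append({
            "subtype": subtype,
            "n": int(mask.sum()),
            "prevalence": float(ys.mean()),
            "auc": float(metrics.roc_auc_score(ys, ss)) if defined else None,
            "accuracy": float(((ss >= thr).astype(int) == ys).mean()),
            "defined": bool(defined),
        })
    table = pd.DataFrame(rows)
    assert table["n"].sum() == len(y)
    return EvaluationResult(roc=curve, subtypes=SubtypePerformance(table))
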