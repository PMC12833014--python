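"""ROC/AUC scoring, DeLong comparison, and ground-truth recovery metrics.

These operations score any case-level risk scores against binary event
status, so externally trained classifiers can be compared without this
package training them.  AUC uses the Mann-Whitney identity with midrank
tie handling; the DeLong test uses the placement-value variance/covariance
estimator for two correlated AUCs on the same cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["roc_auc", "delong_test", "recovery_metrics",
           "ROCResult", "DeLongResult", "RecoveryReport"]


def _check_scored(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d vectors")
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1}:
        raise ValueError("labels must be 0/1")
    if uniq != {0, 1}:
        raise ValueError("both classes must be present")
    return scores, labels.astype(int)


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC.

    AUC is the midrank Mann-Whitney statistic U / (n1 * n0): ties between a
    case and a non-case count one half.  The curve steps through the
    distinct score values from the most extreme threshold, running from
    (0, 0) to (1, 1); tied scores move diagonally in one step.
    """
    scores, labels = _check_scored(scores, labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1

    ranks = stats.rankdata(scores)  # midranks
    auc = (float(ranks[labels == 1].sum()) - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # indices where the threshold (score) changes
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    idx = np.r_[distinct, sorted_labels.size - 1]
    tps = np.cumsum(sorted_labels)[idx]
    fps = (idx + 1) - tps
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    thresholds = np.r_[np.inf, sorted_scores[idx]]
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components (placement values) for one model."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n          # per-positive placement
    v01 = 1.0 - (tz[m:] - ty) / m    # per-negative placement
    return auc, v10, v01


@dataclass
class DeLongResult:
    auc1: float
    auc2: float
    diff: float
    var: float
    z: float
    p: float


def delong_test(scores1, scores2, labels) -> DeLongResult:
    """DeLong test for the difference of two correlated AUCs.

    Both score vectors must be on the same cases with the same labels.
    A model compared with itself has zero variance; by convention z = 0 and
    p = 1 then.  The p-value is two-sided normal.
    """
    s1, lab = _check_scored(scores1, labels)
    s2, lab2 = _check_scored(scores2, labels)
    if not np.array_equal(lab, lab2):
        raise ValueError("label vectors differ between the two score sets")
    auc1, v10_1, v01_1 = _placements(s1, lab)
    auc2, v10_2, v01_2 = _placements(s2, lab)
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc1 - auc2
    if var <= 0:
        z = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / math.sqrt(var)
        p = 2.0 * float(stats.norm.sf(abs(z)))
    return DeLongResult(auc1=float(auc1), auc2=float(auc2), diff=float(diff),
                        var=float(max(var, 0.0)), z=float(z), p=p)


@dataclass
class RecoveryReport:
    sensitivity: float
    fdp: float
    table: pd.DataFrame

    @property
    def n_true(self) -> int:
        return int(self.table["is_signal"].sum())

    @property
    def n_detected(self) -> int:
        return int(self.table["detected"].sum())


def recovery_metrics(detected, truth) -> RecoveryReport:
    """Compare a detection set against the generator's ground truth.

    ``detected`` is an iterable of drug names (e.g. the consensus set of a
    signal scan, or a list of :class:`pvsignal.signals.SignalResult`);
    ``truth`` a :class:`pvsignal.synth.GroundTruth` or a plain set of true
    signal drugs.  Sensitivity = detected true / true; false discovery
    proportion = false detections / detections (0 when nothing detected).
    """
    det = set()
    for d in detected:
        if hasattr(d, "drug"):
            if getattr(d, "consensus", True):
                det.add(d.drug)
        else:
            det.add(d)
    signals = set(truth.signals) if hasattr(truth, "signals") else set(truth)
    drugs = sorted(signals | det)
    table = pd.DataFrame({
        "drug": drugs,
        "is_signal": [g in signals for g in drugs],
        "detected": [g in det for g in drugs],
    }).set_index("drug")
    tp = len(det & signals)
    sens = tp / len(signals) if signals else 1.0
    fdp = (len(det) - tp) / len(det) if det else 0.0
    return RecoveryReport(sensitivity=float(sens), fdp=float(fdp), table=table)
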