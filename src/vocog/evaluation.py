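"""Screening metrics and the published discrimination-test fixture.

Decisions use the "probability ≥ 0.5 means CD" rule.  AUC is computed
as pairwise concordance — the probability that a random CD clip scores
above a random CN clip, with ties counting one half — which handles
tied scores exactly; the trapezoid integral of the threshold-swept ROC
curve is kept as a cross-check (they agree whenever no ties exist).

``table2_fixture`` packages the 20-subject held-out discrimination
test published for this model (clinical diagnosis, MMSE, label, model
probability), so the entire evaluation layer can be reproduced exactly:
accuracy 0.950, sensitivity 0.875, specificity 1.000, AUC 0.990.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .labeling import SubjectRecord, label_from_mmse
from .model import CD_THRESHOLD


@dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc: list[tuple[float, float]] = field(default_factory=list)
    threshold: float = CD_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "auc": self.auc,
            "roc": [list(p) for p in self.roc], "threshold": self.threshold,
        }


def _check_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray([p for p, _ in pairs], dtype=np.float64)
    labels = np.asarray([y for _, y in pairs])
    if len(probs) == 0:
        raise ValueError("no (probability, label) pairs given")
    if not set(np.unique(labels)).issubset({0, 1}):
        raise ValueError("labels must be 0 (CN) or 1 (CD)")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return probs, labels.astype(int)


def roc_auc(pairs) -> tuple[float, list[tuple[float, float]]]:
    """Concordance AUC plus the threshold-swept ROC points.

    AUC = (concordant + 0.5 × tied) / (n_CD × n_CN), evaluated via the
    rank-sum identity.  ROC points sweep every distinct probability as
    a cutoff (decision: score ≥ cutoff), from (0, 0) to (1, 1).
    """
    probs, labels = _check_pairs(pairs)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        missing = "CD (label 1)" if n_pos == 0 else "CN (label 0)"
        raise ValueError(f"AUC needs both classes; missing: {missing}")
    ranks = rankdata(probs)  # average ranks handle ties as half-concordant
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    points = [(0.0, 0.0)]
    for cut in sorted(set(probs), reverse=True):
        dec = probs >= cut
        tpr = float((dec & (labels == 1)).sum() / n_pos)
        fpr = float((dec & (labels == 0)).sum() / n_neg)
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return float(auc), points


def trapezoid_auc(roc: list[tuple[float, float]]) -> float:
    """Trapezoid integral of an ROC point list (cross-check for roc_auc)."""
    fpr = np.array([p[0] for p in roc])
    tpr = np.array([p[1] for p in roc])
    return float(np.trapezoid(tpr, fpr))


def evaluate(pairs, threshold: float = CD_THRESHOLD) -> EvalReport:
    """Confusion counts and screening metrics at a decision threshold.

    With only one class present the undefined rate (sensitivity without
    positives, specificity without negatives) and the AUC are reported
    as NaN rather than silently zero.
    """
    probs, labels = _check_pairs(pairs)
    dec = probs >= threshold
    tp = int((dec & (labels == 1)).sum())
    fp = int((dec & (labels == 0)).sum())
    tn = int((~dec & (labels == 0)).sum())
    fn = int((~dec & (labels == 1)).sum())
    n_pos, n_neg = tp + fn, tn + fp
    sens = tp / n_pos if n_pos else math.nan
    spec = tn / n_neg if n_neg else math.nan
    if n_pos and n_neg:
        auc, roc = roc_auc(pairs)
    else:
        auc, roc = math.nan, []
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / len(labels),
        sensitivity=sens, specificity=spec, auc=auc, roc=roc,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Published 20-subject discrimination test (diagnosis, MMSE, probability)
# ---------------------------------------------------------------------------

_TABLE2_ROWS: list[tuple[str, int, float]] = [
    ("SCD", 30, 0.0367),
    ("SCD", 29, 0.2156),
    ("SCD", 29, 0.1927),
    ("SCD", 28, 0.2509),
    ("SCD", 28, 0.2191),
    ("MCI", 27, 0.2174),
    ("MCI", 26, 0.2940),
    ("MCI", 25, 0.2372),
    ("MCI", 25, 0.1882),
    ("MCI", 25, 0.3585),
    ("MCI", 24, 0.4930),
    ("MCI", 24, 0.3877),
    ("AD", 23, 0.4734),
    ("AD", 23, 0.5320),
    ("AD", 21, 0.7185),
    ("DLB", 19, 0.7641),
    ("AD", 18, 0.5831),
    ("VaD", 17, 0.7356),
    ("AD", 13, 0.7136),
    ("DLB", 13, 0.8704),
]


def table2_fixture() -> tuple[list[SubjectRecord], list[tuple[float, int]]]:
    """The published 20-row held-out test set as records + (prob, label) pairs.

    Labels are derived from the MMSE column by the 23/24 rule (they
    match the published labeling column exactly).
    """
    records = []
    pairs = []
    for i, (dx, mmse, prob) in enumerate(_TABLE2_ROWS, start=1):
        label = label_from_mmse(mmse)
        records.append(
            SubjectRecord(subject_id=f"t2-{i:02d}", mmse=mmse, label=label, diagnosis=dx)
        )
        pairs.append((prob, label))
    return records, pairs
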