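"""Cohort-quality metrics: PPV, recall, F-measure, AUC, pairwise IAA.

Positive-class conventions follow the study design this package
implements: the rule-based classifier is scored with gold {yes, maybe}
as positive (an uncertain chart-review verdict still indicates a
probable case), while the final "yes"-only evaluation of the two-stage
classifier treats {no, maybe, unknown} as negative.

Undefined ratios (0/0) surface as None rather than 0 so a degenerate
cohort cannot silently inflate a score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .core_io import PatientRecord

#: Gold labels counted as positive when scoring case-vs-non-case output.
POSITIVE_YES_MAYBE = frozenset({"yes", "maybe"})
#: Gold labels counted as positive in the final "definite case" evaluation.
POSITIVE_YES_ONLY = frozenset({"yes"})


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int
    tn: int
    auc: Optional[float] = None

    @property
    def ppv(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.ppv, self.recall
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)

    def rounded(self, ndigits: int = 3) -> dict:
        """Render defined metrics to the customary 3 decimals."""
        out = {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}
        for name in ("ppv", "recall", "f1", "auc"):
            val = getattr(self, name)
            out[name] = round(val, ndigits) if val is not None else None
        return out


def f1_from(ppv: float, recall: float) -> float:
    """Harmonic mean of precision and recall: 2pr / (p + r)."""
    if ppv + recall == 0:
        return 0.0
    return 2 * ppv * recall / (ppv + recall)


def binary_metrics(
    predictions: Sequence[bool], gold: Sequence[bool]
) -> EvalReport:
    """Confusion counts and PPV/recall/F1 from aligned binary vectors."""
    if len(predictions) != len(gold):
        raise ValueError("predictions and gold must have equal length")
    pred = np.asarray(predictions, dtype=bool)
    g = np.asarray(gold, dtype=bool)
    return EvalReport(
        tp=int(np.sum(pred & g)),
        fp=int(np.sum(pred & ~g)),
        fn=int(np.sum(~pred & g)),
        tn=int(np.sum(~pred & ~g)),
    )


def auc_score(scores: Sequence[float], gold: Sequence[bool]) -> float:
    """Area under the ROC curve via rank statistics.

    Equals the probability that a random positive outscores a random
    negative, with ties counted one half.
    """
    g = np.asarray(gold, dtype=bool)
    if g.all() or not g.any():
        raise ValueError("AUC needs both classes present in gold")
    return float(roc_auc_score(g.astype(int), np.asarray(scores, dtype=float)))


def pairwise_iaa_f(
    annotations_a: Mapping[str, str],
    annotations_b: Mapping[str, str],
    category: str,
) -> float:
    """Pairwise F-measure between two annotators for one label category.

    Treats annotator A as reference: precision = |A_c & B_c| / |B_c|,
    recall = |A_c & B_c| / |A_c|; F is their harmonic mean, which is
    symmetric under swapping the annotators.
    """
    a_c = {p for p, lab in annotations_a.items() if lab == category}
    b_c = {p for p, lab in annotations_b.items() if lab == category}
    if not a_c and not b_c:
        raise ValueError(
            f"category {category!r} assigned by neither annotator; "
            "pairwise F undefined"
        )
    overlap = len(a_c & b_c)
    denom = len(a_c) + len(b_c)
    return 2 * overlap / denom


def baseline_eval(
    screened: Sequence[PatientRecord],
    positive_labels: frozenset[str] = POSITIVE_YES_MAYBE,
) -> float:
    """PPV of the ICD-9-only baseline on an already screened cohort.

    Every screened patient is a predicted case, so PPV is simply the
    gold-positive fraction.  Recall is deliberately not computed: the
    baseline never sees patients outside the ICD-9 screen, so its false
    negatives are unobservable.
    """
    if not screened:
        raise ValueError("baseline_eval needs a non-empty screened cohort")
    unlabeled = [p.patient_id for p in screened if p.gold_label is None]
    if unlabeled:
        raise ValueError(
            f"{len(unlabeled)} screened patients lack gold labels"
        )
    n_pos = sum(1 for p in screened if p.gold_label in positive_labels)
    return n_pos / len(screened)
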