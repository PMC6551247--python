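"""Score recruited reads against ground-truth labels.

True positives are homolog-labeled reads that were recruited to their
query; false positives are non-homolog reads that were recruited; false
negatives are homolog reads missed. Boundary reads contribute to no count
at all. Undefined ratios (zero denominators) are reported as ``None``,
never coerced to 0 or 1. ROC curves sweep the recruitment over a range of
E-value cutoffs (default 1e6 down to 1e-10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .read_recruitment import RecruitedRead
from .synthetic_data import GroundTruthLabel

__all__ = ["EvalCounts", "score_predictions", "roc_over_cutoffs", "default_cutoffs"]


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fp: int
    fn: int

    @property
    def recall(self) -> Optional[float]:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def precision(self) -> Optional[float]:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None

    @property
    def f_measure(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)


def score_predictions(
    recruited: Sequence[RecruitedRead],
    truth: Sequence[GroundTruthLabel],
) -> Tuple[EvalCounts, Dict[str, EvalCounts]]:
    """Pooled (micro) and per-query counts with boundary exclusion.

    A prediction naming a read id absent from the truth set raises
    ``KeyError``. A homolog read recruited to the *wrong* query counts as
    a false negative for its true query and a false positive for the
    predicted one.
    """
    label_of = {t.read_id: t for t in truth}
    pred_of: Dict[str, RecruitedRead] = {}
    for r in recruited:
        if r.read_id not in label_of:
            raise KeyError(f"prediction for unknown read id {r.read_id!r}")
        pred_of[r.read_id] = r

    queries = sorted(
        {t.query_id for t in truth if t.label == "homolog" and t.query_id}
        | {r.assigned_query for r in recruited}
    )
    per_query: Dict[str, Dict[str, int]] = {q: {"tp": 0, "fp": 0, "fn": 0} for q in queries}
    for t in truth:
        if t.label == "boundary":
            continue
        pred = pred_of.get(t.read_id)
        if t.label == "homolog":
            if pred is not None and pred.assigned_query == t.query_id:
                per_query[t.query_id]["tp"] += 1
            else:
                per_query[t.query_id]["fn"] += 1
                if pred is not None:
                    per_query[pred.assigned_query]["fp"] += 1
        else:  # non_homolog
            if pred is not None:
                per_query[pred.assigned_query]["fp"] += 1
    by_query = {q: EvalCounts(**c) for q, c in per_query.items()}
    pooled = EvalCounts(
        tp=sum(c.tp for c in by_query.values()),
        fp=sum(c.fp for c in by_query.values()),
        fn=sum(c.fn for c in by_query.values()),
    )
    return pooled, by_query


def default_cutoffs() -> List[float]:
    """E-value sweep from 1e6 down to 1e-10 in decade steps."""
    return [10.0**e for e in range(6, -11, -1)]


def roc_over_cutoffs(
    predictions_by_cutoff: Mapping[float, Sequence[RecruitedRead]],
    truth: Sequence[GroundTruthLabel],
) -> List[Tuple[float, Optional[float], Optional[float]]]:
    """One (cutoff, precision, recall) point per cutoff, loosest first.

    With nested prediction sets, recall is non-increasing as the cutoff
    tightens.
    """
    points = []
    for cutoff in sorted(predictions_by_cutoff, reverse=True):
        pooled, _ = score_predictions(predictions_by_cutoff[cutoff], truth)
        points.append((cutoff, pooled.precision, pooled.recall))
    return points
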