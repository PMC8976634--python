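"""Confusion counts and the PPV / recall / F-score metrics.

PVC is the positive class throughout: a true positive is a window
predicted PVC whose ground-truth label is PVC.  Metrics are reported
in percent —

* PPV (precision)      = 100 · TP / (TP + FP)
* recall (sensitivity) = 100 · TP / (TP + FN)
* F-score              = harmonic mean of PPV and recall

A metric with a zero denominator is *undefined* and reported as
``None`` (never coerced to 0 or 100).  The aggregate over a test set is
computed both from pooled counts (micro, the headline number) and as
the mean of per-record metrics (macro).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import PVC_LABEL

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def confusion(pred, truth, positive: str = PVC_LABEL) -> ConfusionCounts:
    """Tally the confusion counts of two equal-length label sequences."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    p = pred == positive
    t = truth == positive
    return ConfusionCounts(
        tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)), fn=int(np.sum(~p & t)))


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        raise ValueError("F undefined when precision + recall = 0")
    return 2.0 * precision * recall / (precision + recall)


def metrics(counts: ConfusionCounts) -> dict:
    """PPV, recall and F (percent) from confusion counts.

    Undefined metrics come back as ``None`` with ``undefined`` listing
    their names.
    """
    undefined = []
    ppv = recall = f = None
    if counts.tp + counts.fp > 0:
        ppv = 100.0 * counts.tp / (counts.tp + counts.fp)
    else:
        undefined.append("ppv")
    if counts.tp + counts.fn > 0:
        recall = 100.0 * counts.tp / (counts.tp + counts.fn)
    else:
        undefined.append("recall")
    if ppv is not None and recall is not None and ppv + recall > 0:
        f = f_measure(ppv, recall)
    else:
        undefined.append("f_score")
    return {"ppv": ppv, "recall": recall, "f_score": f,
            "counts": counts, "undefined": undefined}


@dataclass
class MetricsReport:
    """Aggregate + per-record window-level metrics of one evaluation."""

    counts: ConfusionCounts
    ppv: float | None
    recall: float | None
    f_score: float | None
    macro_ppv: float | None
    macro_recall: float | None
    macro_f_score: float | None
    per_record: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = self.per_record.copy()
        agg = pd.DataFrame([
            {"record_id": "all (micro)", "ppv": self.ppv,
             "recall": self.recall, "f_score": self.f_score,
             "tp": self.counts.tp, "fp": self.counts.fp,
             "tn": self.counts.tn, "fn": self.counts.fn},
            {"record_id": "all (macro)", "ppv": self.macro_ppv,
             "recall": self.macro_recall, "f_score": self.macro_f_score},
        ])
        return pd.concat([rows, agg], ignore_index=True)

    def render(self) -> str:
        """Plain-text table (1 decimal place) of per-record + aggregate."""
        df = self.to_frame()
        lines = [f"{'Record':>12} {'PPV':>7} {'Recall':>7} {'F-score':>8}"]
        for _, row in df.iterrows():
            def fmt(v):
                return "  n/a" if pd.isna(v) else f"{v:.1f}"
            lines.append(f"{row['record_id']:>12} {fmt(row['ppv']):>7} "
                         f"{fmt(row['recall']):>7} {fmt(row['f_score']):>8}")
        return "\n".join(lines)


def per_record_report(pred, truth, record_ids) -> MetricsReport:
    """Window-level metrics per record plus micro/macro aggregates.

    Records whose truth contains no PVC window have undefined recall;
    they are left out of the per-record rows (logged) but still
    contribute to the pooled counts.
    """
    df = pd.DataFrame({"record_id": record_ids, "pred": pred,
                       "truth": truth})
    rows = []
    total = ConfusionCounts(0, 0, 0, 0)
    for rid, grp in df.groupby("record_id", sort=True):
        c = confusion(grp["pred"].to_numpy(), grp["truth"].to_numpy())
        total = total + c
        if c.tp + c.fn == 0:
            logger.info("record %s has no PVC windows in truth; "
                        "recall undefined, row omitted", rid)
            continue
        m = metrics(c)
        rows.append({"record_id": rid, "ppv": m["ppv"],
                     "recall": m["recall"], "f_score": m["f_score"],
                     "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn})
    per_record = pd.DataFrame(
        rows, columns=["record_id", "ppv", "recall", "f_score",
                       "tp", "fp", "tn", "fn"])
    agg = metrics(total)
    macro = {k: (float(per_record[k].dropna().mean())
                 if len(per_record) and per_record[k].notna().any()
                 else None)
             for k in ("ppv", "recall", "f_score")}
    return MetricsReport(
        counts=total, ppv=agg["ppv"], recall=agg["recall"],
        f_score=agg["f_score"], macro_ppv=macro["ppv"],
        macro_recall=macro["recall"], macro_f_score=macro["f_score"],
        per_record=per_record)
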