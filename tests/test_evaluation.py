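"""Confusion tallies and the PPV / recall / F-score algebra."""

import numpy as np
import pandas as pd
import pytest

from pvcdetect.evaluation import (ConfusionCounts, confusion, f_measure,
                                  metrics, per_record_report)


def test_perfect_agreement():
    c = confusion(["PVC", "PVC", "non-PVC", "non-PVC"],
                  ["PVC", "PVC", "non-PVC", "non-PVC"])
    assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)


def test_degenerate_all_negative_predictor():
    truth = ["PVC"] * 3 + ["non-PVC"] * 7
    c = confusion(["non-PVC"] * 10, truth)
    assert (c.tp, c.fn, c.tn, c.fp) == (0, 3, 7, 0)


def test_counts_match_brute_force_tally(rng):
    labels = np.array(["PVC", "non-PVC"])
    pred = labels[rng.integers(0, 2, 100)]
    truth = labels[rng.integers(0, 2, 100)]
    c = confusion(pred, truth)
    tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for p, t in zip(pred, truth):
        key = (("t" if p == t else "f")
               + ("p" if p == "PVC" else "n"))
        tally[key] += 1
    assert (c.tp, c.fp, c.tn, c.fn) == (
        tally["tp"], tally["fp"], tally["tn"], tally["fn"])
    assert c.total == 100


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        confusion(["PVC"], ["PVC", "PVC"])


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ConfusionCounts(1, -1, 0, 0)


def test_perfect_classifier_metrics():
    m = metrics(ConfusionCounts(tp=100, fp=0, tn=50, fn=0))
    assert m["ppv"] == 100.0 and m["recall"] == 100.0
    assert m["f_score"] == 100.0


@pytest.mark.parametrize("ppv,recall,expected", [
    (99.5, 100.0, 99.7),
    (95.4, 94.3, 94.8),
    (98.7, 96.3, 97.5),
    (97.5, 94.1, 95.8),
])
def test_f_measure_published_rows(ppv, recall, expected):
    assert round(f_measure(ppv, recall), 1) == expected


def test_f_measure_symmetric_and_bounded(rng):
    for _ in range(100):
        p, r = rng.uniform(1, 100, 2)
        f = f_measure(p, r)
        assert f == pytest.approx(f_measure(r, p))
        assert min(p, r) <= f + 1e-12
        assert f <= (p + r) / 2 + 1e-12
    x = rng.uniform(1, 100)
    assert f_measure(x, x) == pytest.approx(x)


def test_f_measure_undefined_at_zero():
    with pytest.raises(ValueError):
        f_measure(0.0, 0.0)


def test_undefined_metrics_are_none_not_zero():
    m = metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=0))
    assert m["ppv"] is None and m["recall"] is None
    assert set(m["undefined"]) == {"ppv", "recall", "f_score"}


def test_metric_bounds_f_between_ppv_recall(rng):
    for _ in range(50):
        tp, fp, fn, tn = rng.integers(1, 50, 4)
        m = metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
        assert min(m["ppv"], m["recall"]) <= m["f_score"] + 1e-12
        assert m["f_score"] <= max(m["ppv"], m["recall"]) + 1e-12


def _toy_predictions():
    rows = []
    for rid, (tp, fp, tn, fn) in {"a": (5, 1, 10, 2),
                                  "b": (5, 1, 10, 2),
                                  "c": (3, 0, 12, 1)}.items():
        rows += [(rid, "PVC", "PVC")] * tp
        rows += [(rid, "PVC", "non-PVC")] * fp
        rows += [(rid, "non-PVC", "non-PVC")] * tn
        rows += [(rid, "non-PVC", "PVC")] * fn
    return pd.DataFrame(rows, columns=["record_id", "pred", "truth"])


def test_identical_records_get_identical_rows():
    df = _toy_predictions()
    report = per_record_report(df["pred"], df["truth"], df["record_id"])
    per = report.per_record.set_index("record_id")
    assert per.loc["a"].equals(per.loc["b"])


def test_aggregate_counts_are_sum_of_per_record():
    df = _toy_predictions()
    report = per_record_report(df["pred"], df["truth"], df["record_id"])
    per = report.per_record
    assert report.counts.tp == per["tp"].sum()
    assert report.counts.total == len(df)


def test_micro_metrics_equal_pooled_confusion():
    df = _toy_predictions()
    report = per_record_report(df["pred"], df["truth"], df["record_id"])
    pooled = metrics(confusion(df["pred"].to_numpy(),
                               df["truth"].to_numpy()))
    assert report.ppv == pytest.approx(pooled["ppv"])
    assert report.recall == pytest.approx(pooled["recall"])
    assert report.f_score == pytest.approx(pooled["f_score"])


def test_record_without_positive_truth_omitted_but_pooled():
    df = pd.DataFrame({
        "record_id": ["x"] * 4 + ["y"] * 4,
        "pred": ["PVC", "non-PVC", "non-PVC", "non-PVC"] * 2,
        "truth": ["PVC", "PVC", "non-PVC", "non-PVC",
                  "non-PVC", "non-PVC", "non-PVC", "non-PVC"],
    })
    report = per_record_report(df["pred"], df["truth"], df["record_id"])
    assert list(report.per_record["record_id"]) == ["x"]
    assert report.counts.total == 8


def test_permutation_applied_to_both_sides_leaves_metrics(rng):
    df = _toy_predictions()
    perm = rng.permutation(len(df))
    base = per_record_report(df["pred"], df["truth"], df["record_id"])
    shuf = per_record_report(df["pred"].to_numpy()[perm],
                             df["truth"].to_numpy()[perm],
                             df["record_id"].to_numpy()[perm])
    assert base.ppv == pytest.approx(shuf.ppv)
    assert base.f_score == pytest.approx(shuf.f_score)


def test_render_is_one_decimal_place():
    df = _toy_predictions()
    report = per_record_report(df["pred"], df["truth"], df["record_id"])
    text = report.render()
    assert "all (micro)" in text
    for token in text.split():
        if "." in token and token.replace(".", "").isdigit():
            assert len(token.split(".")[1]) == 1
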