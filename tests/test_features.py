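"""Feature formulas against a naive-loop oracle, labeling, normalization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pvcdetect.ecg_io import BeatAnnotation
from pvcdetect.features import (FEATURE_ORDER, apply_normalization,
                                extract_features, fit_normalization,
                                label_window, morphological_features,
                                segment_windows, statistical_features)
from pvcdetect.beat_detection import BeatFiducials
from pvcdetect.synthetic_ecg import SynthConfig, generate_record


def naive_statistics(rr):
    """Independent plain-loop reference for the seven RR statistics."""
    n = len(rr)
    mean_rr = sum(rr) / n
    sdrr = math.sqrt(sum((x - mean_rr) ** 2 for x in rr) / n)
    d = [rr[i + 1] - rr[i] for i in range(n - 1)]
    mean_d = sum(d) / len(d)
    sdsd = math.sqrt(sum((x - mean_d) ** 2 for x in d) / len(d))
    rmssd = math.sqrt(sum(x * x for x in d) / len(d))
    prr10 = 100.0 * sum(1 for x in d if abs(x) > 10.0) / len(d)
    prr50 = 100.0 * sum(1 for x in d if abs(x) > 50.0) / len(d)
    ratio = (max(rr) - min(rr)) / mean_rr
    return (sdsd, ratio, rmssd, sdrr, prr10, prr50, mean_rr)


def test_constant_series_all_zero_dispersion():
    out = statistical_features(np.array([800.0] * 4))
    assert out.MeanRR == 800.0
    assert out.SDRR == out.SDSD == out.rMSSD == 0.0
    assert out.pRR10 == out.pRR50 == out.Ratio == 0.0


def test_two_interval_hand_example():
    out = statistical_features(np.array([700.0, 760.0]))
    assert out.rMSSD == pytest.approx(60.0)
    assert out.pRR10 == 100.0 and out.pRR50 == 100.0
    assert out.MeanRR == pytest.approx(730.0)
    assert out.Ratio == pytest.approx(60.0 / 730.0)
    assert out.SDSD == 0.0


def test_four_interval_hand_example():
    # brute-force oracle values for [800, 812, 795, 860] ms
    out = statistical_features(np.array([800.0, 812.0, 795.0, 860.0]))
    assert out.pRR10 == pytest.approx(100.0)
    assert out.pRR50 == pytest.approx(100.0 / 3.0)
    assert out.MeanRR == pytest.approx(816.75)
    assert out.Ratio == pytest.approx(65.0 / 816.75)
    assert out.rMSSD == pytest.approx(39.40389, abs=1e-4)
    assert out.SDSD == pytest.approx(33.95094, abs=1e-4)
    assert out.SDRR == pytest.approx(25.72331, abs=1e-4)


def test_matches_naive_oracle_on_random_series(rng):
    for _ in range(200):
        n = int(rng.integers(2, 40))
        rr = rng.uniform(300.0, 1500.0, size=n)
        got = statistical_features(rr)
        expected = naive_statistics(list(rr))
        for g, e in zip(got, expected):
            assert g == pytest.approx(e, rel=1e-9)


def test_too_few_intervals_rejected():
    with pytest.raises(ValueError):
        statistical_features(np.array([800.0]))


rr_series = st.lists(
    st.floats(min_value=200.0, max_value=2000.0,
              allow_nan=False, allow_infinity=False),
    min_size=2, max_size=40)


@settings(max_examples=200, derandomize=True)
@given(rr_series)
def test_prr_nesting_and_rmssd_identity(rr):
    out = statistical_features(np.array(rr))
    assert out.pRR10 >= out.pRR50
    assert out.rMSSD >= out.SDSD - 1e-12
    d = np.diff(rr)
    assert out.rMSSD ** 2 == pytest.approx(
        out.SDSD ** 2 + np.mean(d) ** 2, rel=1e-9, abs=1e-9)
    assert out.Ratio >= 0.0
    if out.Ratio == 0.0:
        assert max(rr) == min(rr)


def test_morphology_unit_conversion_and_amplitudes():
    fid = BeatFiducials(r_index=100, q_index=64, s_index=136,
                        r_amp=1.0, q_amp=-0.1, s_amp=-0.2)
    out = morphological_features([fid], fs=360.0)
    assert out.qrs_width == pytest.approx((136 - 64) * 1000.0 / 360.0)
    assert out.qr_amplitude == pytest.approx(1.1)
    assert out.rs_amplitude == pytest.approx(1.2)


def test_morphology_is_mean_over_beats():
    f1 = BeatFiducials(100, 90, 110, 1.0, -0.1, -0.2)
    f2 = BeatFiducials(300, 280, 320, 0.8, -0.2, -0.1)
    out = morphological_features([f1, f2, None], fs=1000.0)
    assert out.qrs_width == pytest.approx((20 + 40) / 2.0)
    assert out.qr_amplitude == pytest.approx((1.1 + 1.0) / 2.0)


def test_morphology_requires_a_valid_fiducial():
    with pytest.raises(ValueError):
        morphological_features([None, None], fs=360.0)


def _beats(n_pvc, n_total, spacing=300):
    symbols = ["V"] * n_pvc + ["N"] * (n_total - n_pvc)
    return [BeatAnnotation.from_symbol(i * spacing, s)
            for i, s in enumerate(symbols)]


@pytest.mark.parametrize("n_pvc,expected", [
    (20, "PVC"),       # 100 %
    (19, "PVC"),       # exactly 95 %
    (18, "non-PVC"),   # 90 %
    (0, "non-PVC"),
])
def test_95_percent_labeling_rule(n_pvc, expected):
    assert label_window(_beats(n_pvc, 20)) == expected


def test_label_invariant_under_beat_permutation(rng):
    beats = _beats(7, 20)
    base = label_window(beats)
    for _ in range(10):
        perm = [beats[i] for i in rng.permutation(len(beats))]
        assert label_window(perm) == base


def test_label_empty_window_raises():
    with pytest.raises(ValueError):
        label_window([])


def test_segmentation_counts_and_partial_window(clean_mixed_record):
    rec = clean_mixed_record
    windows = segment_windows(rec)
    span = int(20.0 * rec.fs)
    assert all(w.stop - w.start == span for w in windows)
    assert all(w.stop <= rec.n_samples for w in windows)
    total_beats = sum(len(w.beats) for w in windows)
    assert total_beats <= len(rec.annotations)
    # beats fall in the window holding their R index
    for w in windows:
        assert all(w.start <= b.sample_index < w.stop for b in w.beats)


def test_record_shorter_than_window_gives_no_windows():
    rec = generate_record(SynthConfig(n_beats=5, seed=3))
    assert rec.duration_s < 20.0
    assert segment_windows(rec) == []


def test_window_count_at_800ms_rr():
    cfg = SynthConfig(n_beats=400, pvc_fraction=0.0, rr_jitter_sd=10.0,
                      seed=6)
    rec = generate_record(cfg)
    windows = segment_windows(rec)
    # 20 s / 0.8 s -> about 25 beats per window
    for w in windows:
        assert 20 <= len(w.beats) <= 30


def test_normalization_bounds_and_midpoint():
    train = pd.DataFrame(
        {name: [2.0, 4.0, 10.0] for name in FEATURE_ORDER})
    params = fit_normalization(train)
    assert np.all(params.fmin == 2.0) and np.all(params.fmax == 10.0)
    grid = pd.DataFrame({name: [2.0, 10.0, 6.0] for name in FEATURE_ORDER})
    out = apply_normalization(grid, params)
    assert np.allclose(out[0], 0.0)
    assert np.allclose(out[1], 1.0)
    assert np.allclose(out[2], 0.5)


def test_normalized_train_in_unit_interval_test_clipped(rng):
    train = pd.DataFrame(
        rng.normal(size=(50, len(FEATURE_ORDER))), columns=FEATURE_ORDER)
    test = pd.DataFrame(
        10.0 * rng.normal(size=(50, len(FEATURE_ORDER))),
        columns=FEATURE_ORDER)
    params = fit_normalization(train)
    xt = apply_normalization(train, params)
    xs = apply_normalization(test, params)
    assert xt.min() >= 0.0 and xt.max() <= 1.0
    assert xs.min() >= 0.0 and xs.max() <= 1.0


def test_degenerate_feature_maps_to_zero():
    train = pd.DataFrame({name: [5.0, 5.0] for name in FEATURE_ORDER})
    params = fit_normalization(train)
    assert params.degenerate.all()
    out = apply_normalization(train, params)
    assert np.all(out == 0.0)


def test_refit_is_deterministic(rng):
    train = pd.DataFrame(
        rng.normal(size=(30, len(FEATURE_ORDER))), columns=FEATURE_ORDER)
    a, b = fit_normalization(train), fit_normalization(train)
    assert np.array_equal(a.fmin, b.fmin)
    assert np.array_equal(a.fmax, b.fmax)


def test_extract_features_table_layout(clean_mixed_record):
    df = extract_features(clean_mixed_record)
    assert list(df.columns[2:12]) == list(FEATURE_ORDER)
    assert set(df["label"]) <= {"PVC", "non-PVC"}
    assert ((df["pvc_beat_fraction"] >= 0.95)
            == (df["label"] == "PVC")).all()
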