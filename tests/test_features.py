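"""Per-beat feature extraction: Teichholz volumes, EF/FS, extrema, filtering."""

import numpy as np
import pytest

from mmecho.features import (
    MIN_PROMINENCE_MM,
    ExtremumEvent,
    TraceCurve,
    compute_ef_fs,
    detect_extrema,
    mask_to_lvid_curve,
    pair_and_filter,
    summarize_mouse,
    teichholz_volume,
)
from mmecho.io import SegMask
from mmecho.quality import QualityInterval


def brute_force_volume(d: float) -> float:
    """Direct evaluation of V = 7/(2.4+D) * D^3 (independent oracle)."""
    return 7.0 / (2.4 + d) * d * d * d


class TestTeichholz:
    @pytest.mark.parametrize(
        ("lvid", "expected"),
        [
            (0.0, 0.0),
            (1.0, 7.0 / 3.4),  # 2.0588235...
            (4.0, 70.0),  # 7/6.4 * 64
        ],
    )
    def test_reference_values(self, lvid, expected):
        assert teichholz_volume(lvid) == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_on_grid(self):
        for d in np.linspace(0.0, 8.0, 101):
            assert teichholz_volume(d) == pytest.approx(brute_force_volume(d), abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            teichholz_volume(-0.1)


class TestEfFs:
    def test_identity_pair_gives_zero(self):
        ef, fs = compute_ef_fs(3.0, 3.0)
        assert ef == 0.0 and fs == 0.0

    def test_reference_pair_paper_variant(self):
        ef, fs = compute_ef_fs(4.0, 2.0, "paper")
        vd, vs = 70.0, brute_force_volume(2.0)  # 12.7272...
        assert ef == pytest.approx((vd - vs) / vd * 100.0, abs=1e-9)
        assert ef == pytest.approx(81.8182, abs=1e-4)
        assert fs == pytest.approx(100.0, abs=1e-9)  # (4-2)/2

    def test_reference_pair_conventional_variant(self):
        _, fs = compute_ef_fs(4.0, 2.0, "conventional")
        assert fs == pytest.approx(50.0, abs=1e-9)  # (4-2)/4

    def test_invalid_pairs_rejected(self):
        with pytest.raises(ValueError):
            compute_ef_fs(2.0, 4.0)
        with pytest.raises(ValueError):
            compute_ef_fs(4.0, 0.0)
        with pytest.raises(ValueError):
            compute_ef_fs(4.0, 2.0, "bogus")

    def test_monotone_in_both_arguments(self):
        # EF and FS increase with LVIDd at fixed LVIDs and decrease in LVIDs
        ds = np.linspace(2.5, 6.0, 12)
        for s in (1.5, 2.0):
            efs = [compute_ef_fs(d, s) for d in ds]
            assert all(np.diff([e for e, _ in efs]) > 0)
            assert all(np.diff([f for _, f in efs]) > 0)
        ss = np.linspace(1.0, 3.4, 12)
        for d in (3.5, 4.5):
            efs = [compute_ef_fs(d, s) for s in ss]
            assert all(np.diff([e for e, _ in efs]) < 0)
            assert all(np.diff([f for _, f in efs]) < 0)


class TestMaskToCurve:
    def _mask(self, cols):
        h = max(len(c) for c in cols)
        arr = np.zeros((h, len(cols)), dtype=np.uint8)
        for j, col in enumerate(cols):
            arr[: len(col), j] = col
        return SegMask(arr)

    def test_single_run_length(self):
        col = [0] * 10 + [1] * 30 + [0] * 10
        curve = mask_to_lvid_curve(self._mask([col]), y_res_mm=0.01, x_res_ms=1.0)
        assert curve.lvid_mm[0] == pytest.approx(0.30)

    def test_empty_column_is_undefined(self):
        curve = mask_to_lvid_curve(self._mask([[0] * 20]), 0.01, 1.0)
        assert np.isnan(curve.lvid_mm[0])

    def test_longest_of_two_runs_wins(self):
        col = [1] * 20 + [0] * 5 + [1] * 35
        curve = mask_to_lvid_curve(self._mask([col]), 0.01, 1.0)
        assert curve.lvid_mm[0] == pytest.approx(0.35)

    def test_matches_brute_force_run_enumeration(self, rng):
        mask = (rng.random((40, 25)) > 0.6).astype(np.uint8)
        curve = mask_to_lvid_curve(SegMask(mask), 0.01, 1.0)
        for j in range(25):
            runs, n = [], 0
            for v in mask[:, j]:
                n = n + 1 if v else 0
                runs.append(n)
            longest = max(runs)
            if longest == 0:
                assert np.isnan(curve.lvid_mm[j])
            else:
                assert curve.lvid_mm[j] == pytest.approx(longest * 0.01)


class TestDetectExtrema:
    def test_constant_curve_has_no_events(self):
        curve = TraceCurve(np.arange(100.0), np.full(100, 3.0))
        assert detect_extrema(curve) == []

    def test_sinusoid_closed_form(self):
        # LVID(t) = 3 + sin(2*pi*10 Hz*t) mm over 1 s at 1 ms sampling
        t = np.arange(1000.0)
        lvid = 3.0 + np.sin(2 * np.pi * 10.0 * t / 1000.0)
        ev = detect_extrema(TraceCurve(t, lvid))
        maxima = [e for e in ev if e.kind == "max"]
        minima = [e for e in ev if e.kind == "min"]
        assert len(maxima) == 10 and len(minima) == 10
        assert np.allclose([e.lvid_mm for e in maxima], 4.0, atol=1e-3)
        assert np.allclose([e.lvid_mm for e in minima], 2.0, atol=1e-3)
        # peak times: 25 + 100k for maxima, 75 + 100k for minima, +/- 1 sample
        for k, e in enumerate(sorted(maxima, key=lambda e: e.t_ms)):
            assert abs(e.t_ms - (25.0 + 100.0 * k)) <= 1.0
        for k, e in enumerate(sorted(minima, key=lambda e: e.t_ms)):
            assert abs(e.t_ms - (75.0 + 100.0 * k)) <= 1.0

    def test_generator_trace_events_recovered(self, clean_record):
        _, _, trace = clean_record
        curve = TraceCurve(trace.time_ms, trace.lvid_mm)
        ev = detect_extrema(curve)
        pairs = [
            (a, b)
            for a, b in zip(ev, ev[1:])
            if a.kind == "max" and b.kind == "min"
        ]
        assert len(pairs) == len(trace.beat_events)
        for (mx, mn), (td, d, ts, s) in zip(pairs, trace.beat_events):
            assert abs(mx.t_ms - td) <= 0.833
            assert abs(mn.t_ms - ts) <= 0.833
            assert abs(mx.lvid_mm - d) < 0.01
            assert abs(mn.lvid_mm - s) < 0.01

    def test_prominence_filters_micro_wiggles(self):
        t = np.arange(500.0)
        lvid = 3.0 + 0.02 * np.sin(2 * np.pi * t / 50.0)  # below 0.1 mm prominence
        assert detect_extrema(TraceCurve(t, lvid)) == []
        lvid = 3.0 + 2 * MIN_PROMINENCE_MM * np.sin(2 * np.pi * t / 100.0)
        assert len(detect_extrema(TraceCurve(t, lvid))) > 0

    def test_all_undefined_curve(self):
        curve = TraceCurve(np.arange(50.0), np.full(50, np.nan))
        assert detect_extrema(curve) == []


def _ev(t, v, kind):
    return ExtremumEvent(t_ms=t, lvid_mm=v, kind=kind)


class TestPairAndFilter:
    def test_simple_pair_retained(self):
        ivs = [QualityInterval(0, 1000, "high", 0.9)]
        events = [_ev(100, 4.0, "max"), _ev(140, 2.0, "min")]
        beats = pair_and_filter(events, ivs)
        assert len(beats) == 1
        b = beats[0]
        assert (b.lvid_d_mm, b.lvid_s_mm, b.t_d_ms, b.t_s_ms) == (4.0, 2.0, 100, 140)
        assert b.ef_pct == pytest.approx(81.8182, abs=1e-4)

    def test_toy_set_exhaustive_rules(self):
        # 5 candidate pairs: 2 with an endpoint in a low interval, 1 inverted
        ivs = [
            QualityInterval(0, 200, "high", 0.9),
            QualityInterval(200, 400, "low", 0.1),
            QualityInterval(400, 1000, "high", 0.9),
        ]
        events = [
            _ev(50, 4.0, "max"), _ev(80, 2.0, "min"),     # both high -> keep
            _ev(150, 4.0, "max"), _ev(230, 2.0, "min"),   # min in low -> drop
            _ev(250, 4.1, "max"), _ev(300, 2.1, "min"),   # both low -> drop
            _ev(450, 2.0, "max"), _ev(500, 3.0, "min"),   # inverted -> drop
            _ev(600, 4.2, "max"), _ev(640, 2.2, "min"),   # both high -> keep
        ]
        beats = pair_and_filter(events, ivs)
        assert [(b.t_d_ms, b.t_s_ms) for b in beats] == [(50, 80), (600, 640)]

    def test_straddling_pair_dropped(self):
        ivs = [
            QualityInterval(0, 120, "high", 0.9),
            QualityInterval(120, 1000, "low", 0.1),
        ]
        events = [_ev(100, 4.0, "max"), _ev(140, 2.0, "min")]
        assert pair_and_filter(events, ivs) == []

    def test_leading_min_discarded(self):
        ivs = [QualityInterval(0, 1000, "high", 0.9)]
        events = [_ev(20, 2.0, "min"), _ev(100, 4.0, "max"), _ev(140, 2.2, "min")]
        beats = pair_and_filter(events, ivs)
        assert len(beats) == 1 and beats[0].t_d_ms == 100

    def test_every_retained_beat_satisfies_invariants(self, rng):
        # random event/interval soup: retained pairs always obey the gates
        for _ in range(20):
            events = []
            t = 0.0
            for _ in range(30):
                t += rng.uniform(20, 80)
                events.append(
                    _ev(t, rng.uniform(1.5, 4.5), "max" if rng.random() < 0.5 else "min")
                )
            edges = np.sort(rng.uniform(0, t + 50, size=4))
            labels = ["high", "low"] * 3
            bounds = [0.0, *edges, t + 100]
            ivs = [
                QualityInterval(a, b, labels[i], 0.5)
                for i, (a, b) in enumerate(zip(bounds, bounds[1:]))
                if b > a
            ]
            high = [iv for iv in ivs if iv.label == "high"]
            for b in pair_and_filter(events, ivs):
                assert b.lvid_d_mm > b.lvid_s_mm
                for tt in (b.t_d_ms, b.t_s_ms):
                    assert any(iv.start_ms <= tt < iv.end_ms for iv in high)


class TestSummarize:
    def test_single_beat_means_equal_beat(self):
        ivs = [QualityInterval(0, 1000, "high", 0.9)]
        beats = pair_and_filter([_ev(10, 4.0, "max"), _ev(50, 2.0, "min")], ivs)
        s = summarize_mouse(beats, "m1", "F", "control")
        assert s.n_beats == 1 and s.lvid_d_mm == 4.0 and s.lvid_s_mm == 2.0
        assert not s.excluded

    def test_mean_over_beats_matches_brute_force(self):
        ivs = [QualityInterval(0, 10000, "high", 0.9)]
        events = []
        rng = np.random.default_rng(5)
        ds = [3.8, 4.0, 4.2]
        for i, d in enumerate(ds):
            events += [_ev(1000 * i + 10, d, "max"), _ev(1000 * i + 50, 2.0 + 0.1 * i, "min")]
        beats = pair_and_filter(events, ivs)
        s = summarize_mouse(beats, "m", "M", "mutant")
        assert s.lvid_d_mm == pytest.approx(np.mean(ds))
        assert s.ef_pct == pytest.approx(np.mean([b.ef_pct for b in beats]))

    def test_zero_beats_flags_exclusion(self):
        s = summarize_mouse([], "m0", "F", "control")
        assert s.excluded and s.n_beats == 0 and np.isnan(s.lvid_d_mm)
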