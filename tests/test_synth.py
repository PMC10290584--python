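"""Generator contracts: determinism, beat statistics, corruption accounting."""

import dataclasses

import numpy as np
import pytest

from mmecho.io import read_record, stitch_frames, write_record
from mmecho.synth import (
    StudyConfig,
    SynthConfig,
    generate_lvid_trace,
    generate_study,
    manual_surrogate,
    render_record,
)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(dd_mm=2.0, ds_mm=3.0)
        with pytest.raises(ValueError):
            SynthConfig(n_frames=0)
        with pytest.raises(ValueError):
            SynthConfig(corruption_rate=1.0)

    def test_default_tiling_is_exact(self, default_cfg):
        w, o = default_cfg.frame_geometry()
        f = default_cfg.n_frames
        assert w + (f - 1) * (w - o) == default_cfg.n_cols
        assert 0 <= o < w


class TestTrace:
    def test_pure_periodic_case(self):
        cfg = SynthConfig(
            total_duration_ms=1000.0, heart_rate_hz=10.0, beat_cv=0.0,
            drift_amp_mm=0.0, n_frames=1, dd_mm=4.0, ds_mm=2.0,
        )
        tr = generate_lvid_trace(cfg, seed=0)
        assert len(tr.beat_events) == 10
        d_values = [ev[1] for ev in tr.beat_events]
        s_values = [ev[3] for ev in tr.beat_events]
        assert np.ptp(d_values) == 0 and np.allclose(d_values, 4.0)
        assert np.allclose(s_values, 2.0)

    def test_seeded_determinism(self, default_cfg):
        a = generate_lvid_trace(default_cfg, seed=5)
        b = generate_lvid_trace(default_cfg, seed=5)
        assert np.array_equal(a.lvid_mm, b.lvid_mm)
        assert a.beat_events == b.beat_events

    def test_beat_event_invariants(self, default_cfg):
        tr = generate_lvid_trace(default_cfg, seed=9)
        assert (tr.lvid_mm > 0).all()
        prev_end = -np.inf
        for td, d, ts, s in tr.beat_events:
            assert d > s
            assert td < ts
            assert td > prev_end
            prev_end = ts

    def test_monte_carlo_mean_of_lvid_d(self):
        # >= 100 beats: pooled mean within 2 SE of the configured diastole
        cfg = SynthConfig(dd_mm=4.0, ds_mm=2.0, beat_cv=0.05, drift_amp_mm=0.0)
        ds = []
        for seed in range(3):
            ds += [ev[1] for ev in generate_lvid_trace(cfg, seed=seed).beat_events]
        assert len(ds) >= 100
        se = np.std(ds, ddof=1) / np.sqrt(len(ds))
        assert abs(np.mean(ds) - 4.0) < 2 * se + 1e-9


class TestRender:
    def test_no_corruption_gives_single_high_interval(self, clean_record):
        _, gt, _ = clean_record
        assert [iv.label for iv in gt.quality_intervals] == ["high"]

    def test_stitched_duration_matches_protocol(self, noisy_record):
        rec, _, _ = noisy_record
        echo = stitch_frames(rec)
        assert abs(echo.duration_ms - 4869.0) <= echo.x_res_ms

    def test_record_files_byte_identical_for_same_seed(self, tmp_path, default_cfg):
        for name in ("a", "b"):
            tr = generate_lvid_trace(default_cfg, seed=3)
            rec, _ = render_record(tr, default_cfg, seed=3)
            write_record(rec, tmp_path / f"{name}.dcm")
        assert (tmp_path / "a.dcm").read_bytes() == (tmp_path / "b.dcm").read_bytes()

    def test_quality_intervals_tile_record(self, default_cfg):
        for seed in range(5):
            tr = generate_lvid_trace(default_cfg, seed=seed)
            _, gt = render_record(tr, default_cfg, seed=seed)
            ivs = gt.quality_intervals
            assert ivs[0].start_ms == 0.0
            for a, b in zip(ivs, ivs[1:]):
                assert a.end_ms == pytest.approx(b.start_ms)
            total = default_cfg.n_cols * default_cfg.x_res_ms
            assert ivs[-1].end_ms == pytest.approx(total)
            for iv in ivs:
                if iv.label == "high":
                    assert iv.duration_ms >= default_cfg.min_region_ms - 1e-9

    def test_corrupted_fraction_converges_to_rate(self):
        cfg = SynthConfig(corruption_rate=0.3)
        fracs = []
        for seed in range(60):
            tr = generate_lvid_trace(cfg, seed=seed)
            _, gt = render_record(tr, cfg, seed=seed)
            total = sum(iv.duration_ms for iv in gt.quality_intervals)
            low = sum(iv.duration_ms for iv in gt.quality_intervals if iv.label == "low")
            fracs.append(low / total)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.3) < 3 * se

    def test_render_measure_round_trip(self, clean_echo):
        from mmecho.features import TraceCurve, detect_extrema, mask_to_lvid_curve
        from mmecho.io import traces_to_mask

        echo, gt, trace = clean_echo
        mask = traces_to_mask(trace.upper_mm, trace.lower_mm, echo)
        curve = mask_to_lvid_curve(mask, echo.y_res_mm, echo.x_res_ms)
        events = detect_extrema(curve)
        pairs = [
            (a, b) for a, b in zip(events, events[1:])
            if a.kind == "max" and b.kind == "min"
        ]
        assert len(pairs) == len(trace.beat_events)
        col = lambda t: int(t // echo.x_res_ms)  # noqa: E731
        for (mx, mn), (td, d, ts, s) in zip(pairs, trace.beat_events):
            assert abs(mx.lvid_mm - d) <= echo.y_res_mm
            assert abs(mn.lvid_mm - s) <= echo.y_res_mm
            # extremal column adjacent to the true event's column
            assert abs(col(mx.t_ms) - col(td)) <= 1
            assert abs(col(mn.t_ms) - col(ts)) <= 1

    def test_mismatched_trace_rejected(self, default_cfg):
        short = SynthConfig(total_duration_ms=1000.0, n_frames=1)
        tr = generate_lvid_trace(short, seed=0)
        with pytest.raises(ValueError):
            render_record(tr, default_cfg, seed=0)


class TestManualSurrogate:
    def test_surrogate_uses_two_clean_beats(self, noisy_record):
        _, gt, _ = noisy_record
        ms = gt.manual_surrogate
        assert ms is not None
        ds = [ev[1] for ev in gt.trace.beat_events]
        assert min(ds) - 1e-9 <= ms["lvid_d_mm"] <= max(ds) + 1e-9
        assert ms["ef_pct"] > 0

    def test_broad_bias_never_smaller(self, default_cfg):
        for seed in range(5):
            tr = generate_lvid_trace(default_cfg, seed=seed)
            _, gt = render_record(tr, default_cfg, seed=seed)
            plain = manual_surrogate(gt, broad_bias=False)
            broad = manual_surrogate(gt, broad_bias=True)
            if plain and broad:
                assert broad["lvid_d_mm"] >= plain["lvid_d_mm"] - 1e-9


class TestStudy:
    def test_manifest_lists_all_mice(self, tmp_path):
        cfg = StudyConfig(study_name="s", n_per_sex_per_genotype=2)
        bundle = generate_study(cfg, seed=1, out_dir=tmp_path / "study")
        assert len(bundle.mice) == 8  # 2 x 2 sexes x 2 genotypes
        import pandas as pd

        manifest = pd.read_csv(bundle.manifest_path)
        assert len(manifest) == 8
        assert set(manifest.sex) == {"F", "M"}
        assert set(manifest.genotype) == {"control", "mutant"}
        for f in manifest.file:
            assert (tmp_path / "study" / f).exists()

    def test_default_study_size_is_28(self):
        cfg = StudyConfig()
        n = cfg.n_per_sex_per_genotype
        assert n >= 7  # at least seven mutants per sex by default
        assert 2 * 2 * n == 28

    def test_identity_effect_leaves_distribution_alone(self):
        base = StudyConfig(n_per_sex_per_genotype=2, effect_spec={})
        bundle = generate_study(base, seed=4)
        d_ctrl = [
            np.mean([ev[1] for ev in m.ground_truth.trace.beat_events])
            for m in bundle.mice if m.genotype == "control"
        ]
        d_mut = [
            np.mean([ev[1] for ev in m.ground_truth.trace.beat_events])
            for m in bundle.mice if m.genotype == "mutant"
        ]
        spread = np.std(d_ctrl + d_mut)
        assert abs(np.mean(d_ctrl) - np.mean(d_mut)) < 4 * spread + 0.1

    def test_effect_spec_shifts_mutants(self):
        cfg = StudyConfig(
            n_per_sex_per_genotype=2, effect_spec={"ds_mm": ("mul", 1.4)}
        )
        bundle = generate_study(cfg, seed=4)
        s_ctrl = np.mean([
            np.mean([ev[3] for ev in m.ground_truth.trace.beat_events])
            for m in bundle.mice if m.genotype == "control"
        ])
        s_mut = np.mean([
            np.mean([ev[3] for ev in m.ground_truth.trace.beat_events])
            for m in bundle.mice if m.genotype == "mutant"
        ])
        assert s_mut / s_ctrl == pytest.approx(1.4, rel=0.05)

    def test_study_reload_round_trip(self, tmp_path):
        from mmecho.synth import load_ground_truth

        cfg = StudyConfig(n_per_sex_per_genotype=1)
        bundle = generate_study(cfg, seed=2, out_dir=tmp_path / "s")
        m = bundle.mice[0]
        back = read_record(m.path)
        for a, b in zip(m.record.frames, back.frames):
            assert np.array_equal(a, b)
        gt = load_ground_truth(m.path.with_suffix(".gt.json"))
        assert len(gt.trace.beat_events) == len(m.ground_truth.trace.beat_events)
        assert [iv.label for iv in gt.quality_intervals] == [
            iv.label for iv in m.ground_truth.quality_intervals
        ]
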