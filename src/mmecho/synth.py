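"""Synthetic conscious-mouse M-mode echocardiograms with full ground truth.

Generates quasi-periodic left-ventricle wall traces (beat-to-beat jitter
plus a slow physiological drift), renders them into speckled M-mode
images with optional low-quality stretches (superimposed papillary-like
bands, probe-motion dropouts), slices the image into overlapping frames
like a real multi-frame acquisition, and keeps exact ground truth for
every stage: the wall traces, per-beat diastole/systole events, the
high/low-quality time intervals, and a two-beat "manual" surrogate
annotation.

The trace model places systole/diastole nodes alternately in time and
joins them with half-cosine segments, so the sampled curve has its strict
local extrema exactly at the recorded beat events.  It is a geometric
emulation, not a physical ultrasound simulation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import features as feat
from .io import ContinuousEcho, MModeRecord, traces_to_mask, write_record
from .quality import QualityInterval


@dataclass
class SynthConfig:
    """Geometry and physiology of one synthetic acquisition.

    Defaults follow the real acquisition protocol (49 frames, 4.869 s at
    0.833 ms per column) and plausible conscious-mouse physiology
    (~11 Hz heart rate, LVIDd ~3.8 mm, LVIDs ~2.4 mm).
    """

    n_frames: int = 49
    total_duration_ms: float = 4869.0
    x_res_ms: float = 0.833
    overlap_frac: float = 0.2  # target; exact tiling picks the nearest feasible
    frame_overlap_ms: float | None = None  # overrides overlap_frac when set
    y_res_mm_range: tuple[float, float] = (0.015, 0.02)
    depth_mm: float = 6.0
    heart_rate_hz: float = 11.0
    dd_mm: float = 3.8
    ds_mm: float = 2.4
    beat_cv: float = 0.04
    drift_amp_mm: float = 0.15
    drift_period_ms: float = 1500.0
    noise_level: float = 0.15
    corruption_rate: float = 0.25
    min_region_ms: float = 300.0
    wall_thickness_mm: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.dd_mm > self.ds_mm > 0):
            raise ValueError("need dd_mm > ds_mm > 0")
        if self.n_frames < 1:
            raise ValueError("need n_frames >= 1")
        if self.x_res_ms <= 0:
            raise ValueError("need x_res_ms > 0")
        if not (0 <= self.corruption_rate < 1):
            raise ValueError("need 0 <= corruption_rate < 1")

    @property
    def n_cols(self) -> int:
        return int(round(self.total_duration_ms / self.x_res_ms))

    def frame_geometry(self) -> tuple[int, int]:
        """Exact integer (frame_width, overlap) columns tiling the record.

        With F equal-width frames the widths must satisfy
        ``w + (F-1)(w-o) = n_cols``; among the feasible integer pairs the
        one whose overlap fraction o/w is closest to ``overlap_frac`` is
        chosen (or o is fixed from ``frame_overlap_ms`` and w solved,
        possibly nudging the column count by < one frame).
        """
        f, n = self.n_frames, self.n_cols
        if f == 1:
            return n, 0
        if self.frame_overlap_ms is not None:
            o = int(round(self.frame_overlap_ms / self.x_res_ms))
            w = int(np.ceil((n + (f - 1) * o) / f))
            if o >= w:
                raise ValueError("frame overlap >= frame width")
            return w, o
        best = None
        for step in range(1, n // (f - 1) + 1):
            w = n - (f - 1) * step
            o = w - step
            if o < 0 or w <= 0:
                continue
            score = abs(o / w - self.overlap_frac)
            if best is None or score < best[0]:
                best = (score, w, o)
        if best is None:
            raise ValueError("no feasible frame tiling")
        return best[1], best[2]


@dataclass
class HeartTrace:
    """Sampled LV wall positions plus the exact per-beat events."""

    time_ms: np.ndarray
    upper_mm: np.ndarray
    lower_mm: np.ndarray
    beat_events: list[tuple[float, float, float, float]]
    # each event: (t_diastole_ms, lvid_d_mm, t_systole_ms, lvid_s_mm)

    @property
    def lvid_mm(self) -> np.ndarray:
        return self.lower_mm - self.upper_mm


@dataclass
class GroundTruth:
    trace: HeartTrace
    quality_intervals: list[QualityInterval]
    manual_surrogate: dict | None = None
    y_res_mm: float = float("nan")


@dataclass
class StudyConfig:
    study_name: str = "synthetic-study"
    n_per_sex_per_genotype: int = 7
    base: SynthConfig = field(default_factory=SynthConfig)
    #: per-parameter shifts applied to mutants, e.g. {"ds_mm": ("mul", 1.35)}
    effect_spec: dict = field(default_factory=dict)


@dataclass
class StudyMouse:
    mouse_id: str
    sex: str
    genotype: str
    record: MModeRecord
    ground_truth: GroundTruth
    path: Path | None = None


@dataclass
class StudyBundle:
    study_name: str
    mice: list[StudyMouse]
    out_dir: Path | None = None
    manifest_path: Path | None = None


# ---------------------------------------------------------------------------
# Trace generation


def generate_lvid_trace(cfg: SynthConfig, seed: int | None = None) -> HeartTrace:
    """Generate a quasi-periodic LVID(t) with exact beat-event bookkeeping.

    Systole and diastole node times alternate with half-period spacing
    jittered by ``beat_cv``; node amplitudes get the same relative jitter
    plus the slow sinusoidal drift; half-cosine interpolation keeps each
    node a strict local extremum of the sampled curve.  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_cols
    t = (np.arange(n) + 0.5) * cfg.x_res_ms
    total = n * cfg.x_res_ms
    period = 1000.0 / cfg.heart_rate_hz
    half = period / 2.0

    # alternating node times: d0, s0, d1, s1, ... first diastole ~0.35 period in
    node_t: list[float] = []
    node_kind: list[str] = []
    tt = 0.35 * period
    kind = "d"
    while tt < total - 0.5 * cfg.x_res_ms:
        node_t.append(tt)
        node_kind.append(kind)
        gap = half * (1.0 + cfg.beat_cv * rng.standard_normal())
        tt += max(gap, 0.2 * half)
        kind = "s" if kind == "d" else "d"

    drift_phase = rng.uniform(0, 2 * np.pi)

    def drift(x: float) -> float:
        if cfg.drift_amp_mm == 0:
            return 0.0
        return cfg.drift_amp_mm * float(
            np.sin(2 * np.pi * np.asarray(x) / cfg.drift_period_ms + drift_phase)
        )

    node_v: list[float] = []
    for tt, k in zip(node_t, node_kind):
        if k == "d":
            v = cfg.dd_mm * (1.0 + cfg.beat_cv * rng.standard_normal())
        else:
            v = cfg.ds_mm * (1.0 + cfg.beat_cv * rng.standard_normal())
        v += drift(tt)
        node_v.append(v)
    # enforce d > s > 0 between neighbours
    for i in range(len(node_v)):
        if node_kind[i] == "s":
            cap = min(
                node_v[j] for j in (i - 1, i + 1) if 0 <= j < len(node_v)
            ) if len(node_v) > 1 else cfg.dd_mm
            node_v[i] = float(np.clip(node_v[i], 0.2, cap - 0.2))

    # virtual anchor nodes beyond both ends so the curve is monotone there
    vt = [node_t[0] - half] + node_t + [node_t[-1] + half]
    anchor0 = cfg.ds_mm if node_kind[0] == "d" else cfg.dd_mm
    anchor1 = cfg.ds_mm if node_kind[-1] == "d" else cfg.dd_mm
    vv = [anchor0 + drift(node_t[0] - half)] + node_v + [anchor1 + drift(node_t[-1] + half)]

    lvid = _cosine_interp(np.array(vt), np.array(vv), t)

    beat_events = []
    for i in range(len(node_t) - 1):
        if node_kind[i] == "d" and node_kind[i + 1] == "s":
            beat_events.append((node_t[i], node_v[i], node_t[i + 1], node_v[i + 1]))

    center = cfg.depth_mm / 2.0
    upper = center - 0.45 * lvid
    lower = upper + lvid
    if (lvid <= 0).any():
        raise ValueError("generated LVID not strictly positive; check config")
    return HeartTrace(time_ms=t, upper_mm=upper, lower_mm=lower, beat_events=beat_events)


def _cosine_interp(xk: np.ndarray, yk: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Piecewise half-cosine interpolation through nodes (C1, extrema at nodes)."""
    idx = np.clip(np.searchsorted(xk, x, side="right") - 1, 0, xk.size - 2)
    x0, x1 = xk[idx], xk[idx + 1]
    y0, y1 = yk[idx], yk[idx + 1]
    u = (x - x0) / (x1 - x0)
    return y0 + (y1 - y0) * (1.0 - np.cos(np.pi * u)) / 2.0


# ---------------------------------------------------------------------------
# Corruption interval sampling


def _draw_corruption_intervals(
    cfg: SynthConfig, rng: np.random.Generator, total_ms: float
) -> list[tuple[float, float]]:
    """Low-quality spans with unbiased expected total = corruption_rate*T.

    Interval lengths are uniform on [min_region, 3*min_region]; the count
    is the fractional-rounding of target/mean so the expected corrupted
    fraction equals ``corruption_rate``; placement is uniform via
    stick-breaking, rejecting layouts that leave a high-quality gap
    shorter than ``min_region_ms``.
    """
    if cfg.corruption_rate <= 0:
        return []
    lo, hi = cfg.min_region_ms, 3.0 * cfg.min_region_ms
    mean_len = (lo + hi) / 2.0
    target = cfg.corruption_rate * total_ms
    k_frac = target / mean_len
    k = int(np.floor(k_frac)) + int(rng.random() < (k_frac - np.floor(k_frac)))
    if k == 0:
        return []
    for _ in range(200):
        lengths = rng.uniform(lo, hi, size=k)
        free = total_ms - lengths.sum()
        if free < 0:
            continue
        cuts = np.sort(rng.uniform(0, free, size=k))
        gaps = np.diff(np.concatenate(([0.0], cuts, [free])))
        if (gaps < cfg.min_region_ms).any():
            continue
        starts = np.cumsum(gaps[:-1]) + np.concatenate(([0.0], np.cumsum(lengths[:-1])))
        return [(float(s), float(s + ln)) for s, ln in zip(starts, lengths)]
    return []  # pathological config: give up, record stays clean


def _tile_quality(
    corrupt: list[tuple[float, float]], total_ms: float
) -> list[QualityInterval]:
    """High/low intervals tiling [0, total) from the corrupted spans."""
    ivs: list[QualityInterval] = []
    cursor = 0.0
    for s, e in sorted(corrupt):
        if s > cursor:
            ivs.append(QualityInterval(cursor, s, "high", 1.0))
        ivs.append(QualityInterval(s, e, "low", 0.0))
        cursor = e
    if cursor < total_ms:
        ivs.append(QualityInterval(cursor, total_ms, "high", 1.0))
    return ivs


# ---------------------------------------------------------------------------
# Rendering


def render_record(
    trace: HeartTrace, cfg: SynthConfig, seed: int | None = None
) -> tuple[MModeRecord, GroundTruth]:
    """Render a trace into a sliced, speckled multi-frame record.

    Paints bright wall bands, a dark cavity and mid-grey surrounding
    tissue, applies multiplicative speckle, injects the drawn corruption
    intervals (bright papillary-like band inside the cavity, or a
    probe-motion dropout), quantises to the 8-bit grid and slices the
    continuous image into overlapping equal-width frames whose geometry is
    stored in the record metadata.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1_000_003)
    y_res = float(rng.uniform(*cfg.y_res_mm_range))
    w, o = cfg.frame_geometry()
    f = cfg.n_frames
    n_cols = w + (f - 1) * (w - o)
    if n_cols != trace.time_ms.size:
        raise ValueError("trace duration does not match the configured record")
    rows = int(round(cfg.depth_mm / y_res))
    total_ms = n_cols * cfg.x_res_ms

    depth = (np.arange(rows) + 0.5)[:, None] * y_res  # mm
    upper = trace.upper_mm[None, :]
    lower = trace.lower_mm[None, :]
    wt = cfg.wall_thickness_mm

    img = np.full((rows, n_cols), 0.35, dtype=np.float32)  # tissue
    cavity = (depth >= upper) & (depth < lower)
    img[cavity] = 0.08
    upper_wall = (depth >= upper - wt) & (depth < upper)
    lower_wall = (depth >= lower) & (depth < lower + wt)
    img[upper_wall | lower_wall] = 0.85

    corrupt = _draw_corruption_intervals(cfg, rng, total_ms)
    col_t = (np.arange(n_cols) + 0.5) * cfg.x_res_ms
    for s, e in corrupt:
        cols = (col_t >= s) & (col_t < e)
        if rng.random() < 0.5:
            # papillary-muscle-like echogenic band across the cavity
            band_c = rng.uniform(0.35, 0.65)
            band_depth = upper + band_c * (lower - upper)
            wobble = 0.15 * np.sin(2 * np.pi * col_t / rng.uniform(200, 600))
            band = np.abs(depth - (band_depth + wobble)) < 0.25
            img[:, cols] = np.where(band[:, cols], 0.7, img[:, cols])
        else:
            # probe-motion dropout: contrast collapses into haze
            img[:, cols] = 0.18 + 0.1 * img[:, cols]

    if cfg.noise_level > 0:
        speckle = 1.0 + cfg.noise_level * rng.standard_normal(img.shape, dtype=np.float32)
        img = img * np.clip(speckle, 0.0, None)
    img = np.clip(img, 0.0, 1.0)
    img = np.rint(img * 255.0).astype(np.float32) / 255.0  # 8-bit grid

    frames = [img[:, i * (w - o) : i * (w - o) + w].copy() for i in range(f)]
    acq_id = f"synth-{(cfg.seed if seed is None else seed)}"
    rec = MModeRecord(
        frames=frames,
        x_res_ms=cfg.x_res_ms,
        y_res_mm=y_res,
        acquisition_id=acq_id,
        overlap_ms=o * cfg.x_res_ms,
    )
    quality = _tile_quality(corrupt, total_ms)
    gt = GroundTruth(trace=trace, quality_intervals=quality, y_res_mm=y_res)
    gt.manual_surrogate = manual_surrogate(gt)
    return rec, gt


def manual_surrogate(gt: GroundTruth, broad_bias: bool = False) -> dict | None:
    """Two-consecutive-beat annotation a human operator would produce.

    Deterministically uses the 3rd and 4th clean beats of the longest
    high-quality region (falling back to its first two).  With
    ``broad_bias`` it instead picks the two consecutive beats with the
    largest mean LVIDd, emulating the human preference for broad regions.
    """
    highs = [iv for iv in gt.quality_intervals if iv.label == "high"]
    if not highs:
        return None
    longest = max(highs, key=lambda iv: iv.end_ms - iv.start_ms)
    clean = [
        ev
        for ev in gt.trace.beat_events
        if longest.start_ms <= ev[0] and ev[2] < longest.end_ms
    ]
    if len(clean) < 2:
        return None
    if broad_bias:
        best = max(range(len(clean) - 1), key=lambda i: clean[i][1] + clean[i + 1][1])
        chosen = clean[best : best + 2]
    else:
        chosen = clean[2:4] if len(clean) >= 4 else clean[:2]
    d = float(np.mean([ev[1] for ev in chosen]))
    s = float(np.mean([ev[3] for ev in chosen]))
    ef, fs = feat.compute_ef_fs(d, s)
    return {"lvid_d_mm": d, "lvid_s_mm": s, "ef_pct": ef, "fs_pct": fs}


# ---------------------------------------------------------------------------
# Studies


def _apply_effects(cfg: SynthConfig, effect_spec: dict) -> SynthConfig:
    changes = {}
    for name, (mode, value) in effect_spec.items():
        base = getattr(cfg, name)
        changes[name] = base * value if mode == "mul" else base + value
    return replace(cfg, **changes)


def generate_study(
    study_cfg: StudyConfig, seed: int = 0, out_dir: str | Path | None = None
) -> StudyBundle:
    """A balanced knockout study: controls vs mutants, both sexes.

    Controls are drawn from the base config; mutants get ``effect_spec``
    applied.  With ``out_dir`` set, every record is written as DICOM with
    a ground-truth JSON sidecar plus a study manifest CSV.
    """
    if study_cfg.n_per_sex_per_genotype < 1:
        raise ValueError("need at least one mouse per sex per genotype")
    ss = np.random.SeedSequence([seed, study_cfg.base.seed])
    mice: list[StudyMouse] = []
    idx = 0
    for genotype in ("control", "mutant"):
        cfg = study_cfg.base
        if genotype == "mutant":
            cfg = _apply_effects(cfg, study_cfg.effect_spec)
        for sex in ("F", "M"):
            for k in range(study_cfg.n_per_sex_per_genotype):
                child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                mouse_id = f"{study_cfg.study_name}-{genotype[0]}{sex}{k:02d}"
                mcfg = replace(cfg, seed=child)
                trace = generate_lvid_trace(mcfg)
                rec, gt = render_record(trace, mcfg)
                rec.acquisition_id = mouse_id
                mice.append(StudyMouse(mouse_id, sex, genotype, rec, gt))
                idx += 1

    bundle = StudyBundle(study_name=study_cfg.study_name, mice=mice)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for m in mice:
            p = out_dir / f"{m.mouse_id}.dcm"
            write_record(m.record, p)
            _write_ground_truth(m.ground_truth, p.with_suffix(".gt.json"))
            m.path = p
            rows.append((m.mouse_id, m.sex, m.genotype, p.name))
        manifest = out_dir / "manifest.csv"
        with open(manifest, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["mouse_id", "sex", "genotype", "file"])
            wr.writerows(rows)
        bundle.out_dir = out_dir
        bundle.manifest_path = manifest
    return bundle


def _write_ground_truth(gt: GroundTruth, path: Path) -> None:
    payload = {
        "y_res_mm": gt.y_res_mm,
        "beat_events": gt.trace.beat_events,
        "quality_intervals": [
            {"start_ms": iv.start_ms, "end_ms": iv.end_ms, "label": iv.label}
            for iv in gt.quality_intervals
        ],
        "manual_surrogate": gt.manual_surrogate,
        "upper_mm": np.round(gt.trace.upper_mm, 6).tolist(),
        "lower_mm": np.round(gt.trace.lower_mm, 6).tolist(),
        "time_ms": [float(gt.trace.time_ms[0]), float(gt.trace.time_ms[-1])],
    }
    path.write_text(json.dumps(payload))


def load_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    upper = np.asarray(d["upper_mm"])
    n = upper.size
    t0, t1 = d["time_ms"]
    trace = HeartTrace(
        time_ms=np.linspace(t0, t1, n),
        upper_mm=upper,
        lower_mm=np.asarray(d["lower_mm"]),
        beat_events=[tuple(ev) for ev in d["beat_events"]],
    )
    ivs = [
        QualityInterval(q["start_ms"], q["end_ms"], q["label"], 1.0 if q["label"] == "high" else 0.0)
        for q in d["quality_intervals"]
    ]
    return GroundTruth(
        trace=trace,
        quality_intervals=ivs,
        manual_surrogate=d.get("manual_surrogate"),
        y_res_mm=d["y_res_mm"],
    )


def record_to_echo(rec: MModeRecord) -> ContinuousEcho:
    """Convenience: stitch a record (metadata path)."""
    from .io import stitch_frames

    return stitch_frames(rec)


def oracle_mask(gt: GroundTruth, echo: ContinuousEcho):
    """Ground-truth segmentation of a rendered record."""
    return traces_to_mask(gt.trace.upper_mm, gt.trace.lower_mm, echo)
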