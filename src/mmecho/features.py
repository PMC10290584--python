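"""Per-beat functional parameters from left-ventricle masks.

The LV inner diameter (LVID) is measured column by column from the binary
mask, its local maxima/minima are end-diastole (LVIDd) and end-systole
(LVIDs), pairs are gated by acquisition quality, and ejection fraction /
fractional shortening are derived through Teichholz volumes:

    V(D) = 7 / (2.4 + D) * D^3        [mm^3, D in mm]
    EF   = (Vd - Vs) / Vd * 100       [%]
    FS   = (LVIDd - LVIDs) / LVIDs * 100   [%]   ("paper" variant)

The FS above normalises by LVIDs.  The conventional echocardiographic
definition divides by LVIDd instead; both variants are implemented
(``fs_variant`` = "paper" | "conventional") and which one was used is
logged, since the former exceeds 100 % for strong contractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .io import SegMask

log = logging.getLogger(__name__)

#: default minimum separation between same-type extrema: half a period at a
#: 16 Hz heart-rate cap
MIN_SEPARATION_MS = 31.0
#: default minimum prominence, suppresses speckle-induced micro-extrema
MIN_PROMINENCE_MM = 0.1


@dataclass
class TraceCurve:
    """LVID per column; NaN where the mask has no foreground."""

    time_ms: np.ndarray
    lvid_mm: np.ndarray

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.lvid_mm)


@dataclass
class ExtremumEvent:
    t_ms: float
    lvid_mm: float
    kind: str  # "max" (diastole) or "min" (systole)


@dataclass
class BeatMeasurement:
    """One diastole-systole pair with its derived volumes and EF/FS."""

    lvid_d_mm: float
    lvid_s_mm: float
    t_d_ms: float
    t_s_ms: float
    lv_vol_d_mm3: float
    lv_vol_s_mm3: float
    ef_pct: float
    fs_pct: float


@dataclass
class MouseSummary:
    """Per-mouse means of the four parameters over retained beats."""

    mouse_id: str
    sex: str
    genotype: str
    n_beats: int
    lvid_d_mm: float = float("nan")
    lvid_s_mm: float = float("nan")
    ef_pct: float = float("nan")
    fs_pct: float = float("nan")
    excluded: bool = False
    beat_times_ms: list = field(default_factory=list)


def mask_to_lvid_curve(mask: SegMask, y_res_mm: float, x_res_ms: float) -> TraceCurve:
    """Per-column LVID = longest contiguous foreground run * y_res.

    Columns without foreground are NaN and excluded from extrema search.
    """
    m = mask.mask.astype(bool)
    h, w = m.shape
    # longest run per column via cumulative run-length trick
    padded = np.zeros((h + 2, w), dtype=np.int32)
    padded[1:-1] = m
    runlen = np.zeros_like(padded)
    for r in range(1, h + 1):
        runlen[r] = (runlen[r - 1] + 1) * padded[r]
    longest = runlen.max(axis=0).astype(np.float64)
    lvid = longest * y_res_mm
    lvid[longest == 0] = np.nan
    time_ms = (np.arange(w) + 0.5) * x_res_ms
    return TraceCurve(time_ms=time_ms, lvid_mm=lvid)


def detect_extrema(
    curve: TraceCurve,
    min_separation_ms: float = MIN_SEPARATION_MS,
    min_prominence_mm: float = MIN_PROMINENCE_MM,
) -> list[ExtremumEvent]:
    """Local maxima (diastole) and minima (systole) of the LVID curve.

    Extrema are searched independently per contiguous defined segment with
    a minimum same-type separation and prominence; times are the centre of
    the extremal column.  Returns a time-sorted event list.
    """
    lvid = curve.lvid_mm
    t = curve.time_ms
    if t.size > 1:
        dt = float(t[1] - t[0])
    else:
        dt = 1.0
    distance = max(1, int(round(min_separation_ms / dt)))
    events: list[ExtremumEvent] = []
    defined = ~np.isnan(lvid)
    if defined.sum() < 3:
        return events
    # split into contiguous defined segments
    idx = np.flatnonzero(defined)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        seg = slice(idx[s], idx[e] + 1)
        y = lvid[seg]
        if y.size < 3:
            continue
        maxima, _ = find_peaks(y, distance=distance, prominence=min_prominence_mm)
        minima, _ = find_peaks(-y, distance=distance, prominence=min_prominence_mm)
        off = idx[s]
        for i in maxima:
            events.append(ExtremumEvent(float(t[off + i]), float(y[i]), "max"))
        for i in minima:
            events.append(ExtremumEvent(float(t[off + i]), float(y[i]), "min"))
    events.sort(key=lambda ev: ev.t_ms)
    return events


def _in_high(t_ms: float, intervals) -> bool:
    return any(iv.label == "high" and iv.start_ms <= t_ms < iv.end_ms for iv in intervals)


def pair_and_filter(
    events: list[ExtremumEvent],
    intervals,
    fs_variant: str = "paper",
) -> list[BeatMeasurement]:
    """Pair each diastole with the immediately following systole and gate.

    A pair is retained only when BOTH event times fall in high-quality
    intervals and LVIDd > LVIDs.  A leading unmatched minimum is discarded;
    consecutive maxima keep only the later one as pairing candidate.
    """
    beats: list[BeatMeasurement] = []
    i = 0
    n = len(events)
    while i < n - 1:
        ev = events[i]
        nxt = events[i + 1]
        if ev.kind != "max":
            i += 1
            continue
        if nxt.kind != "min":  # two maxima in a row: retry from the later one
            i += 1
            continue
        if (
            _in_high(ev.t_ms, intervals)
            and _in_high(nxt.t_ms, intervals)
            and ev.lvid_mm > nxt.lvid_mm
        ):
            ef, fs = compute_ef_fs(ev.lvid_mm, nxt.lvid_mm, fs_variant)
            beats.append(
                BeatMeasurement(
                    lvid_d_mm=ev.lvid_mm,
                    lvid_s_mm=nxt.lvid_mm,
                    t_d_ms=ev.t_ms,
                    t_s_ms=nxt.t_ms,
                    lv_vol_d_mm3=teichholz_volume(ev.lvid_mm),
                    lv_vol_s_mm3=teichholz_volume(nxt.lvid_mm),
                    ef_pct=ef,
                    fs_pct=fs,
                )
            )
        i += 2
    return beats


def teichholz_volume(lvid_mm: float) -> float:
    """LV volume estimate V = 7/(2.4 + D) * D^3 from one linear dimension."""
    lvid_mm = np.asarray(lvid_mm, dtype=np.float64)
    if (lvid_mm < 0).any():
        raise ValueError("LVID must be non-negative")
    v = 7.0 / (2.4 + lvid_mm) * lvid_mm**3
    return float(v) if v.ndim == 0 else v


def compute_ef_fs(
    lvid_d: float, lvid_s: float, fs_variant: str = "paper"
) -> tuple[float, float]:
    """Ejection fraction and fractional shortening of one beat, in percent.

    EF always uses Teichholz volumes.  FS normalises by LVIDs in the
    "paper" variant and by LVIDd in the "conventional" one.
    """
    if fs_variant not in ("paper", "conventional"):
        raise ValueError(f"unknown fs_variant {fs_variant!r}")
    if lvid_s <= 0 or lvid_d < lvid_s:
        raise ValueError(
            f"need LVIDd >= LVIDs > 0, got d={lvid_d}, s={lvid_s}; "
            "such pairs should have been filtered out"
        )
    vd = teichholz_volume(lvid_d)
    vs = teichholz_volume(lvid_s)
    ef = (vd - vs) / vd * 100.0
    denom = lvid_s if fs_variant == "paper" else lvid_d
    fs = (lvid_d - lvid_s) / denom * 100.0
    if fs_variant == "paper":
        log.debug(
            "FS computed with LVIDs denominator ('paper' variant); this can "
            "exceed 100%% and differs from the conventional FS definition"
        )
    return float(ef), float(fs)


def summarize_mouse(
    beats: list[BeatMeasurement], mouse_id: str, sex: str, genotype: str
) -> MouseSummary:
    """Arithmetic means of the four parameters over the retained beats.

    A mouse with zero retained beats is flagged excluded (its means stay
    NaN); downstream statistics drop such mice explicitly.
    """
    if not beats:
        return MouseSummary(mouse_id, sex, genotype, n_beats=0, excluded=True)
    return MouseSummary(
        mouse_id=mouse_id,
        sex=sex,
        genotype=genotype,
        n_beats=len(beats),
        lvid_d_mm=float(np.mean([b.lvid_d_mm for b in beats])),
        lvid_s_mm=float(np.mean([b.lvid_s_mm for b in beats])),
        ef_pct=float(np.mean([b.ef_pct for b in beats])),
        fs_pct=float(np.mean([b.fs_pct for b in beats])),
        beat_times_ms=[(b.t_d_ms, b.t_s_ms) for b in beats],
    )
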