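"""End-to-end orchestration: records in, study statistics out.

Stages run in a fixed order per record — read, stitch, quality intervals,
segmentation, LVID curve, extrema, pair/filter, per-mouse summary — and a
final study-level comparison.  Every stage's output can be persisted and
each run logs per-stage counts (windows, intervals, beats retained and
dropped) because the fraction of data discarded as low quality is itself a
headline quantity of the screening.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import quality as qual
from . import seg as segm
from . import stats as phen
from .io import read_record, stitch_frames, crop_classification_windows
from .synth import StudyBundle, StudyMouse, load_ground_truth

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (fully serialisable)."""

    manifest: str | None = None
    out_dir: str | None = None
    window_size: int = 256
    window_step: int = 128
    quality_cutoff: float = 0.5
    min_region_ms: float = 300.0
    min_separation_ms: float = feat.MIN_SEPARATION_MS
    min_prominence_mm: float = feat.MIN_PROMINENCE_MM
    fs_variant: str = "paper"
    alpha: float = 0.05
    segmentation_backend: str = "model"  # "model" | "oracle"
    quality_backend: str = "model"  # "model" | "truth"
    seed: int = 0
    study_name: str = "study"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RecordOutput:
    mouse_id: str
    beats: list
    intervals: list
    n_windows: int
    high_fraction: float
    n_events: int
    n_beats_dropped: int


@dataclass
class StudyOutputs:
    config: PipelineConfig
    beat_table: pd.DataFrame
    summaries: list
    summary_table: pd.DataFrame
    result: phen.StudyResult
    record_outputs: list
    report: str = ""


class PipelineError(RuntimeError):
    def __init__(self, record_id: str, stage: str, cause: Exception):
        super().__init__(f"record {record_id!r} failed at stage {stage!r}: {cause}")
        self.record_id = record_id
        self.stage = stage


def process_record(
    mouse: StudyMouse,
    cfg: PipelineConfig,
    quality_model=None,
    seg_model=None,
) -> tuple[feat.MouseSummary, RecordOutput]:
    """Run the per-record stages for one mouse and summarise its beats."""
    mid = mouse.mouse_id
    stage = "read"
    try:
        rec = mouse.record if mouse.record is not None else read_record(mouse.path)
        stage = "stitch"
        echo = stitch_frames(rec)
        stage = "quality"
        if cfg.quality_backend == "truth":
            intervals = mouse.ground_truth.quality_intervals
            n_windows = 0
        else:
            ws = crop_classification_windows(echo, cfg.window_size, cfg.window_step)
            scores = qual.score_windows(quality_model, ws)
            intervals = qual.scores_to_intervals(
                scores,
                ws.origins,
                n_cols=echo.n_cols,
                x_res_ms=echo.x_res_ms,
                window_w=cfg.window_size,
                cutoff=cfg.quality_cutoff,
                min_len_ms=cfg.min_region_ms,
            )
            n_windows = len(ws)
        stage = "segment"
        if cfg.segmentation_backend == "oracle":
            mask = segm.oracle_segmenter(mouse.ground_truth, echo)
        else:
            mask, _ = segm.predict_mask(
                seg_model, echo, width=cfg.window_size, step=cfg.window_step
            )
        stage = "curve"
        curve = feat.mask_to_lvid_curve(mask, echo.y_res_mm, echo.x_res_ms)
        stage = "extrema"
        events = feat.detect_extrema(
            curve, cfg.min_separation_ms, cfg.min_prominence_mm
        )
        stage = "pair_filter"
        beats = feat.pair_and_filter(events, intervals, fs_variant=cfg.fs_variant)
        stage = "summarize"
        summary = feat.summarize_mouse(beats, mid, mouse.sex, mouse.genotype)
    except Exception as exc:  # noqa: BLE001 - annotate with record and stage
        raise PipelineError(mid, stage, exc) from exc
    n_pairs_possible = sum(1 for ev in events if ev.kind == "max")
    out = RecordOutput(
        mouse_id=mid,
        beats=beats,
        intervals=intervals,
        n_windows=n_windows,
        high_fraction=qual.high_fraction(intervals),
        n_events=len(events),
        n_beats_dropped=max(0, n_pairs_possible - len(beats)),
    )
    return summary, out


def run_study(
    bundle: StudyBundle,
    cfg: PipelineConfig,
    quality_model=None,
    seg_model=None,
) -> StudyOutputs:
    """Run the full pipeline over an in-memory study bundle."""
    if not bundle.mice:
        raise ValueError("study bundle contains no mice")
    t0 = time.perf_counter()
    summaries, rec_outputs, beat_rows = [], [], []
    for mouse in bundle.mice:
        summary, out = process_record(mouse, cfg, quality_model, seg_model)
        summaries.append(summary)
        rec_outputs.append(out)
        for b in out.beats:
            beat_rows.append(
                {
                    "mouse_id": mouse.mouse_id,
                    "t_d_ms": b.t_d_ms,
                    "t_s_ms": b.t_s_ms,
                    "lvid_d_mm": b.lvid_d_mm,
                    "lvid_s_mm": b.lvid_s_mm,
                    "ef_pct": b.ef_pct,
                    "fs_pct": b.fs_pct,
                }
            )
    result = phen.compare_study(
        summaries, alpha=cfg.alpha, study_name=bundle.study_name
    )
    summary_table = summaries_to_frame(summaries)
    beat_table = pd.DataFrame(beat_rows)
    outputs = StudyOutputs(
        config=cfg,
        beat_table=beat_table,
        summaries=summaries,
        summary_table=summary_table,
        result=result,
        record_outputs=rec_outputs,
    )
    outputs.report = write_report(outputs)
    log.info(
        "study %s: %d mice, %d beats retained, %.1fs",
        bundle.study_name,
        len(summaries),
        len(beat_rows),
        time.perf_counter() - t0,
    )
    if cfg.out_dir:
        persist(outputs, Path(cfg.out_dir))
    return outputs


def run_pipeline(cfg: PipelineConfig, quality_model=None, seg_model=None) -> StudyOutputs:
    """Disk-driven entry point: load a study manifest, then run it."""
    if not cfg.manifest:
        raise ValueError("config has no manifest path")
    manifest = Path(cfg.manifest)
    if not manifest.exists():
        raise FileNotFoundError(manifest)
    table = pd.read_csv(manifest)
    if table.empty:
        raise ValueError(f"manifest {manifest} lists no mice")
    mice = []
    for row in table.itertuples():
        path = manifest.parent / row.file
        gt_path = path.with_suffix(".gt.json")
        gt = load_ground_truth(gt_path) if gt_path.exists() else None
        if gt is None and (cfg.segmentation_backend == "oracle" or cfg.quality_backend == "truth"):
            raise ValueError(f"oracle/truth backend needs ground truth for {row.mouse_id}")
        mice.append(
            StudyMouse(
                mouse_id=row.mouse_id,
                sex=row.sex,
                genotype=row.genotype,
                record=read_record(path),
                ground_truth=gt,
                path=path,
            )
        )
    bundle = StudyBundle(study_name=cfg.study_name, mice=mice)
    return run_study(bundle, cfg, quality_model, seg_model)


def summaries_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mouse_id": s.mouse_id,
                "sex": s.sex,
                "genotype": s.genotype,
                "n_beats": s.n_beats,
                "lvid_d_mm": s.lvid_d_mm,
                "lvid_s_mm": s.lvid_s_mm,
                "ef_pct": s.ef_pct,
                "fs_pct": s.fs_pct,
                "excluded": s.excluded,
            }
            for s in summaries
        ]
    )


def persist(outputs: StudyOutputs, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs.config.to_yaml(out_dir / "config.yaml")
    outputs.beat_table.to_csv(out_dir / "beats.csv", index=False)
    outputs.summary_table.to_csv(out_dir / "summaries.csv", index=False)
    (out_dir / "study_result.json").write_text(json.dumps(result_to_dict(outputs.result), indent=2))
    (out_dir / "report.txt").write_text(outputs.report)


def result_to_dict(result: phen.StudyResult) -> dict:
    return {
        "study_name": result.study_name,
        "alpha": result.alpha,
        "excluded_mice": result.excluded_mice,
        "strata": {
            f"{param}/{sex}": {
                "p_value": s.p_value,
                "n_control": s.n_control,
                "n_mutant": s.n_mutant,
                "significant": s.significant(result.alpha),
                "method": s.method,
                "testable": s.testable,
            }
            for (param, sex), s in result.strata.items()
        },
    }


def write_report(outputs: StudyOutputs, outcome: phen.OutcomeClass | None = None) -> str:
    """Human-readable run summary: tests, exclusions, QC accounting."""
    res = outputs.result
    lines = [
        f"Study: {res.study_name}",
        f"alpha = {res.alpha}, FS variant = {outputs.config.fs_variant}",
        "",
        "Rank-sum tests (parameter x sex):",
    ]
    for (param, sex), s in res.strata.items():
        if not s.testable:
            lines.append(f"  {param:7s} {sex}: untestable (nc={s.n_control}, nm={s.n_mutant})")
            continue
        star = " *" if s.significant(res.alpha) else ""
        lines.append(
            f"  {param:7s} {sex}: p = {s.p_value:.4f} "
            f"(nc={s.n_control}, nm={s.n_mutant}, {s.method}){star}"
        )
    lines.append("")
    if res.excluded_mice:
        lines.append("Excluded mice (no retained beats): " + ", ".join(res.excluded_mice))
    else:
        lines.append("Excluded mice (no retained beats): none")
    hf = [r.high_fraction for r in outputs.record_outputs]
    if hf:
        lines.append(
            f"High-quality time fraction: mean {np.mean(hf):.3f} "
            f"(min {np.min(hf):.3f}, max {np.max(hf):.3f})"
        )
    n_beats = int(outputs.summary_table["n_beats"].sum()) if len(outputs.summary_table) else 0
    dropped = sum(r.n_beats_dropped for r in outputs.record_outputs)
    lines.append(f"Beats retained: {n_beats}; candidate pairs dropped: {dropped}")
    if outcome is not None:
        lines.append("")
        lines.append("Outcome vs manual baseline:")
        for (param, sex), cat in outcome.categories.items():
            lines.append(f"  {param:7s} {sex}: {cat}")
    return "\n".join(lines) + "\n"
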