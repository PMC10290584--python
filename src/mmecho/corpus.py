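"""Training-corpus builders: windows and labels from simulated studies.

Quality windows are labelled from the ground-truth quality intervals and
only windows lying fully inside a single interval are kept (mirroring
expert region annotation, where labels are per time span, not per
window).  Segmentation windows come from high-quality regions only, with
masks rasterised from the ground-truth wall traces.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    crop_classification_windows,
    crop_segmentation_windows,
    read_record,
    stitch_frames,
    traces_to_mask,
)
from .synth import StudyBundle, load_ground_truth


def _window_label(c0: int, c1: int, x_res_ms: float, intervals) -> int | None:
    """1 = fully high, 0 = fully low, None = straddles a boundary."""
    t0, t1 = c0 * x_res_ms, c1 * x_res_ms
    for iv in intervals:
        if iv.start_ms <= t0 and t1 <= iv.end_ms:
            return 1 if iv.label == "high" else 0
    return None


def quality_corpus(
    bundle: StudyBundle, size: int = 256, step: int = 128
) -> tuple[list, np.ndarray, np.ndarray]:
    """(windows, labels, record groups) for classifier training."""
    windows, labels, groups = [], [], []
    for gi, mouse in enumerate(bundle.mice):
        echo = stitch_frames(mouse.record)
        ws = crop_classification_windows(echo, size=size, step=step)
        for crop, (_, c) in zip(ws.crops, ws.origins):
            lab = _window_label(
                c, c + size, echo.x_res_ms, mouse.ground_truth.quality_intervals
            )
            if lab is None:
                continue
            windows.append(crop)
            labels.append(lab)
            groups.append(gi)
    return windows, np.asarray(labels), np.asarray(groups)


def seg_corpus(
    bundle: StudyBundle, width: int = 64, step: int = 64
) -> tuple[list, list, np.ndarray]:
    """(windows, masks, record groups) from high-quality regions only."""
    windows, masks, groups = [], [], []
    for gi, mouse in enumerate(bundle.mice):
        echo = stitch_frames(mouse.record)
        gt = mouse.ground_truth
        full_mask = traces_to_mask(gt.trace.upper_mm, gt.trace.lower_mm, echo).mask
        ws = crop_segmentation_windows(echo, width=width, step=step)
        for crop, (_, c) in zip(ws.crops, ws.origins):
            lab = _window_label(c, c + width, echo.x_res_ms, gt.quality_intervals)
            if lab != 1:
                continue
            windows.append(crop)
            masks.append(full_mask[:, c : c + width])
            groups.append(gi)
    return windows, masks, np.asarray(groups)


def _bundle_from_dir(study_dir: str | Path) -> StudyBundle:
    from .synth import StudyMouse

    study_dir = Path(study_dir)
    table = pd.read_csv(study_dir / "manifest.csv")
    mice = []
    for row in table.itertuples():
        path = study_dir / row.file
        mice.append(
            StudyMouse(
                mouse_id=row.mouse_id,
                sex=row.sex,
                genotype=row.genotype,
                record=read_record(path),
                ground_truth=load_ground_truth(path.with_suffix(".gt.json")),
                path=path,
            )
        )
    return StudyBundle(study_name=study_dir.name, mice=mice)


def quality_corpus_from_dir(study_dir: str | Path, **kw):
    return quality_corpus(_bundle_from_dir(study_dir), **kw)


def seg_corpus_from_dir(study_dir: str | Path, **kw):
    return seg_corpus(_bundle_from_dir(study_dir), **kw)
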