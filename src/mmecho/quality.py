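"""Acquisition-quality classification and high/low interval construction.

A compact CNN scores 256x256 sliding windows as high (1) or low (0)
acquisition quality: five Convolution-ReLU-BatchNorm-MaxPooling blocks
(3x3 convolutions, 2x2 pooling) followed by a fully connected layer and a
sigmoid.  Training uses cross-entropy and Adam at 1e-4 for 15 epochs.
Window scores are then aggregated per time column, thresholded at the
0.5 cutoff, and high runs shorter than 0.3 s are relabelled low, yielding
quality intervals that tile the record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .io import WindowSet

CUTOFF = 0.5
MIN_REGION_MS = 300.0


@dataclass
class QualityModelSpec:
    n_blocks: int = 5
    conv_kernel: int = 3
    pool_kernel: int = 2
    channels: tuple[int, ...] = (4, 8, 16, 32, 32)
    input_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels) != self.n_blocks:
            raise ValueError("need one channel width per block")


@dataclass
class TrainConfig:
    epochs: int = 15
    lr: float = 1e-4
    batch_size: int = 8
    val_frac: float = 0.2
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "epochs": self.epochs,
            "loss": "cross-entropy",
            "optimizer": "Adam",
            "lr": self.lr,
            "batch_size": self.batch_size,
            "val_frac": self.val_frac,
            "seed": self.seed,
        }


@dataclass
class QualityInterval:
    """Half-open time span of one quality label with its mean score."""

    start_ms: float
    end_ms: float
    label: str  # "high" | "low"
    mean_score: float = float("nan")

    def __post_init__(self) -> None:
        if not self.end_ms > self.start_ms:
            raise ValueError("need end_ms > start_ms")
        if self.label not in ("high", "low"):
            raise ValueError(f"bad label {self.label!r}")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class ClassMetrics:
    accuracy: float
    f1: float
    fpr: float
    fnr: float
    confusion: dict = field(default_factory=dict)  # tp/fp/tn/fn


class QualityModel:
    """The five-block classifier; spec + seed fully determine the init."""

    def __init__(self, spec: QualityModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.convs: list[nn.Conv2d] = []
        self.bns: list[nn.BatchNorm2d] = []
        self.pools: list[nn.MaxPool2d] = []
        cin = 1
        for c in spec.channels:
            self.convs.append(nn.Conv2d(cin, c, spec.conv_kernel, rng=rng))
            self.bns.append(nn.BatchNorm2d(c))
            self.pools.append(nn.MaxPool2d())
            cin = c
        side = spec.input_size // spec.pool_kernel**spec.n_blocks
        self.head = nn.Linear(cin * side * side, 1, rng=rng)
        self._relu_masks: list[np.ndarray] = []

    def params(self):
        ps = []
        for conv, bn in zip(self.convs, self.bns):
            ps += conv.params() + bn.params()
        return ps + self.head.params()

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._relu_masks = []
        for conv, bn, pool in zip(self.convs, self.bns, self.pools):
            x = conv.forward(x)
            x, mask = nn.relu_forward(x)
            self._relu_masks.append(mask)
            x = bn.forward(x, train=train)
            x, _ = pool.forward(x)
        self._flat_shape = x.shape
        return self.head.forward(x.reshape(x.shape[0], -1))[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits[:, None]).reshape(self._flat_shape)
        for conv, bn, pool, mask in zip(
            reversed(self.convs), reversed(self.bns), reversed(self.pools),
            reversed(self._relu_masks),
        ):
            dy = pool.backward(dy)
            dy = bn.backward(dy)
            dy = nn.relu_backward(dy, mask)
            dy = conv.backward(dy)

    def scores(self, x: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.forward_logits(x, train=False))

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()] + [
            arr.copy() for bn in self.bns for arr in (bn.running_mean, bn.running_var)
        ]

    def load_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, state[: len(ps)]):
            p.value[...] = v
        rest = state[len(ps) :]
        for i, bn in enumerate(self.bns):
            bn.running_mean[...] = rest[2 * i]
            bn.running_var[...] = rest[2 * i + 1]


def build_quality_model(spec: QualityModelSpec | None = None) -> QualityModel:
    return QualityModel(spec or QualityModelSpec())


@dataclass
class TrainedQuality:
    model: QualityModel
    loss_history: list[float]
    val_loss_history: list[float]
    best_epoch: int
    config: dict


def _stack(windows) -> np.ndarray:
    arr = np.stack([np.asarray(w, dtype=np.float32) for w in windows])
    return arr[:, None, :, :]


def train_quality(
    model: QualityModel,
    windows,
    labels,
    tc: TrainConfig | None = None,
    groups=None,
) -> TrainedQuality:
    """Train the classifier; keeps the best-epoch checkpoint by held-out loss.

    The 80/20 train/validation split is by ``groups`` (record ids) when
    given, never by window, so overlapping windows of one record cannot
    leak across the split.
    """
    tc = tc or TrainConfig()
    labels = np.asarray(labels, dtype=np.float32)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set contains a single class; refusing to train")
    x = _stack(windows)
    rng = np.random.default_rng(tc.seed)

    if groups is None:
        groups = np.arange(len(labels))
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    perm = rng.permutation(uniq)
    n_val_groups = max(1, int(round(tc.val_frac * uniq.size)))
    val_groups = set(perm[:n_val_groups].tolist())
    val_mask = np.array([g in val_groups for g in groups])
    xt, yt = x[~val_mask], labels[~val_mask]
    xv, yv = x[val_mask], labels[val_mask]
    if len(np.unique(yt)) < 2:
        raise ValueError("train split lost a class; provide more groups")

    opt = nn.Adam(model.params(), lr=tc.lr)
    history, val_history = [], []
    best = (np.inf, None, -1)
    for epoch in range(tc.epochs):
        order = rng.permutation(len(yt))
        ep_loss, nb = 0.0, 0
        for start in range(0, len(order), tc.batch_size):
            sel = order[start : start + tc.batch_size]
            logits = model.forward_logits(xt[sel], train=True)
            loss, dz = nn.bce_with_logits(logits, yt[sel])
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            ep_loss += loss
            nb += 1
        history.append(ep_loss / max(nb, 1))
        vl = _eval_loss(model, xv, yv, tc.batch_size)
        val_history.append(vl)
        if vl < best[0]:
            best = (vl, model.state(), epoch)
    if best[1] is not None:
        model.load_state(best[1])
    return TrainedQuality(
        model=model,
        loss_history=history,
        val_loss_history=val_history,
        best_epoch=best[2],
        config=tc.as_dict(),
    )


def _eval_loss(model: QualityModel, x: np.ndarray, y: np.ndarray, bs: int) -> float:
    tot, n = 0.0, 0
    for start in range(0, len(y), bs):
        logits = model.forward_logits(x[start : start + bs], train=False)
        loss, _ = nn.bce_with_logits(logits, y[start : start + bs])
        tot += loss * len(logits)
        n += len(logits)
    return tot / max(n, 1)


def score_windows(model: QualityModel, ws: WindowSet | list, batch_size: int = 16) -> np.ndarray:
    """One score in [0, 1] per crop, order preserved."""
    crops = ws.crops if isinstance(ws, WindowSet) else ws
    if not crops:
        return np.empty(0)
    x = _stack(crops)
    if x.shape[2] != model.spec.input_size or x.shape[3] != model.spec.input_size:
        raise ValueError(
            f"window shape {x.shape[2:]} does not match model input "
            f"{model.spec.input_size}"
        )
    out = [model.scores(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
    return np.concatenate(out)


def scores_to_intervals(
    scores,
    origins,
    n_cols: int,
    x_res_ms: float,
    window_w: int = 256,
    cutoff: float = CUTOFF,
    min_len_ms: float = MIN_REGION_MS,
) -> list[QualityInterval]:
    """Window scores -> high/low intervals tiling [0, n_cols * x_res).

    Per-column score = arithmetic mean over the windows covering the
    column; columns at or above the cutoff are high (ties high); adjacent
    same-label runs merge; any high run shorter than ``min_len_ms`` is
    relabelled low.
    """
    scores = np.asarray(scores, dtype=np.float64)
    total_ms = n_cols * x_res_ms
    if scores.size == 0:
        return [QualityInterval(0.0, total_ms, "low", 0.0)]
    cols = [o[1] if isinstance(o, tuple) else int(o) for o in origins]
    if any(b < a for a, b in zip(cols, cols[1:])):
        raise ValueError("origins must be sorted by column")
    acc = np.zeros(n_cols)
    cnt = np.zeros(n_cols)
    for s, c in zip(scores, cols):
        hi = min(c + window_w, n_cols)
        acc[c:hi] += s
        cnt[c:hi] += 1
    col_score = np.divide(acc, cnt, out=np.zeros(n_cols), where=cnt > 0)
    high = (col_score >= cutoff) & (cnt > 0)

    # run-length encode, then relabel short high runs
    change = np.flatnonzero(np.diff(high.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [n_cols]))
    runs = [(bounds[i], bounds[i + 1], bool(high[bounds[i]])) for i in range(len(bounds) - 1)]
    runs = [
        (a, b, lab and (b - a) * x_res_ms >= min_len_ms)
        for a, b, lab in runs
    ]
    # merge adjacent same-label runs after relabelling
    merged: list[list] = []
    for a, b, lab in runs:
        if merged and merged[-1][2] == lab:
            merged[-1][1] = b
        else:
            merged.append([a, b, lab])
    out = []
    for a, b, lab in merged:
        out.append(
            QualityInterval(
                a * x_res_ms,
                b * x_res_ms,
                "high" if lab else "low",
                float(col_score[a:b].mean()),
            )
        )
    return out


def high_fraction(intervals: list[QualityInterval]) -> float:
    """Fraction of the record time labelled high quality."""
    total = sum(iv.duration_ms for iv in intervals)
    high = sum(iv.duration_ms for iv in intervals if iv.label == "high")
    return high / total if total else 0.0


def evaluate_classifier(pred_labels, true_labels) -> ClassMetrics:
    """Accuracy, F1, FPR and FNR from the stored confusion table.

    Positive class = high quality (label 1); fpr = FP/(FP+TN),
    fnr = FN/(FN+TP).
    """
    pred = np.asarray(pred_labels).astype(int)
    true = np.asarray(true_labels).astype(int)
    if pred.shape != true.shape:
        raise ValueError("label vectors must align")
    tp = int(((pred == 1) & (true == 1)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    n = tp + tn + fp + fn
    return ClassMetrics(
        accuracy=(tp + tn) / n if n else float("nan"),
        f1=2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan"),
        fpr=fp / (fp + tn) if (fp + tn) else float("nan"),
        fnr=fn / (fn + tp) if (fn + tp) else float("nan"),
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )
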