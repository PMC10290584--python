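"""Binary LV-interior segmentation with a dense-block encoder-decoder.

The architecture follows the QuickNAT family: four dense blocks in the
encoder and four in the decoder around a bottleneck, internal skip
connections (feature concatenation) inside every block, long skip
connections from encoder to decoder, 2x2 max-pooling with index-preserving
unpooling, and a 1x1 classifier head with a single output channel.  Inputs
of any size are accepted (zero-padded internally to a multiple of 16).

Training mirrors the quality classifier's conditions (Adam 1e-4,
cross-entropy as per-pixel binary cross-entropy) for 20 epochs.  An oracle
backend that rasterises ground-truth wall traces stands in for the network
in deterministic end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .io import ContinuousEcho, SegMask, crop_segmentation_windows, traces_to_mask


@dataclass
class SegModelSpec:
    depth: int = 4  # dense blocks in encoder and in decoder
    channels: int = 8
    growth: int = 8
    seed: int = 0


@dataclass
class SegMetrics:
    dsc: float
    mse: float


class DenseBlock:
    """Two 3x3 convolutions with internal concat skips + a 1x1 fuse.

    Every convolution is followed by ReLU then BatchNorm, matching the
    classifier's block ordering.
    """

    def __init__(self, cin: int, cout: int, growth: int, rng: np.random.Generator):
        g = growth
        self.cin, self.g = cin, g
        self.conv1 = nn.Conv2d(cin, g, 3, rng=rng)
        self.bn1 = nn.BatchNorm2d(g)
        self.conv2 = nn.Conv2d(cin + g, g, 3, rng=rng)
        self.bn2 = nn.BatchNorm2d(g)
        self.fuse = nn.Conv2d(cin + 2 * g, cout, 1, rng=rng)
        self.bn3 = nn.BatchNorm2d(cout)

    def params(self):
        return (
            self.conv1.params() + self.bn1.params()
            + self.conv2.params() + self.bn2.params()
            + self.fuse.params() + self.bn3.params()
        )

    def bns(self):
        return [self.bn1, self.bn2, self.bn3]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        a, m1 = nn.relu_forward(self.conv1.forward(x))
        a = self.bn1.forward(a, train=train)
        cat1 = np.concatenate([x, a], axis=1)
        b, m2 = nn.relu_forward(self.conv2.forward(cat1))
        b = self.bn2.forward(b, train=train)
        cat2 = np.concatenate([x, a, b], axis=1)
        out, m3 = nn.relu_forward(self.fuse.forward(cat2))
        out = self.bn3.forward(out, train=train)
        self._masks = (m1, m2, m3)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        m1, m2, m3 = self._masks
        c, g = self.cin, self.g
        dcat2 = self.fuse.backward(nn.relu_backward(self.bn3.backward(dout), m3))
        dx2, da2, db = dcat2[:, :c], dcat2[:, c : c + g], dcat2[:, c + g :]
        dcat1 = self.conv2.backward(nn.relu_backward(self.bn2.backward(db), m2))
        dx1, da1 = dcat1[:, :c], dcat1[:, c:]
        da = da1 + da2
        dx0 = self.conv1.backward(nn.relu_backward(self.bn1.backward(da), m1))
        return dx0 + dx1 + dx2


def _unpool_backward(dy: np.ndarray, idx: np.ndarray) -> np.ndarray:
    n, c, h, w = dy.shape
    flat = (
        dy.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )
    return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]


class SegModel:
    """Dense-block encoder-decoder with index-preserving unpooling."""

    def __init__(self, spec: SegModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        C, g, d = spec.channels, spec.growth, spec.depth
        self.enc = [DenseBlock(1 if i == 0 else C, C, g, rng) for i in range(d)]
        self.pools = [nn.MaxPool2d() for _ in range(d)]
        self.bottleneck = DenseBlock(C, C, g, rng)
        self.dec = [DenseBlock(2 * C, C, g, rng) for _ in range(d)]
        self.cls = nn.Conv2d(C, 1, 1, rng=rng)
        self.factor = 2**d

    def params(self):
        ps = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            ps += blk.params()
        return ps + self.cls.params()

    def _all_bns(self):
        out = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            out += blk.bns()
        return out

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        d = self.spec.depth
        h, w = x.shape[2], x.shape[3]
        ph = (-h) % self.factor
        pw = (-w) % self.factor
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        self._pad = (h, w)
        e, idxs = [], []
        cur = x
        for i in range(d):
            cur = self.enc[i].forward(cur, train)
            e.append(cur)
            cur, idx = self.pools[i].forward(cur)
            idxs.append(idx)
        cur = self.bottleneck.forward(cur, train)
        self._skip_channels = self.spec.channels
        self._enc_cache = (e, idxs)
        for i in reversed(range(d)):
            up = nn.max_unpool(cur, idxs[i], e[i].shape)
            cur = self.dec[d - 1 - i].forward(np.concatenate([up, e[i]], axis=1), train)
        logits = self.cls.forward(cur)
        return logits[:, :, :h, :w]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.spec.depth
        h, w = self._pad
        e, idxs = self._enc_cache
        full = e[0].shape
        ph, pw = (-h) % self.factor, (-w) % self.factor
        if ph or pw:
            dlogits = np.pad(dlogits, ((0, 0), (0, 0), (0, ph), (0, pw)))
        cur = self.cls.backward(dlogits)
        C = self._skip_channels
        # forward ran dec[j] at encoder level d-1-j; walk back bottom-up
        skip_grads = [None] * d
        for j in reversed(range(d)):
            lvl = d - 1 - j
            dcat = self.dec[j].backward(cur)
            dup, dskip = dcat[:, :C], dcat[:, C:]
            skip_grads[lvl] = dskip
            cur = _unpool_backward(dup, idxs[lvl])
        dcur = self.bottleneck.backward(cur)
        for i in reversed(range(d)):
            de = self.pools[i].backward(dcur) + skip_grads[i]
            dcur = self.enc[i].backward(de)

    def probabilities(self, x: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.forward_logits(x, train=False))

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()] + [
            arr.copy() for bn in self._all_bns() for arr in (bn.running_mean, bn.running_var)
        ]

    def load_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, state[: len(ps)]):
            p.value[...] = v
        rest = state[len(ps) :]
        for i, bn in enumerate(self._all_bns()):
            bn.running_mean[...] = rest[2 * i]
            bn.running_var[...] = rest[2 * i + 1]


def build_seg_model(spec: SegModelSpec | None = None) -> SegModel:
    return SegModel(spec or SegModelSpec())


@dataclass
class TrainedSeg:
    model: SegModel
    loss_history: list[float]
    val_dsc_history: list[float]
    best_epoch: int
    config: dict


def train_seg(model: SegModel, windows, masks, tc=None, groups=None) -> TrainedSeg:
    """Train on full-height window/mask pairs from high-quality regions.

    Loss is per-pixel binary cross-entropy; per-epoch held-out DSC is
    logged and the best-epoch checkpoint retained.  Windows are bucketed
    by shape so records with different depths can share a corpus.
    """
    from .quality import TrainConfig

    tc = tc or TrainConfig(epochs=20, batch_size=4)
    if len(windows) == 0 or len(masks) == 0:
        raise ValueError("empty training set; refusing to train")
    if len(windows) != len(masks):
        raise ValueError("windows and masks must align")
    rng = np.random.default_rng(tc.seed)

    if groups is None:
        groups = np.arange(len(windows))
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    perm = rng.permutation(uniq)
    n_val = max(1, int(round(tc.val_frac * uniq.size)))
    val_groups = set(perm[:n_val].tolist())
    val_mask = np.array([g in val_groups for g in groups])
    idx_train = np.flatnonzero(~val_mask)
    idx_val = np.flatnonzero(val_mask)
    if idx_train.size == 0:
        raise ValueError("no training windows left after the validation split")

    opt = nn.Adam(model.params(), lr=tc.lr)
    history, val_hist = [], []
    best = (-np.inf, None, -1)
    for epoch in range(tc.epochs):
        order = rng.permutation(idx_train)
        ep_loss, nb = 0.0, 0
        for batch in _shape_batches(order, windows, tc.batch_size):
            x = np.stack([np.asarray(windows[i], dtype=np.float32) for i in batch])[:, None]
            y = np.stack([np.asarray(masks[i], dtype=np.float32) for i in batch])[:, None]
            logits = model.forward_logits(x, train=True)
            loss, dz = nn.bce_with_logits(logits, y)
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            ep_loss += loss
            nb += 1
        history.append(ep_loss / max(nb, 1))
        dsc = _eval_dsc(model, windows, masks, idx_val, tc.batch_size)
        val_hist.append(dsc)
        if dsc > best[0]:
            best = (dsc, model.state(), epoch)
    if best[1] is not None:
        model.load_state(best[1])
    return TrainedSeg(
        model=model,
        loss_history=history,
        val_dsc_history=val_hist,
        best_epoch=best[2],
        config=tc.as_dict(),
    )


def _shape_batches(order, windows, batch_size):
    by_shape: dict[tuple, list[int]] = {}
    for i in order:
        by_shape.setdefault(np.asarray(windows[i]).shape, []).append(int(i))
    for idxs in by_shape.values():
        for s in range(0, len(idxs), batch_size):
            yield idxs[s : s + batch_size]


def _eval_dsc(model, windows, masks, idx_val, bs) -> float:
    if idx_val.size == 0:
        return float("nan")
    inter = tot = 0.0
    for batch in _shape_batches(idx_val, windows, bs):
        x = np.stack([np.asarray(windows[i], dtype=np.float32) for i in batch])[:, None]
        y = np.stack([np.asarray(masks[i], dtype=np.float32) for i in batch])[:, None]
        pred = model.probabilities(x) >= 0.5
        inter += 2.0 * (pred & (y > 0.5)).sum()
        tot += pred.sum() + (y > 0.5).sum()
    return float(inter / tot) if tot else 1.0


def keep_longest_run_per_column(mask: np.ndarray) -> np.ndarray:
    """Retain only the longest contiguous foreground run in each column.

    Detached specks (e.g. echoes of superimposed structures) are dropped
    rather than bridged; ties keep the topmost run.  Never increases the
    per-column foreground extent.
    """
    m = mask.astype(bool)
    h, w = m.shape
    run = np.zeros((h + 1, w), dtype=np.int32)
    for r in range(1, h + 1):
        run[r] = (run[r - 1] + 1) * m[r - 1]
    end = run.argmax(axis=0)  # first maximal run end (1-based, topmost on ties)
    length = run.max(axis=0)
    rows = np.arange(1, h + 1)[:, None]  # mask row i is run-space row i+1
    keep = (rows > (end - length)[None, :]) & (rows <= end[None, :])
    return (keep & m).astype(np.uint8)


def predict_mask(
    model: SegModel,
    echo: ContinuousEcho,
    width: int = 256,
    step: int = 128,
    batch_size: int = 4,
    postprocess: bool = True,
) -> tuple[SegMask, np.ndarray]:
    """Tile the record, average window probabilities, threshold at 0.5.

    Overlapping predictions are averaged per pixel (permutation-invariant
    in the window order); the binary map is then cleaned column-wise.
    Returns the mask and the averaged probability map.
    """
    ws = crop_segmentation_windows(echo, width=width, step=step)
    h, wcols = echo.image.shape
    acc = np.zeros((h, wcols), dtype=np.float64)
    cnt = np.zeros(wcols, dtype=np.float64)
    crops = [np.asarray(c, dtype=np.float32) for c in ws.crops]
    for s in range(0, len(crops), batch_size):
        batch = crops[s : s + batch_size]
        probs = model.probabilities(np.stack(batch)[:, None])[:, 0]
        for p, (_, c) in zip(probs, ws.origins[s : s + batch_size]):
            hi = min(c + width, wcols)
            acc[:, c:hi] += p[:, : hi - c]
            cnt[c:hi] += 1
    prob = acc / np.maximum(cnt, 1)[None, :]
    binary = (prob >= 0.5).astype(np.uint8)
    if postprocess:
        binary = keep_longest_run_per_column(binary)
    return SegMask(binary, y_res_mm=echo.y_res_mm, x_res_ms=echo.x_res_ms), prob


def oracle_segmenter(gt, echo: ContinuousEcho) -> SegMask:
    """Ground-truth-backed segmentation (deterministic test backend)."""
    return traces_to_mask(gt.trace.upper_mm, gt.trace.lower_mm, echo)


def evaluate_seg(pred, truth) -> SegMetrics:
    """Dice coefficient of the binarised masks and MSE of probabilities.

    ``pred`` may be a SegMask, a binary array or a probability map; DSC
    binarises at 0.5, MSE compares raw values against the binary truth.
    """
    p = pred.mask if isinstance(pred, SegMask) else np.asarray(pred, dtype=np.float64)
    t = truth.mask if isinstance(truth, SegMask) else np.asarray(truth)
    t = (np.asarray(t) > 0.5).astype(np.float64)
    if p.shape != t.shape:
        raise ValueError("mask shapes differ")
    pb = p >= 0.5
    tb = t > 0.5
    denom = pb.sum() + tb.sum()
    dsc = 2.0 * (pb & tb).sum() / denom if denom else 1.0
    mse = float(((p - t) ** 2).mean())
    return SegMetrics(dsc=float(dsc), mse=mse)
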