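"""Reading, stitching and windowing of M-mode echocardiogram records.

An acquisition is stored as a DICOM Ultrasound Multi-frame Image Storage
object whose frames cover overlapping time spans.  This module reads such
records, joins the frames into one continuous image with unique time
columns, extracts sliding-window crops for the quality classifier and the
segmenter, and converts wall traces into binary left-ventricle masks.

Conventions: time runs along columns (0-based, half-open ``[i*x_res,
(i+1)*x_res)`` ms intervals), depth along rows (row 0 shallowest).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

US_MULTIFRAME_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.3.1"
_PRIVATE_GROUP = 0x0011
_PRIVATE_CREATOR = "MMECHO"
_OVERLAP_ELEM = 0x01


class RecordReadError(RuntimeError):
    """A record file could not be parsed into an M-mode acquisition."""


@dataclass
class MModeRecord:
    """One multi-frame M-mode acquisition.

    ``frames`` are 2-D intensity grids in [0, 1] (rows = depth, columns =
    time); all frames share their shape.  ``overlap_ms`` is the inter-frame
    overlap if the writer recorded it, else None (the stitcher then falls
    back to content-based overlap estimation).
    """

    frames: list[np.ndarray]
    x_res_ms: float
    y_res_mm: float
    acquisition_id: str = ""
    overlap_ms: float | None = None

    def __post_init__(self) -> None:
        if self.x_res_ms <= 0 or self.y_res_mm <= 0:
            raise ValueError("pixel spacings must be positive")
        heights = {f.shape[0] for f in self.frames}
        if len(heights) > 1:
            raise ValueError("all frames must share their height")


@dataclass
class ContinuousEcho:
    """The stitched record: one image spanning the full acquisition."""

    image: np.ndarray
    x_res_ms: float
    y_res_mm: float
    acquisition_id: str = ""

    @property
    def n_cols(self) -> int:
        return self.image.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_cols * self.x_res_ms

    def col_time_ms(self) -> np.ndarray:
        """Centre time of every column."""
        return (np.arange(self.n_cols) + 0.5) * self.x_res_ms


@dataclass
class WindowSet:
    """Sliding-window crops plus their (row, col) origins in the source."""

    crops: list[np.ndarray]
    origins: list[tuple[int, int]]
    size: tuple[int, int]
    step: int
    padded: bool = False

    def __len__(self) -> int:
        return len(self.crops)


@dataclass
class SegMask:
    """Binary mask aligned to a ContinuousEcho; 1 = LV interior."""

    mask: np.ndarray
    y_res_mm: float = 1.0
    x_res_ms: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be 0/1")


# ---------------------------------------------------------------------------
# DICOM reading / writing


def write_record(rec: MModeRecord, path: str | Path) -> Path:
    """Write a record as an 8-bit Ultrasound Multi-frame DICOM file.

    Pixel spacings go into a SequenceOfUltrasoundRegions item
    (PhysicalDeltaX in seconds, PhysicalDeltaY in cm, per the US region
    calibration convention); the frame overlap, when known, into a private
    MMECHO block.  All UIDs are derived from the acquisition id so a given
    record always serialises byte-identically.
    """
    path = Path(path)
    frames8 = [np.clip(np.rint(f * 255.0), 0, 255).astype(np.uint8) for f in rec.frames]
    rows, cols = frames8[0].shape

    entropy = hashlib.sha256(rec.acquisition_id.encode()).hexdigest()
    ds = Dataset()
    ds.SOPClassUID = US_MULTIFRAME_SOP_CLASS
    ds.SOPInstanceUID = generate_uid(entropy_srcs=[entropy, "sop"])
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=[entropy, "series"])
    ds.StudyInstanceUID = generate_uid(entropy_srcs=[entropy, "study"])
    ds.Modality = "US"
    ds.SeriesDescription = rec.acquisition_id[:64]
    ds.NumberOfFrames = len(frames8)
    ds.Rows = rows
    ds.Columns = cols
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0

    region = Dataset()
    region.RegionSpatialFormat = 3  # M-mode
    region.RegionDataType = 1
    region.RegionFlags = 0
    region.PhysicalUnitsXDirection = 4  # seconds
    region.PhysicalUnitsYDirection = 3  # cm
    region.PhysicalDeltaX = rec.x_res_ms / 1000.0
    region.PhysicalDeltaY = rec.y_res_mm / 10.0
    ds.SequenceOfUltrasoundRegions = [region]

    if rec.overlap_ms is not None:
        block = ds.private_block(_PRIVATE_GROUP, _PRIVATE_CREATOR, create=True)
        block.add_new(_OVERLAP_ELEM, "DS", f"{rec.overlap_ms:.6f}")

    ds.PixelData = b"".join(f.tobytes() for f in frames8)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    ds.save_as(path, enforce_file_format=True)
    return path


def read_record(path: str | Path) -> MModeRecord:
    """Read a multi-frame ultrasound DICOM file into an MModeRecord.

    Pixel values are normalised to [0, 1].  Missing spacing attributes are
    a hard error naming the attribute; a single-frame file is accepted and
    behaves as an already-continuous record.
    """
    path = Path(path)
    if not path.exists():
        raise RecordReadError(f"no such file: {path}")
    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:  # noqa: BLE001 - surface as a structured error
        raise RecordReadError(f"cannot parse {path.name}: {exc}") from exc

    regions = getattr(ds, "SequenceOfUltrasoundRegions", None)
    if not regions:
        raise RecordReadError(
            f"{path.name}: missing SequenceOfUltrasoundRegions (no calibration)"
        )
    region = regions[0]
    for attr in ("PhysicalDeltaX", "PhysicalDeltaY"):
        if getattr(region, attr, None) is None:
            raise RecordReadError(f"{path.name}: missing spacing attribute {attr}")
    x_res_ms = float(region.PhysicalDeltaX) * 1000.0
    y_res_mm = float(region.PhysicalDeltaY) * 10.0

    if arr.ndim == 2:
        arr = arr[None]
    frames = [np.asarray(f, dtype=np.float32) / 255.0 for f in arr]

    overlap_ms = None
    try:
        block = ds.private_block(_PRIVATE_GROUP, _PRIVATE_CREATOR)
        overlap_ms = float(block[_OVERLAP_ELEM].value)
    except KeyError:
        pass

    return MModeRecord(
        frames=frames,
        x_res_ms=x_res_ms,
        y_res_mm=y_res_mm,
        acquisition_id=str(getattr(ds, "SeriesDescription", "")),
        overlap_ms=overlap_ms,
    )


# ---------------------------------------------------------------------------
# Stitching


def estimate_overlap_cols(prev: np.ndarray, nxt: np.ndarray, max_frac: float = 0.5) -> int:
    """Estimate the overlap (in columns) between two consecutive frames.

    Searches offsets 1..max_frac*width for the one minimising the mean
    absolute difference between the trailing block of ``prev`` and the
    leading block of ``nxt``; returns 0 when no offset matches well (the
    frames then simply abut).
    """
    w = prev.shape[1]
    max_o = max(1, int(max_frac * w))
    best_o, best_err = 0, np.inf
    for o in range(1, max_o + 1):
        err = float(np.abs(prev[:, w - o :] - nxt[:, :o]).mean())
        if err < best_err:
            best_err, best_o = err, o
    # overlapping columns are duplicated samples, so a true overlap matches
    # almost exactly even on noisy data; anything worse means no overlap
    return best_o if best_err < 5e-3 else 0


def stitch_frames(rec: MModeRecord) -> ContinuousEcho:
    """Join the frames of a record into one continuous image.

    Uses the recorded overlap metadata when present, otherwise estimates
    the overlap of every adjacent pair by block matching.
    """
    if not rec.frames:
        raise ValueError("record has no frames")
    w = rec.frames[0].shape[1]
    if rec.overlap_ms is not None:
        o = int(round(rec.overlap_ms / rec.x_res_ms))
        if o >= w:
            raise ValueError(f"overlap {o} cols >= frame width {w}")
        overlaps = [o] * (len(rec.frames) - 1)
    else:
        overlaps = [
            estimate_overlap_cols(a, b) for a, b in zip(rec.frames[:-1], rec.frames[1:])
        ]
        if any(o >= w for o in overlaps):
            raise ValueError("estimated overlap >= frame width")
    parts = [rec.frames[0]]
    parts.extend(f[:, o:] for f, o in zip(rec.frames[1:], overlaps))
    image = np.concatenate(parts, axis=1)
    return ContinuousEcho(
        image=image,
        x_res_ms=rec.x_res_ms,
        y_res_mm=rec.y_res_mm,
        acquisition_id=rec.acquisition_id,
    )


# ---------------------------------------------------------------------------
# Windowing


def _col_origins(width: int, win_w: int, step: int) -> tuple[list[int], bool]:
    """Column origins of a left-to-right sweep, last window right-aligned."""
    if width <= win_w:
        return [0], width < win_w
    origins = list(range(0, width - win_w + 1, step))
    if origins[-1] != width - win_w:
        origins.append(width - win_w)
    return origins, False


def _pad_to(img: np.ndarray, h: int, w: int) -> np.ndarray:
    out = np.zeros((h, w), dtype=img.dtype)
    out[: img.shape[0], : img.shape[1]] = img
    return out


def lv_band_top(image: np.ndarray, band: int) -> int:
    """Top row of the ``band``-row strip with maximal temporal variance.

    The LV band is where wall motion lives, so the strip whose rows vary
    most over time is centred on it.  Deterministic (first argmax).
    """
    h = image.shape[0]
    if h <= band:
        return 0
    row_var = image.var(axis=1)
    csum = np.concatenate(([0.0], np.cumsum(row_var)))
    strip = csum[band:] - csum[:-band]  # sum over [top, top+band)
    return int(np.argmax(strip))


def crop_classification_windows(
    echo: ContinuousEcho, size: int = 256, step: int = 128
) -> WindowSet:
    """Square crops for the quality classifier.

    Vertically centred on the LV band (maximal temporal-variance strip),
    swept horizontally with the given stride; the last window is
    right-aligned so the whole width is covered.  A record narrower (or
    shallower) than ``size`` yields zero-padded windows, flagged.
    """
    img = echo.image
    top = lv_band_top(img, size)
    band = img[top : top + size, :]
    origins_c, padded = _col_origins(img.shape[1], size, step)
    pad_rows = band.shape[0] < size
    crops = []
    for c in origins_c:
        crop = band[:, c : c + size]
        if padded or pad_rows:
            crop = _pad_to(crop, size, size)
        crops.append(crop)
    return WindowSet(
        crops=crops,
        origins=[(top, c) for c in origins_c],
        size=(size, size),
        step=step,
        padded=padded or pad_rows,
    )


def crop_segmentation_windows(
    echo: ContinuousEcho, width: int = 256, step: int = 128
) -> WindowSet:
    """Full-height, fixed-width crops for the segmenter."""
    img = echo.image
    h = img.shape[0]
    origins_c, padded = _col_origins(img.shape[1], width, step)
    crops = []
    for c in origins_c:
        crop = img[:, c : c + width]
        if padded:
            crop = _pad_to(crop, h, width)
        crops.append(crop)
    return WindowSet(
        crops=crops,
        origins=[(0, c) for c in origins_c],
        size=(h, width),
        step=step,
        padded=padded,
    )


# ---------------------------------------------------------------------------
# Masks


def traces_to_mask(
    upper_mm: np.ndarray, lower_mm: np.ndarray, echo: ContinuousEcho
) -> SegMask:
    """Rasterise upper/lower wall traces into a binary LV-interior mask.

    ``mask[r, c] = 1`` iff ``upper_mm[c] <= r * y_res < lower_mm[c]``.
    """
    upper_mm = np.asarray(upper_mm, dtype=np.float64)
    lower_mm = np.asarray(lower_mm, dtype=np.float64)
    h, wcols = echo.image.shape
    if upper_mm.shape != (wcols,) or lower_mm.shape != (wcols,):
        raise ValueError("traces must be defined on every column")
    if (upper_mm > lower_mm).any():
        raise ValueError("upper trace must not lie below lower trace")
    if (upper_mm < 0).any() or (lower_mm > h * echo.y_res_mm).any():
        raise ValueError("trace outside image depth")
    rows_mm = np.arange(h)[:, None] * echo.y_res_mm
    mask = (rows_mm >= upper_mm[None, :]) & (rows_mm < lower_mm[None, :])
    return SegMask(mask.astype(np.uint8), y_res_mm=echo.y_res_mm, x_res_ms=echo.x_res_ms)


def save_continuous(echo: ContinuousEcho, path: str | Path) -> None:
    """Save a stitched image as 16-bit PNG with a JSON spacing sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    img16 = np.clip(np.rint(echo.image * 65535.0), 0, 65535).astype(np.uint16)
    iio.imwrite(path, img16)
    sidecar = {
        "x_res_ms": echo.x_res_ms,
        "y_res_mm": echo.y_res_mm,
        "acquisition_id": echo.acquisition_id,
        "scale": 65535,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_continuous(path: str | Path) -> ContinuousEcho:
    import imageio.v3 as iio

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    img = np.asarray(iio.imread(path), dtype=np.float32) / meta["scale"]
    return ContinuousEcho(
        image=img,
        x_res_ms=meta["x_res_ms"],
        y_res_mm=meta["y_res_mm"],
        acquisition_id=meta.get("acquisition_id", ""),
    )
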