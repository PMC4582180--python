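"""Turn a FRAP time-lapse stack into a normalized recovery curve.

The three stages mirror a standard FRAP post-processing chain on embryonic
epithelia: rigid registration of frame-to-frame specimen drift against the
pre-bleach reference, mean-intensity extraction over a membrane ROI, and
full-scale normalization (pre-bleach mean = 1) with optional photofading
correction against an unbleached reference ROI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import dilation, footprint_rectangle
from skimage.registration import phase_cross_correlation

__all__ = [
    "ImageStack",
    "RoiSpec",
    "RecoveryCurve",
    "RegistrationResult",
    "register_stack",
    "extract_intensity",
    "normalize_curve",
]


@dataclass
class ImageStack:
    """A time x row x column intensity grid with physical calibration.

    ``bleach_frame`` is the index of the first post-bleach frame; frames
    ``0 .. bleach_frame-1`` are the pre-bleach reference frames.
    """

    data: np.ndarray              # (T, H, W) float64
    pixel_size: float             # micrometers / pixel
    frame_interval: float         # seconds
    bit_depth: int = 16
    bleach_frame: int = 2

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3-D (time, row, column)")
        if not (1 <= self.bleach_frame <= self.n_frames - 1):
            raise ValueError("bleach_frame must leave >=1 pre-bleach and >=1 post-bleach frame")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        limit = 2 ** self.bit_depth - 1
        if self.data.min() < 0 or self.data.max() > limit:
            raise ValueError(f"intensities must lie in [0, {limit}] for bit_depth={self.bit_depth}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_prebleach(self) -> int:
        return self.bleach_frame

    def times(self) -> np.ndarray:
        """Frame times in seconds with origin at the first post-bleach frame."""
        return (np.arange(self.n_frames) - self.bleach_frame) * self.frame_interval

    # --- I/O ------------------------------------------------------------
    def to_tiff(self, path: str | Path) -> None:
        path = Path(path)
        limit = 2 ** self.bit_depth - 1
        dtype = np.uint8 if self.bit_depth <= 8 else np.uint16
        tifffile.imwrite(
            path,
            np.clip(np.round(self.data), 0, limit).astype(dtype),
            photometric="minisblack",
        )
        meta = {
            "pixel_size_um": self.pixel_size,
            "frame_interval_s": self.frame_interval,
            "bit_depth": self.bit_depth,
            "bleach_frame": self.bleach_frame,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        data = tifffile.imread(path).astype(float)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            data=data,
            pixel_size=meta["pixel_size_um"],
            frame_interval=meta["frame_interval_s"],
            bit_depth=meta["bit_depth"],
            bleach_frame=meta["bleach_frame"],
        )


@dataclass
class RoiSpec:
    """A pixel-coordinate ROI: an axis-aligned rectangle or a thick polyline.

    Rectangles are 0-based half-open ``(r0, r1, c0, c1)``. Polylines are a
    list of ``(row, col)`` vertices dilated to ``width`` pixels.
    """

    kind: str = "rect"
    rect: tuple[int, int, int, int] | None = None
    points: Sequence[tuple[int, int]] | None = None
    width: int = 3

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        if self.kind == "rect":
            if self.rect is None:
                raise ValueError("rect ROI needs a (r0, r1, c0, c1) tuple")
            r0, r1, c0, c1 = self.rect
            m[max(r0, 0): r1, max(c0, 0): c1] = True
        elif self.kind == "line":
            if not self.points or len(self.points) < 2:
                raise ValueError("line ROI needs >=2 points")
            for (r0, c0), (r1, c1) in zip(self.points[:-1], self.points[1:]):
                rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
                keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
                m[rr[keep], cc[keep]] = True
            if self.width > 1:
                half = (int(self.width) - 1) // 2
                m = dilation(m, footprint_rectangle((2 * half + 1, 2 * half + 1)))
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if not m.any():
            raise ValueError("ROI does not intersect the image bounds")
        return m

    def to_json(self, path: str | Path) -> None:
        d = {"kind": self.kind, "rect": self.rect, "points": self.points, "width": self.width}
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiSpec":
        d = json.loads(Path(path).read_text())
        if d.get("rect") is not None:
            d["rect"] = tuple(d["rect"])
        if d.get("points") is not None:
            d["points"] = [tuple(p) for p in d["points"]]
        return cls(**d)


@dataclass
class RecoveryCurve:
    """Normalized relative fluorescence over time.

    ``times`` use the first post-bleach frame as origin (pre-bleach frames sit
    at negative times), ``values`` are relative fluorescence F_rel with the
    pre-bleach mean normalized to 1.
    """

    times: np.ndarray
    values: np.ndarray
    n_prebleach: int
    background: float = 0.0
    reference_corrected: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")
        if not (1 <= self.n_prebleach < len(self.times)):
            raise ValueError("need >=1 pre-bleach and >=1 post-bleach sample")

    @property
    def prebleach_values(self) -> np.ndarray:
        return self.values[: self.n_prebleach]

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.n_prebleach:]

    @property
    def post_values(self) -> np.ndarray:
        return self.values[self.n_prebleach:]

    def recovery(self) -> tuple[np.ndarray, np.ndarray]:
        """Recovery re-expressed relative to the first post-bleach value.

        R(t) = (F_rel(t) - F_rel(t0)) / (1 - F_rel(t0)) removes the bleach
        depth so that mobile fractions are comparable across bleach depths.
        """
        f0 = self.post_values[0]
        if f0 >= 1:
            raise ValueError("first post-bleach value >= 1: no bleach depth to normalize out")
        r = (self.post_values - f0) / (1.0 - f0)
        return self.post_times, r

    def to_csv(self, path: str | Path) -> None:
        t, r = self.recovery()
        df = pd.DataFrame({"time_s": self.times, "F_rel": self.values})
        df["R"] = np.concatenate([np.full(self.n_prebleach, np.nan), r])
        df.to_csv(path, index=False)
        meta = {
            "n_prebleach": self.n_prebleach,
            "background": self.background,
            "reference_corrected": self.reference_corrected,
            **self.meta,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1, default=float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "RecoveryCurve":
        df = pd.read_csv(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        n_pre = int(meta.pop("n_prebleach"))
        return cls(
            times=df["time_s"].to_numpy(),
            values=df["F_rel"].to_numpy(),
            n_prebleach=n_pre,
            background=float(meta.pop("background", 0.0)),
            reference_corrected=bool(meta.pop("reference_corrected", False)),
            meta=meta,
        )


@dataclass
class RegistrationResult:
    stack: ImageStack
    shifts: np.ndarray            # (T, 2) (row, col) drift estimate of each frame
    invalid: np.ndarray           # (T, H, W) bool, True where border fill was shifted in
    degenerate: np.ndarray        # (T,) bool, True where a frame was flat (zero shift forced)
    fill_value: float = 0.0


def register_stack(
    stack: ImageStack,
    upsample_factor: int = 10,
    fill_value: float = 0.0,
) -> RegistrationResult:
    """Rigid-translation registration against the mean pre-bleach frame.

    Shift estimation is two-stage: the integer offset comes from masked
    normalized cross-correlation (robust to the partial frame overlap a large
    drift causes), the sub-pixel residual from upsampled phase
    cross-correlation (``upsample_factor``) on the overlapping crop.  Each
    frame is shifted back onto the reference with linear interpolation;
    pixels that were filled in from outside the frame are flagged in
    ``invalid`` and must be excluded from intensity extraction.

    Returns the corrected stack together with the per-frame drift estimates
    (in pixels, (row, col), the translation the specimen underwent relative to
    the pre-bleach reference).
    """
    if stack.n_frames < 2:
        raise ValueError("registration needs at least 2 frames")
    reference = stack.data[: stack.n_prebleach].mean(axis=0)
    t = stack.n_frames
    shifts = np.zeros((t, 2))
    degenerate = np.zeros(t, dtype=bool)
    corrected = np.empty_like(stack.data)
    invalid = np.zeros(stack.data.shape, dtype=bool)
    ones = np.ones(stack.data.shape[1:])
    full = np.ones(stack.data.shape[1:], dtype=bool)
    h, w = stack.data.shape[1:]
    for k in range(t):
        frame = stack.data[k]
        if np.ptp(frame) == 0 or np.ptp(reference) == 0:
            degenerate[k] = True
            shift = np.zeros(2)
        else:
            # integer offset mapping `frame` onto `reference`
            coarse = phase_cross_correlation(
                reference, frame, reference_mask=full, moving_mask=full
            )[0]
            dr, dc = np.round(coarse).astype(int)
            r0, r1 = max(0, dr), min(h, h + dr)
            c0, c1 = max(0, dc), min(w, w + dc)
            if r1 - r0 >= 8 and c1 - c0 >= 8:
                fine = phase_cross_correlation(
                    reference[r0:r1, c0:c1],
                    frame[r0 - dr: r1 - dr, c0 - dc: c1 - dc],
                    upsample_factor=upsample_factor,
                    normalization=None,
                )[0]
            else:
                fine = np.zeros(2)
            shift = np.array([dr, dc], dtype=float) + fine
        corrected[k] = ndimage.shift(frame, shift, order=1, mode="constant", cval=fill_value)
        support = ndimage.shift(ones, shift, order=1, mode="constant", cval=0.0)
        invalid[k] = support < 0.999
        shifts[k] = -shift
    out = ImageStack(
        data=np.clip(corrected, 0, 2 ** stack.bit_depth - 1),
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
        bit_depth=stack.bit_depth,
        bleach_frame=stack.bleach_frame,
    )
    return RegistrationResult(out, shifts, invalid, degenerate, fill_value)


def extract_intensity(
    stack: ImageStack,
    roi: RoiSpec | np.ndarray,
    invalid: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Mean ROI intensity per frame, excluding registration-fill pixels.

    ``weights`` (same shape as a frame) selects a weighted mean instead of a
    plain mean; weights of masked pixels are dropped and renormalized.
    """
    roi_mask = roi.mask(stack.data.shape[1:]) if isinstance(roi, RoiSpec) else np.asarray(roi, bool)
    if roi_mask.shape != stack.data.shape[1:]:
        raise ValueError("ROI mask shape does not match frame shape")
    if not roi_mask.any():
        raise ValueError("ROI is empty or fully outside the image")
    series = np.empty(stack.n_frames)
    for k in range(stack.n_frames):
        valid = roi_mask if invalid is None else roi_mask & ~invalid[k]
        if not valid.any():
            raise ValueError(f"frame {k}: ROI fully covered by registration fill")
        if weights is None:
            series[k] = stack.data[k][valid].mean()
        else:
            w = weights[valid]
            series[k] = float(np.sum(stack.data[k][valid] * w) / np.sum(w))
    return series


def normalize_curve(
    raw: np.ndarray,
    times: np.ndarray,
    n_prebleach: int,
    background: float = 0.0,
    reference: np.ndarray | None = None,
) -> RecoveryCurve:
    """Full-scale normalization: F_rel(t) = (I(t) - B) / (mean_pre - B).

    If an unbleached ``reference`` ROI series is supplied, every sample is
    additionally divided by the identically-normalized reference, which
    cancels a multiplicative photofading common to both ROIs.
    """
    raw = np.asarray(raw, dtype=float)
    times = np.asarray(times, dtype=float)
    if raw.shape != times.shape:
        raise ValueError("raw series and times must have the same length")
    if n_prebleach < 1 or n_prebleach >= len(raw):
        raise ValueError("need >=1 pre-bleach and >=1 post-bleach sample")
    pre_mean = raw[:n_prebleach].mean()
    if background >= pre_mean:
        raise ValueError("background >= pre-bleach mean: non-physical normalization")
    f_rel = (raw - background) / (pre_mean - background)
    corrected = False
    if reference is not None:
        reference = np.asarray(reference, dtype=float)
        if reference.shape != raw.shape:
            raise ValueError("reference series must match raw series length")
        ref_pre = reference[:n_prebleach].mean()
        if background >= ref_pre:
            raise ValueError("background >= reference pre-bleach mean")
        ref_rel = (reference - background) / (ref_pre - background)
        if np.any(ref_rel <= 0):
            raise ValueError("reference series crosses zero after normalization")
        f_rel = f_rel / ref_rel
        corrected = True
    return RecoveryCurve(
        times=times,
        values=f_rel,
        n_prebleach=n_prebleach,
        background=background,
        reference_corrected=corrected,
    )
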