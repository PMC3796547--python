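"""Reading, assembling and pre-conditioning per-ROI calcium traces.

A recording is represented as a :class:`RoiTraceSet`: a ``T x N`` matrix of
fluorescence (or ratio) values, one column per circular region of interest
(ROI).  ROIs are drawn along the cell and labelled ``1..N`` starting from the
growth cone; ROI ``0`` is by convention drawn outside the cell and supplies
the background trace, so it never appears as a column of the trace matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

VALID_CHANNELS = ("ratio", "f340", "f380")


@dataclass(frozen=True)
class RoiTraceSet:
    """Time-by-ROI matrix of concentration-proxy values.

    Parameters
    ----------
    values
        ``(T, N)`` float array; frame ``t`` of ROI ``n`` at ``values[t, n]``.
    dt
        Sampling interval in seconds.
    roi_ids
        Strictly increasing integer labels, growth-cone end first (``1..N``).
    channel
        One of ``"ratio"``, ``"f340"``, ``"f380"``.
    background_subtracted
        Whether the ROI-0 background trace has already been removed.
    n_guarded
        Number of denominator values that hit the epsilon guard when this set
        was produced by :func:`compute_ratio` (0 otherwise).
    """

    values: np.ndarray
    dt: float
    roi_ids: np.ndarray = None  # type: ignore[assignment]
    channel: str = "ratio"
    background_subtracted: bool = False
    n_guarded: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (frames x ROIs) array")
        T, N = values.shape
        if N < 2:
            raise ValueError(f"need at least 2 ROIs, got {N}")
        if T < 8:
            raise ValueError(f"need at least 8 frames, got {T}")
        if not np.all(np.isfinite(values)):
            raise ValueError("trace matrix contains non-finite values")
        if self.dt <= 0:
            raise ValueError(f"sampling interval must be positive, got {self.dt}")
        roi_ids = self.roi_ids
        if roi_ids is None:
            roi_ids = np.arange(1, N + 1)
        roi_ids = np.asarray(roi_ids, dtype=int)
        if roi_ids.shape != (N,):
            raise ValueError("roi_ids length must match the number of ROI columns")
        if np.any(np.diff(roi_ids) <= 0):
            raise ValueError("roi_ids must be strictly increasing")
        if 0 in roi_ids:
            raise ValueError("ROI 0 is reserved for the background trace")
        if self.channel not in VALID_CHANNELS:
            raise ValueError(f"channel must be one of {VALID_CHANNELS}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "roi_ids", roi_ids)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.dt


@dataclass(frozen=True)
class RoiGeometrySpec:
    """Identical circular ROIs along the cell, ordered growth cone -> soma."""

    centers: np.ndarray  # (N, 2) array of (x, y) pixel coordinates
    radius_px: int = 3

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 2:
            raise ValueError("centers must be an (N, 2) array of (x, y) pairs")
        if int(self.radius_px) != self.radius_px or self.radius_px < 0:
            raise ValueError("radius_px must be a non-negative integer")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "radius_px", int(self.radius_px))


def load_traces(path, dt: float, channel: str = "ratio",
                background_subtracted: bool = False) -> RoiTraceSet:
    """Load a delimited trace table into a :class:`RoiTraceSet`.

    The table is column-per-ROI with an optional leading time column (header
    ``t``); headers ``roi1..roiN`` follow the cone -> soma ordering.  Comma,
    tab and whitespace delimiters are auto-detected.  Any non-numeric or
    missing cell is an error.
    """
    if dt <= 0:
        raise ValueError(f"sampling interval must be positive, got {dt}")
    df = pd.read_csv(path, sep=None, engine="python")
    if df.isna().any().any():
        raise ValueError(f"non-numeric or missing cell in trace table {path}")
    cols = [str(c).strip() for c in df.columns]
    roi_ids = None
    if cols and cols[0].lower() in ("t", "time", "time_s"):
        df = df.iloc[:, 1:]
        cols = cols[1:]
    if all(c.lower().startswith("roi") and c[3:].isdigit() for c in cols):
        roi_ids = np.array([int(c[3:]) for c in cols])
    values = df.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("trace table must contain at least 2 ROI columns")
    return RoiTraceSet(values=values, dt=dt, roi_ids=roi_ids, channel=channel,
                       background_subtracted=background_subtracted)


def save_traces(traces: RoiTraceSet, path) -> None:
    """Write a trace table (``t,roi1,...,roiN`` header) readable by
    :func:`load_traces`; full float round-trip precision."""
    df = pd.DataFrame(traces.values,
                      columns=[f"roi{i}" for i in traces.roi_ids])
    df.insert(0, "t", traces.times)
    df.to_csv(path, index=False, float_format="%.17g")


def subtract_background(traces: RoiTraceSet, background_trace) -> RoiTraceSet:
    """Subtract the ROI-0 (outside-the-cell) trace from every ROI, frame by
    frame.  Frame-wise subtraction also corrects slow lamp drift."""
    if traces.background_subtracted:
        raise ValueError("traces are already background-subtracted")
    bg = np.asarray(background_trace, dtype=float).reshape(-1)
    if bg.shape[0] != traces.n_frames:
        raise ValueError(
            f"background trace length {bg.shape[0]} != number of frames "
            f"{traces.n_frames}")
    return replace(traces, values=traces.values - bg[:, None],
                   background_subtracted=True)


def compute_ratio(f340: RoiTraceSet, f380: RoiTraceSet,
                  eps: float = 1e-9) -> RoiTraceSet:
    """Ratiometric signal R = F340/F380, element-wise.

    Both inputs must be background-subtracted and share shape and sampling.
    Denominators below ``eps`` are clamped to ``eps``; the number of clamped
    cells is recorded in ``n_guarded`` on the result.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if f340.values.shape != f380.values.shape:
        raise ValueError("F340 and F380 trace matrices differ in shape")
    if f340.dt != f380.dt:
        raise ValueError("F340 and F380 sampling intervals differ")
    if not (f340.background_subtracted and f380.background_subtracted):
        raise ValueError("both channels must be background-subtracted "
                         "before ratioing")
    denom = f380.values
    guarded = int(np.count_nonzero(denom <= eps))
    ratio = f340.values / np.maximum(denom, eps)
    return RoiTraceSet(values=ratio, dt=f340.dt, roi_ids=f340.roi_ids,
                       channel="ratio", background_subtracted=True,
                       n_guarded=guarded)


def circle_mask(shape: tuple[int, int], center: tuple[float, float],
                radius: float) -> np.ndarray:
    """Boolean mask of pixels whose *center* lies within ``radius`` of
    ``center`` (inclusive); deterministic pixel-in-circle rule."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    cx, cy = center
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2


def extract_roi_traces(stack: np.ndarray, spec: RoiGeometrySpec, dt: float,
                       channel: str = "f380") -> RoiTraceSet:
    """Mean intensity inside each circular ROI, per frame.

    ``stack`` is a ``(T, H, W)`` grayscale image stack.  Every circle must lie
    fully inside the frame.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("image stack must be 3-D (frames, height, width)")
    T, H, W = stack.shape
    r = spec.radius_px
    flat = stack.reshape(T, -1)
    traces = np.empty((T, len(spec.centers)))
    for i, (cx, cy) in enumerate(spec.centers):
        if cx - r < 0 or cy - r < 0 or cx + r > W - 1 or cy + r > H - 1:
            raise ValueError(f"ROI {i + 1} circle extends outside the image")
        mask = circle_mask((H, W), (cx, cy), r)
        if not mask.any():
            raise ValueError(f"ROI {i + 1} mask is empty")
        traces[:, i] = flat[:, mask.ravel()].mean(axis=1)
    return RoiTraceSet(values=traces, dt=dt, channel=channel)


def load_stack(path) -> np.ndarray:
    """Load a multi-page grayscale TIFF stack as a (T, H, W) float array
    (one page per frame, one file per excitation wavelength)."""
    import tifffile

    stack = np.asarray(tifffile.imread(path), dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a (frames, H, W) grayscale stack, got "
                         f"shape {stack.shape}")
    return stack


def detrend(trace, mode: str = "mean") -> np.ndarray:
    """Remove the DC level (``mean``), a least-squares line (``linear``) or
    nothing (``none``) from a 1-D trace."""
    x = np.asarray(trace, dtype=float).reshape(-1)
    if x.size < 2:
        raise ValueError("trace must have at least 2 samples")
    if mode == "none":
        return x.copy()
    if mode == "mean":
        return x - x.mean()
    if mode == "linear":
        t = np.arange(x.size, dtype=float)
        coeffs = np.polynomial.polynomial.polyfit(t, x, 1)
        return x - np.polynomial.polynomial.polyval(t, coeffs)
    raise ValueError(f"unknown detrend mode {mode!r}")
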