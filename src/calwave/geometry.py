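"""Surface-to-volume profile from single-wavelength fluorescence.

At a frame where the calcium ratio is spatially homogeneous, the intensity
recorded at a single excitation wavelength is proportional to the cytosolic
volume under each ROI.  Since every ROI has the same area A, that intensity
is proportional to the local cytosolic thickness h(n); approximating the
volume under a ROI as a cylinder whose membrane surface is its top and
bottom faces (S = 2A, V = A*h) gives the local surface-to-volume proxy
sv(n) = 2/h(n).  Both h and sv are in arbitrary fluorescence units — only
their variation along the cell matters, and the downstream Pearson
correlations are invariant to the unknown proportionality constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_io import RoiTraceSet


@dataclass(frozen=True)
class GeometryProfile:
    """Per-ROI thickness proxy and surface-to-volume proxy.

    Arbitrary units; do not mix profiles from different cells without
    renormalizing.
    """

    h: np.ndarray
    sv: np.ndarray
    roi_ids: np.ndarray
    frames_used: list[int]
    homogeneity_cv: float

    def __post_init__(self) -> None:
        if np.any(self.h <= 0):
            raise ValueError("thickness proxy must be positive everywhere")
        if not self.frames_used:
            raise ValueError("frames_used must be non-empty")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"roi": self.roi_ids, "h": self.h, "sv": self.sv})


def find_homogeneous_frames(ratio_traces: RoiTraceSet,
                            cv_threshold: float = 0.05,
                            k: int = 3) -> list[int]:
    """Frames where the ratio is spatially uniform across ROIs.

    Returns up to ``k`` frame indices with the lowest spatial coefficient of
    variation (std/mean over ROIs), all below ``cv_threshold``; ties broken
    by earliest frame.
    """
    if ratio_traces.channel != "ratio":
        raise ValueError("homogeneity is assessed on the ratio channel")
    vals = ratio_traces.values
    mean = vals.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, vals.std(axis=1) / np.abs(mean), np.inf)
    ok = np.nonzero(cv < cv_threshold)[0]
    if ok.size == 0:
        raise ValueError(
            f"no frame has spatial CV below {cv_threshold} "
            f"(best: {np.nanmin(cv):.4g})")
    # stable sort keeps the earliest frame first among ties
    order = ok[np.argsort(cv[ok], kind="stable")]
    return [int(i) for i in order[:k]]


def estimate_thickness(f_single: RoiTraceSet, frames: list[int]) -> np.ndarray:
    """Thickness proxy h(n): mean single-wavelength intensity over the
    selected homogeneous frames (intensity ~ volume ~ thickness for
    equal-area ROIs).  The 380 nm channel is usually preferred: at basal
    calcium it carries the stronger signal.
    """
    if f_single.channel not in ("f340", "f380"):
        raise ValueError("thickness needs a single-wavelength channel "
                         "(f340 or f380)")
    if not f_single.background_subtracted:
        raise ValueError("single-wavelength traces must be "
                         "background-subtracted")
    frames = list(frames)
    if not frames:
        raise ValueError("no frames selected")
    if min(frames) < 0 or max(frames) >= f_single.n_frames:
        raise ValueError("frame index out of range")
    h = f_single.values[frames].mean(axis=0)
    if np.any(h <= 0):
        raise ValueError("non-positive intensity at some ROI: check the "
                         "background subtraction")
    return h


def sv_ratio(h) -> np.ndarray:
    """Surface-to-volume proxy sv(n) = 2/h(n) (cylinder: S = 2A, V = A*h).

    The factor 2 is conventional; downstream correlations only use sv up to
    a positive scale.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("thickness must be positive")
    return 2.0 / h


def build_geometry(ratio_traces: RoiTraceSet, f_single: RoiTraceSet,
                   cv_threshold: float = 0.05, k: int = 3) -> GeometryProfile:
    """Homogeneous-frame selection, thickness estimate and sv profile."""
    frames = find_homogeneous_frames(ratio_traces, cv_threshold, k)
    h = estimate_thickness(f_single, frames)
    vals = ratio_traces.values[frames]
    cv = float((vals.std(axis=1) / np.abs(vals.mean(axis=1))).max())
    return GeometryProfile(h=h, sv=sv_ratio(h),
                           roi_ids=f_single.roi_ids.copy(),
                           frames_used=frames, homogeneity_cv=cv)
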