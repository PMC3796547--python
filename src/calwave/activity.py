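"""Energy and activity measures derived from scaleograms.

Each ROI's scaleogram is reduced to

* the energy density ``E(t) = int |W(nu, t)|^2 dnu`` (all frequencies
  integrated),
* its time average and total (``E_avg * window length = total_E``), and
* the maxima-based activity index
  ``I(t) = sum over frequency-axis local maxima of nu * |W(nu, t)|``,
  smoothed by a centered moving average.

``I`` weights each spectral ridge by its frequency, which amplifies the
high-frequency components that mark sharp peaks and oscillatory bursts; its
time average ``Y(n)`` is the per-ROI integral measure of oscillatory
activity used for the spatial profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import grey_dilation

from .cwt import Scaleogram, WaveletParams, cwt
from .signal_io import RoiTraceSet, detrend

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ActivityProfile:
    """Per-ROI activity summaries, cone -> soma order.

    ``I_map``/``E_map`` are ``(N, T)``; ``Y``, ``E_avg`` and ``total_E`` are
    their windowed time reductions (length N).
    """

    I_map: np.ndarray
    E_map: np.ndarray
    Y: np.ndarray
    E_avg: np.ndarray
    total_E: np.ndarray
    roi_ids: np.ndarray
    times: np.ndarray
    dt: float
    smoothing_window: float

    def to_frame(self) -> pd.DataFrame:
        """Per-ROI summary table (roi, Y, E_avg, total_E)."""
        return pd.DataFrame({"roi": self.roi_ids, "Y": self.Y,
                             "E_avg": self.E_avg, "total_E": self.total_E})

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form (roi, t, I, E) table for space-time map plotting."""
        n, t = np.meshgrid(self.roi_ids, self.times, indexing="ij")
        return pd.DataFrame({"roi": n.ravel(), "t": t.ravel(),
                             "I": self.I_map.ravel(),
                             "E": self.E_map.ravel()})


def _window_slice(n_frames: int, dt: float, window) -> slice:
    if window is None:
        return slice(0, n_frames)
    t0, t1 = window
    i0 = int(np.ceil(t0 / dt - 1e-9))
    i1 = int(np.floor(t1 / dt + 1e-9)) + 1
    i0 = max(i0, 0)
    i1 = min(i1, n_frames)
    if i1 <= i0:
        raise ValueError(f"window {window} selects no frames")
    return slice(i0, i1)


def energy_density(sc: Scaleogram) -> np.ndarray:
    """Frequency-integrated squared modulus, one value per frame.

    Trapezoidal integration over the (ascending) frequency grid; with a
    single-frequency grid the integral degenerates to 0, so ``|W|^2`` is
    returned instead (with a logged warning).
    """
    mod2 = np.abs(sc.coeffs) ** 2
    if sc.freqs.size == 0:
        raise ValueError("empty frequency grid")
    if sc.freqs.size == 1:
        logger.warning("single-frequency grid: energy density taken as |W|^2 "
                       "without a bandwidth factor")
        return mod2[0]
    return np.trapezoid(mod2, x=sc.freqs, axis=0)


def time_avg_energy(E, dt: float, window=None) -> float:
    """Mean of the energy density over the observation window."""
    E = np.asarray(E, dtype=float)
    sl = _window_slice(E.size, dt, window)
    return float(E[sl].mean())


def total_energy(E, dt: float, window=None) -> float:
    """Integral of the energy density over the window: the total energy of
    the signal in that interval.  Equals ``time_avg_energy * window length``
    with the window length counted as ``n_frames * dt``."""
    E = np.asarray(E, dtype=float)
    sl = _window_slice(E.size, dt, window)
    return float(E[sl].sum() * dt)


def _local_maxima_mask(mod: np.ndarray) -> np.ndarray:
    """Strictly interior local maxima along axis 0 via 3-sample dilation."""
    if mod.shape[0] < 3:
        return np.zeros(mod.shape, dtype=bool)
    size = (3,) + (1,) * (mod.ndim - 1)
    dil = grey_dilation(mod, size=size, mode="nearest")
    mask = mod >= dil
    # a flat column dilates to itself everywhere; demand a strict drop on at
    # least one side so plateaus of a constant column are not maxima
    rises = np.zeros_like(mask)
    rises[1:-1] = (mod[1:-1] > mod[:-2]) | (mod[1:-1] > mod[2:])
    mask &= rises
    mask[0] = False
    mask[-1] = False
    return mask


def frequency_maxima(sc: Scaleogram, frame: int,
                     min_prominence: float = 0.05,
                     use_coi: bool = True) -> list[tuple[float, float]]:
    """Local maxima of ``|W|`` along the frequency axis at one frame.

    Maxima below ``min_prominence`` times the column maximum are discarded
    (0 restores the unthresholded definition); frequencies inside the cone
    of influence are excluded when ``use_coi``.  Returns ``(freq, modulus)``
    pairs, ascending in frequency; may be empty.
    """
    if not 0 <= frame < sc.times.size:
        raise IndexError(f"frame {frame} out of range")
    col = np.abs(sc.coeffs[:, frame])
    mask = _local_maxima_mask(col[:, None])[:, 0]
    if use_coi:
        mask &= sc.coi_mask()[:, frame]
    if mask.any() and col.max() > 0:
        mask &= col >= min_prominence * col.max()
    idx = np.nonzero(mask)[0]
    return [(float(sc.freqs[j]), float(col[j])) for j in idx]


def activity_index(sc: Scaleogram, smooth_window: float = 5.0,
                   min_prominence: float = 0.05,
                   use_coi: bool = True) -> np.ndarray:
    """Frequency-weighted sum of scaleogram maxima, smoothed in time.

    ``raw(t) = sum_{nu_m in maxima(t)} nu_m * |W(nu_m, t)|``; the number of
    maxima varies with t.  ``raw`` is then smoothed by a centered moving
    average of width ``smooth_window`` seconds (edge frames use truncated
    windows), which avoids abrupt variations where frequency ridges appear
    or vanish.
    """
    if smooth_window < sc.dt:
        raise ValueError("smooth_window must be at least one frame")
    mod = np.abs(sc.coeffs)
    mask = _local_maxima_mask(mod)
    if use_coi:
        mask &= sc.coi_mask()
    colmax = mod.max(axis=0, keepdims=True)
    with np.errstate(invalid="ignore"):
        mask &= mod >= min_prominence * colmax
    raw = np.where(mask, sc.freqs[:, None] * mod, 0.0).sum(axis=0)

    w = int(round(smooth_window / sc.dt))
    w = max(w, 1)
    if w % 2 == 0:
        w += 1
    kernel = np.ones(w)
    smoothed = np.convolve(raw, kernel, mode="same")
    counts = np.convolve(np.ones_like(raw), kernel, mode="same")
    return smoothed / counts


def time_avg_activity(I, dt: float, window=None) -> float:
    """Time average Y of the activity index over the observation window."""
    I = np.asarray(I, dtype=float)
    sl = _window_slice(I.size, dt, window)
    return float(I[sl].mean())


def build_profile(traces: RoiTraceSet, params: WaveletParams | None = None,
                  smooth_window: float = 5.0, window=None,
                  min_prominence: float = 0.05,
                  detrend_mode: str = "mean",
                  use_coi: bool = True) -> ActivityProfile:
    """Full per-cell activity profile: CWT of every ROI trace, then the
    activity index and energy reductions, assembled cone -> soma.

    Traces are detrended (default: mean removal, so the DC level never
    leaks into the low-frequency scales) before transformation.
    """
    if params is None:
        params = WaveletParams()
    N = traces.n_rois
    T = traces.n_frames
    I_map = np.empty((N, T))
    E_map = np.empty((N, T))
    Y = np.empty(N)
    E_avg = np.empty(N)
    tot = np.empty(N)
    for i in range(N):
        x = detrend(traces.values[:, i], mode=detrend_mode)
        sc = cwt(x, traces.dt, params, roi_id=int(traces.roi_ids[i]))
        E = energy_density(sc)
        I = activity_index(sc, smooth_window=smooth_window,
                           min_prominence=min_prominence, use_coi=use_coi)
        I_map[i] = I
        E_map[i] = E
        Y[i] = time_avg_activity(I, traces.dt, window)
        E_avg[i] = time_avg_energy(E, traces.dt, window)
        tot[i] = total_energy(E, traces.dt, window)
    return ActivityProfile(I_map=I_map, E_map=E_map, Y=Y, E_avg=E_avg,
                           total_E=tot, roi_ids=traces.roi_ids.copy(),
                           times=traces.times, dt=traces.dt,
                           smoothing_window=smooth_window)
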