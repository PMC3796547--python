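"""Morlet continuous wavelet transform computed as a Fourier-domain product.

The mother wavelet is the zero-mean-corrected Morlet

    psi(t) = pi^(-1/4) * exp(-t^2/2) * (exp(i*omega0*t) - exp(-omega0^2/2)),

dilated and translated as ``psi_{s,tau}(t) = s^(-1/2) psi((t - tau)/s)`` so
that the L2 norm is preserved across scales.  The transform of a trace x is

    W(s, tau) = s^(-1/2) * integral x(t) psi*((t - tau)/s) dt,

evaluated for every scale of a geometric frequency grid via one FFT of the
(padded) trace and one inverse FFT per scale, at O(F * T * log T) cost.  A
scale s maps to the frequency of the peak of the Morlet Fourier spectrum,
``nu = omega0 / (2*pi*s)``; this relation is used everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# e-folding time of the Morlet Gaussian envelope, in units of the scale s;
# coefficients closer than sqrt(2)*s to either record edge are edge-affected.
COI_EFOLD = np.sqrt(2.0)


@dataclass(frozen=True)
class WaveletParams:
    """Morlet CWT configuration.

    omega0 : dimensionless central parameter of the Morlet wavelet; >= 5 keeps
        the analytic (zero-mean) approximation admissible and the
        scale-frequency identification accurate to < 1 %.
    voices_per_octave : grid density of the geometric frequency grid.
    fmin, fmax : grid limits in Hz; ``None`` selects the defaults
        ``4/(T*dt)`` and ``Nyquist/2`` at transform time.
    pad_mode : ``"reflect"`` (default) or ``"zero"`` padding to the next
        power of two before the FFT.
    """

    omega0: float = 6.0
    voices_per_octave: int = 16
    fmin: float | None = None
    fmax: float | None = None
    pad_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.omega0 < 5:
            raise ValueError("omega0 must be >= 5 for an admissible analytic "
                             "Morlet")
        if self.voices_per_octave < 1:
            raise ValueError("voices_per_octave must be >= 1")
        if self.pad_mode not in ("zero", "reflect"):
            raise ValueError("pad_mode must be 'zero' or 'reflect'")
        if self.fmin is not None and self.fmin <= 0:
            raise ValueError("fmin must be positive")
        if (self.fmin is not None and self.fmax is not None
                and self.fmax < self.fmin):
            raise ValueError("fmax must be >= fmin")


@dataclass(frozen=True)
class Scaleogram:
    """Complex CWT coefficients of one ROI trace on a (frequency, time) grid.

    ``coeffs[f, t]`` is W at ``freqs[f]`` (Hz, strictly increasing) and frame
    ``t``.  ``coi_n_trusted[t]`` counts the trustworthy frequencies at frame
    ``t``; since frequencies ascend, those are always the *highest*
    ``coi_n_trusted[t]`` rows (smallest scales).  Use :meth:`coi_mask` rather
    than indexing by hand.
    """

    coeffs: np.ndarray          # (F, T) complex
    freqs: np.ndarray           # (F,) Hz, ascending
    scales: np.ndarray          # (F,) seconds, descending
    times: np.ndarray           # (T,) seconds
    dt: float
    omega0: float
    coi_n_trusted: np.ndarray   # (T,) number of trustworthy (highest) freqs
    roi_id: int = 0

    @property
    def modulus(self) -> np.ndarray:
        return np.abs(self.coeffs)

    def to_long_frame(self):
        """Long-form (freq, t, modulus) table for export or plotting."""
        import pandas as pd

        f, t = np.meshgrid(self.freqs, self.times, indexing="ij")
        return pd.DataFrame({"freq": f.ravel(), "t": t.ravel(),
                             "modulus": np.abs(self.coeffs).ravel()})

    def coi_mask(self) -> np.ndarray:
        """Boolean (F, T) mask; True where the coefficient is trustworthy
        (its scale's e-folding time fits inside the record at that frame)."""
        F = self.freqs.size
        # freqs ascending <=> scales descending: the n trusted frequencies at
        # a frame are the n highest, i.e. the n smallest scales.
        idx = np.arange(F)[:, None]
        return idx >= (F - self.coi_n_trusted[None, :])


def morlet_mother(t, omega0: float = 6.0) -> np.ndarray:
    """Zero-mean-corrected Morlet mother wavelet evaluated at ``t``."""
    if omega0 <= 0:
        raise ValueError("omega0 must be positive")
    t = np.asarray(t, dtype=float)
    correction = np.exp(-omega0 ** 2 / 2.0)
    return (np.pi ** -0.25 * np.exp(-t ** 2 / 2.0)
            * (np.exp(1j * omega0 * t) - correction))


def wavelet_family(s: float, tau: float, omega0: float = 6.0):
    """Dilated/translated Morlet ``psi_{s,tau}``; L2 norm independent of s."""
    if s <= 0:
        raise ValueError("scale must be positive")

    def psi(t):
        t = np.asarray(t, dtype=float)
        return s ** -0.5 * morlet_mother((t - tau) / s, omega0)

    return psi


def morlet_fourier(omega, omega0: float = 6.0) -> np.ndarray:
    """Exact continuous Fourier transform of the corrected Morlet,
    ``psihat(w) = int psi(t) exp(-i w t) dt`` (real-valued)."""
    omega = np.asarray(omega, dtype=float)
    c = np.exp(-omega0 ** 2 / 2.0)
    return (np.pi ** -0.25 * np.sqrt(2.0 * np.pi)
            * (np.exp(-((omega - omega0) ** 2) / 2.0)
               - c * np.exp(-omega ** 2 / 2.0)))


def scale_to_frequency(s, omega0: float = 6.0) -> np.ndarray:
    """Peak frequency (Hz) of the Morlet spectrum at scale ``s`` seconds."""
    return omega0 / (2.0 * np.pi * np.asarray(s, dtype=float))


def frequency_to_scale(nu, omega0: float = 6.0) -> np.ndarray:
    """Scale (seconds) whose Morlet spectrum peaks at ``nu`` Hz."""
    return omega0 / (2.0 * np.pi * np.asarray(nu, dtype=float))


def make_frequency_grid(params: WaveletParams, dt: float,
                        n_frames: int | None = None):
    """Geometric frequency grid and matching scales.

    Frequencies run from ``fmin`` upward in steps of ``2^(1/voices)`` while
    not exceeding ``fmax`` (both endpoints included when they fall on the
    grid).  Returns ``(freqs ascending, scales descending)``.
    """
    nyquist = 1.0 / (2.0 * dt)
    fmin = params.fmin
    fmax = params.fmax
    if fmin is None:
        if n_frames is None:
            raise ValueError("fmin default needs the trace length")
        fmin = 4.0 / (n_frames * dt)
    if fmax is None:
        fmax = nyquist / 2.0
    if fmax > nyquist * (1 + 1e-12):
        raise ValueError(f"fmax {fmax} exceeds the Nyquist frequency "
                         f"{nyquist}")
    if fmin > fmax:
        raise ValueError("fmin exceeds fmax")
    v = params.voices_per_octave
    n_octaves = np.log2(fmax / fmin)
    n_points = int(np.floor(n_octaves * v + 1e-9)) + 1
    freqs = fmin * 2.0 ** (np.arange(n_points) / v)
    freqs = freqs[freqs <= fmax * (1 + 1e-12)]
    scales = frequency_to_scale(freqs, params.omega0)
    return freqs, scales


def cone_of_influence(n_frames: int, dt: float, scales) -> np.ndarray:
    """Per-frame count of trustworthy scales.

    ``scales`` must be sorted descending (the ascending-frequency
    convention).  At frame ``k`` a scale is trustworthy when its e-folding
    time ``s*sqrt(2)`` fits within the distance to the nearest record edge;
    the return value ``n[k]`` is the number of trustworthy (smallest) scales.
    """
    scales = np.asarray(scales, dtype=float)
    k = np.arange(n_frames)
    dist = np.minimum(k, n_frames - 1 - k) * dt
    # scales descending: the trusted scales (s*sqrt(2) <= dist) are the
    # trailing (smallest) entries; count them via the ascending -s*sqrt(2)
    first_ok = np.searchsorted(-scales * COI_EFOLD, -dist, side="left")
    return (scales.size - first_ok).astype(int)


def _pad(x: np.ndarray, mode: str) -> tuple[np.ndarray, int]:
    """Pad to the next power of two >= 4T (generous margins keep the
    circular wrap-around of the largest scales negligible); returns
    (padded, offset)."""
    T = x.size
    P = 1 << int(np.ceil(np.log2(max(4 * T, 2))))
    extra = P - T
    left = extra // 2
    right = extra - left
    if mode == "zero":
        xp = np.pad(x, (left, right))
    else:
        # reflect in chunks no longer than T-1 so short traces still pad
        xp = x
        lneed, rneed = left, right
        while lneed > 0 or rneed > 0:
            lt = min(lneed, xp.size - 1)
            rt = min(rneed, xp.size - 1)
            xp = np.pad(xp, (lt, rt), mode="reflect")
            lneed -= lt
            rneed -= rt
    return xp, left


from functools import lru_cache


@lru_cache(maxsize=16)
def _fourier_kernels(P: int, dt: float, omega0: float,
                     scales: tuple) -> np.ndarray:
    """Per-scale Fourier multipliers sqrt(s) * psihat(s w) on the padded
    grid; cached because they depend only on the grid geometry, not the
    trace."""
    omega = 2.0 * np.pi * np.fft.fftfreq(P, d=dt)
    s = np.asarray(scales, dtype=float)
    return np.sqrt(s)[:, None] * morlet_fourier(s[:, None] * omega[None, :],
                                                omega0)


def cwt(trace, dt: float, params: WaveletParams | None = None,
        roi_id: int = 0) -> Scaleogram:
    """Morlet CWT of a single trace on a geometric frequency grid.

    The trace is padded (``params.pad_mode``) to the next power of two of at
    least four times its length; each scale row is the inverse FFT of
    ``X(w) * sqrt(s) * psihat(s w)`` restricted to the original frames.
    ``psihat`` is real, so conjugation is a no-op and the product implements
    the correlation integral with ``psi*`` directly.
    """
    if params is None:
        params = WaveletParams()
    x = np.asarray(trace, dtype=float).reshape(-1)
    T = x.size
    if T < 8:
        raise ValueError("trace must have at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite values")
    freqs, scales = make_frequency_grid(params, dt, n_frames=T)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")

    xp, offset = _pad(x, params.pad_mode)
    P = xp.size
    X = np.fft.fft(xp)
    kernels = _fourier_kernels(P, dt, params.omega0, tuple(scales))
    coeffs = np.fft.ifft(X[None, :] * kernels, axis=1)[:, offset:offset + T]

    coi = cone_of_influence(T, dt, scales)
    return Scaleogram(coeffs=coeffs, freqs=freqs, scales=scales,
                      times=np.arange(T) * dt, dt=dt, omega0=params.omega0,
                      coi_n_trusted=coi, roi_id=roi_id)
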