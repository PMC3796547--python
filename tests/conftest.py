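import numpy as np
import pytest

from calwave import SyntheticCellSpec, generate_cell
from calwave.cwt import _pad, morlet_mother


@pytest.fixture(scope="session")
def small_cell():
    """One deterministic synthetic cell at reduced size for fast tests."""
    spec = SyntheticCellSpec(n_rois=12, boundary=6, T=240, seed=11)
    return spec, generate_cell(spec)


def cwt_direct(x, dt, freqs, omega0=6.0, pad_mode=None):
    """Independent oracle: direct time-domain summation of the wavelet
    correlation integral, W(s, tau) = dt * sum_t x(t) s^(-1/2)
    psi*((t - tau)/s), evaluated on the raw record (optionally on the same
    padded record the FFT route uses, restricted to the original frames)."""
    x = np.asarray(x, dtype=float)
    if pad_mode is not None:
        xp, off = _pad(x, pad_mode)
    else:
        xp, off = x, 0
    T = x.size
    tp = np.arange(xp.size) * dt
    tau = (np.arange(T) + off) * dt
    scales = omega0 / (2 * np.pi * np.asarray(freqs, dtype=float))
    W = np.empty((scales.size, T), dtype=complex)
    for i, s in enumerate(scales):
        arg = (tp[None, :] - tau[:, None]) / s
        W[i] = dt * s ** -0.5 * (np.conj(morlet_mother(arg, omega0))
                                 @ xp.reshape(-1, 1)).ravel()
    return W
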