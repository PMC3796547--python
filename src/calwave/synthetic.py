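"""Seed-reproducible synthetic neurons for end-to-end pipeline testing.

A synthetic cell is a chain of ROIs from growth cone (thin) to soma
(thick) carrying slow calcium-like ratio oscillations.  The generator
emulates the phenomenology the pipeline is built to quantify:

* a thickness profile h(n) rising from cone to soma (sigmoid, linear or
  sigmoid-plus-bump), hence a surface-to-volume profile sv(n) = 2/h(n)
  falling toward the soma;
* amplitude-modulated sinusoidal bursts (raised-cosine envelopes) in the
  0.01-0.1 Hz band of slow calcium oscillations, with per-compartment
  frequency bands (faster at the cone) and burst timing shared within a
  compartment;
* a *coupling* knob per compartment tying burst amplitude to the local
  surface-to-volume ratio: at coupling 1 the amplitude follows sv(n)
  exactly, at coupling 0 it is an independent per-ROI draw.  The coupling
  target is the sv profile standardized within each compartment (affine,
  fixed spread), so equal couplings in the two compartments imply equal
  expected compartment correlations regardless of the reciprocal's shape —
  the property the null-calibration tests rely on;
* two noisy excitation-wavelength channels whose background-subtracted
  ratio recovers the ratio signal, with F380 at the basal frame
  proportional to true thickness, plus an out-of-cell background trace;
* a spatially homogeneous pre-burst baseline (the first ``quiet_s``
  seconds) so geometry estimation is always feasible.

This is declared fixture machinery, not a biophysical calcium model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import RoiTraceSet, compute_ratio, subtract_background
from .geometry import sv_ratio

#: gain applied to F380 per unit thickness at zero calcium ratio excess
_F380_GAIN = 100.0
#: flat out-of-cell background level added to both wavelengths
_BACKGROUND_LEVEL = 20.0


@dataclass(frozen=True)
class BurstParams:
    """Oscillation bursts of one compartment.

    ``fband`` in Hz; ``amplitude`` in ratio units (peak, before coupling
    scaling); ``duration_s`` is the minimum raised-cosine envelope length —
    a burst always contains at least ``min_cycles`` oscillation cycles, so
    low-frequency bursts get proportionally longer envelopes.
    """

    fband: tuple[float, float] = (0.01, 0.1)
    amplitude: float = 0.5
    duration_s: float = 60.0
    count: int = 3
    min_cycles: float = 3.0


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Parameters of one synthetic cell.

    Defaults describe a 30-ROI neuron sampled at 1 Hz for 8 minutes with a
    cone/neurite-soma boundary after ROI 18, strong soma coupling and weak
    cone coupling (the configuration the analysis is meant to detect).
    """

    n_rois: int = 30
    boundary: int = 18
    dt: float = 1.0
    T: int = 480
    thickness_shape: str = "sigmoid"   # sigmoid | linear | bump
    h_cone: float = 1.0
    h_soma: float = 4.0
    bump_height: float = 0.8
    burst_cone: BurstParams = field(default_factory=lambda: BurstParams(
        fband=(0.03, 0.1), amplitude=0.5, duration_s=60.0, count=3))
    burst_soma: BurstParams = field(default_factory=lambda: BurstParams(
        fband=(0.01, 0.05), amplitude=0.5, duration_s=60.0, count=3))
    coupling_soma: float = 0.9
    coupling_cone: float = 0.1
    noise_sd: float = 0.02
    baseline_ratio: float = 1.0
    quiet_s: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 6:
            raise ValueError("need at least 6 ROIs (3 per compartment)")
        if not 3 <= self.boundary <= self.n_rois - 3:
            raise ValueError("boundary must leave >= 3 ROIs per compartment")
        if self.dt <= 0 or self.T < 8:
            raise ValueError("invalid sampling parameters")
        for c in (self.coupling_soma, self.coupling_cone):
            if not 0.0 <= c <= 1.0:
                raise ValueError("couplings must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.thickness_shape not in ("sigmoid", "linear", "bump"):
            raise ValueError(f"unknown thickness shape "
                             f"{self.thickness_shape!r}")


def thickness_profile(spec: SyntheticCellSpec) -> np.ndarray:
    """True thickness h(n), rising cone -> soma; 'bump' adds a local
    Gaussian thickening mid-neurite."""
    n = np.arange(spec.n_rois, dtype=float)
    # sigmoid centered on the compartment boundary so both compartments see
    # part of the transition
    mid = spec.boundary - 0.5
    width = spec.n_rois / 8.0
    if spec.thickness_shape == "linear":
        h = spec.h_cone + (spec.h_soma - spec.h_cone) * n / (spec.n_rois - 1)
    else:
        h = spec.h_cone + (spec.h_soma - spec.h_cone) / (
            1.0 + np.exp(-(n - mid) / width))
        if spec.thickness_shape == "bump":
            h = h + spec.bump_height * np.exp(
                -((n - spec.boundary / 2.0) ** 2) / (2.0 * width ** 2))
    return h


def _standardized_target(x: np.ndarray, center: float = 0.6,
                         spread: float = 0.2) -> np.ndarray:
    """Affine map of x to mean ``center`` and SD ``spread``.

    Being affine it correlates perfectly with x, and fixing the SD gives
    the coupling target the same spread in every compartment regardless of
    the sv profile's curvature — both needed for equal couplings to imply
    symmetric compartment statistics.  Clipped away from zero so burst
    amplitudes stay positive for extreme profiles.
    """
    sd = x.std()
    if sd == 0:
        return np.full_like(x, center)
    z = (x - x.mean()) / sd
    return np.clip(center + spread * z, 0.05, None)


def _burst_envelope(t: np.ndarray, t0: float, duration: float) -> np.ndarray:
    """Raised-cosine (Hann) envelope on [t0, t0 + duration]."""
    phase = (t - t0) / duration
    env = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    env[(phase < 0) | (phase > 1)] = 0.0
    return env


def _compartment_oscillation(t: np.ndarray, bp: BurstParams, quiet_s: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude oscillation pattern shared by a compartment's ROIs."""
    sig = np.zeros_like(t)
    t_end = t[-1] if t.size else 0.0
    for _ in range(bp.count):
        f = rng.uniform(*bp.fband)
        duration = max(bp.duration_s, bp.min_cycles / f)
        latest = max(quiet_s, t_end - duration)
        t0 = rng.uniform(quiet_s, latest) if latest > quiet_s else quiet_s
        phase = rng.uniform(0, 2 * np.pi)
        env = _burst_envelope(t, t0, duration)
        sig += env * np.sin(2.0 * np.pi * f * (t - t0) + phase)
    return sig


def generate_cell(spec: SyntheticCellSpec):
    """Generate one synthetic cell.

    Returns ``(ratio, f340, f380, true_h, labels)`` where the trace sets are
    background-subtracted, ``true_h`` is the generator's thickness profile
    and ``labels`` marks each ROI ``"cone"`` or ``"soma"``.  The raw (noisy,
    background-added) wavelength matrices and the background trace are
    available through :func:`generate_cell_raw` for I/O round-trip tests.
    """
    _, subtracted = generate_cell_raw(spec)
    return subtracted


def generate_cell_raw(spec: SyntheticCellSpec):
    """As :func:`generate_cell` but also returning the raw acquisition:
    ``(raw, (ratio, f340, f380, true_h, labels))`` with ``raw`` a dict of
    the background-included wavelength matrices and the ROI-0 background
    trace."""
    rng = np.random.default_rng(spec.seed)
    N, T = spec.n_rois, spec.T
    t = np.arange(T) * spec.dt
    h = thickness_profile(spec)
    sv = sv_ratio(h)
    b = spec.boundary

    labels = np.array(["cone"] * b + ["soma"] * (N - b))

    # per-compartment coupling targets: sv standardized within compartment,
    # so cone and soma amplitude statistics match under equal couplings
    target = np.empty(N)
    target[:b] = _standardized_target(sv[:b])
    target[b:] = _standardized_target(sv[b:])
    independent = rng.uniform(0.2, 1.0, size=N)
    coupling = np.where(labels == "cone", spec.coupling_cone,
                        spec.coupling_soma)
    mix = coupling * target + (1.0 - coupling) * independent

    osc_cone = _compartment_oscillation(t, spec.burst_cone, spec.quiet_s, rng)
    osc_soma = _compartment_oscillation(t, spec.burst_soma, spec.quiet_s, rng)

    ratio_clean = np.empty((T, N))
    for i in range(N):
        bp = spec.burst_cone if labels[i] == "cone" else spec.burst_soma
        osc = osc_cone if labels[i] == "cone" else osc_soma
        ratio_clean[:, i] = (spec.baseline_ratio
                             + bp.amplitude * mix[i] * osc)

    # two-wavelength acquisition: F380 falls as calcium (ratio) rises, and
    # at the basal ratio F380 is proportional to thickness
    denom = 1.0 + (ratio_clean - spec.baseline_ratio) / (
        1.0 + spec.baseline_ratio)
    denom = np.maximum(denom, 0.1)
    f380_clean = _F380_GAIN * h[None, :] * denom
    f340_clean = ratio_clean * f380_clean

    # additive Gaussian noise per wavelength (before ratioing), with SD
    # proportional to the local fluorescence level (shot-noise-like), so the
    # ratio noise is comparably sized in thin and thick ROIs
    f340_noisy = f340_clean * (1.0 + rng.normal(0, spec.noise_sd, (T, N)))
    f380_noisy = f380_clean * (1.0 + rng.normal(0, spec.noise_sd, (T, N)))
    background = np.full(T, _BACKGROUND_LEVEL) + rng.normal(
        0, spec.noise_sd * _BACKGROUND_LEVEL, T)

    f340_raw = RoiTraceSet(values=f340_noisy + background[:, None],
                           dt=spec.dt, channel="f340")
    f380_raw = RoiTraceSet(values=f380_noisy + background[:, None],
                           dt=spec.dt, channel="f380")
    f340 = subtract_background(f340_raw, background)
    f380 = subtract_background(f380_raw, background)
    ratio = compute_ratio(f340, f380)

    raw = {"f340": f340_raw, "f380": f380_raw, "background": background}
    return raw, (ratio, f340, f380, h, labels)


@dataclass(frozen=True)
class CohortJitter:
    """Per-cell relative jitter applied when generating a cohort."""

    amplitude: float = 0.2
    thickness: float = 0.15
    coupling: float = 0.05


def generate_cohort(n_cells: int, spec_template: SyntheticCellSpec,
                    jitter: CohortJitter | None = None, seed: int = 0):
    """Independent cells from a jittered template; per-cell seeds derive
    deterministically from the master seed.

    Returns a list of ``(spec, cell)`` pairs where ``cell`` is the
    :func:`generate_cell` tuple.
    """
    if n_cells < 2:
        raise ValueError("a cohort needs at least 2 cells")
    if jitter is None:
        jitter = CohortJitter()
    master = np.random.default_rng(np.random.SeedSequence(seed))
    cells = []
    for _ in range(n_cells):
        jit = master.normal(0.0, 1.0, size=4)
        amp_f = math.exp(jitter.amplitude * jit[0])
        th_f = math.exp(jitter.thickness * jit[1])

        def _jc(c, z):
            return float(np.clip(c + jitter.coupling * z, 0.0, 1.0))

        cell_seed = int(master.integers(0, 2 ** 31 - 1))
        spec = replace(
            spec_template,
            h_soma=spec_template.h_cone
            + (spec_template.h_soma - spec_template.h_cone) * th_f,
            burst_cone=replace(spec_template.burst_cone,
                               amplitude=spec_template.burst_cone.amplitude
                               * amp_f),
            burst_soma=replace(spec_template.burst_soma,
                               amplitude=spec_template.burst_soma.amplitude
                               * amp_f),
            coupling_cone=_jc(spec_template.coupling_cone, jit[2]),
            coupling_soma=_jc(spec_template.coupling_soma, jit[3]),
            seed=cell_seed)
        cells.append((spec, generate_cell(spec)))
    return cells
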