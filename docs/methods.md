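# Methods

This note records the models, conventions and numerical choices behind
`calwave`, and what the synthetic tests do and do not establish.

## Signal model and pre-conditioning

A recording is a T×N matrix of per-ROI values sampled every `dt` seconds:
either the ratiometric signal R = F340/F380 (a monotone proxy of cytosolic
calcium) or a single-wavelength intensity. ROIs are identical circles laid
along the cell, labelled 1..N from the growth cone; ROI 0 is drawn outside
the cell and its trace is subtracted frame-by-frame from every ROI (frame-
wise rather than as a scalar so slow lamp drift cancels too). Ratio
denominators are clamped at a configurable ε (default 1e-9) and the number
of clamped cells is reported rather than silently ignored.

Before wavelet analysis each trace is detrended; the default removes the
mean only. Removing the DC level is essential because the analyzed band
starts at a few cycles per recording and an offset otherwise dominates the
largest scales; a `linear` mode is available for recordings with pronounced
monotone drift, and `none` restores the raw trace.

When traces are extracted from an image stack, a pixel belongs to a circular
ROI iff its center lies within the radius (inclusive). This rule is
deterministic, makes masks identical for identical circles, and renders the
extraction exactly linear in the image. The default radius is 3 px,
configurable.

## Continuous wavelet transform

The mother wavelet is the zero-mean–corrected Morlet

ψ(t) = π^(−1/4) e^(−t²/2) (e^(iω₀t) − e^(−ω₀²/2)),

with ω₀ = 6 by default: the standard admissible choice, for which the
correction term is ~1.5e-8 and the identification of scale with spectral
peak frequency, ν = ω₀/(2πs), is accurate to well under 1 %. ω₀ below 5 is
rejected. The family ψ_{s,τ}(t) = s^(−1/2) ψ((t−τ)/s) preserves the L² norm
across scales; the transform is

W(s, τ) = s^(−1/2) ∫ x(t) ψ*((t−τ)/s) dt.

It is evaluated as a Fourier-domain product: with ψ̂ the closed-form
transform of ψ (real-valued), each scale row is the inverse FFT of
X(ω)·√s·ψ̂(sω), costing O(F·T·log T). The correctness of this route is not
assumed: a test compares it against brute-force time-domain summation of
the correlation integral on random traces and requires agreement to 1e-6
relative outside the cone of influence.

Numerical choices:

- **Frequency grid.** Geometric from `fmin` to `fmax` with 16 voices per
  octave by default; defaults `fmin = 4/(T·dt)` (at least ~4 cycles in the
  record) and `fmax = Nyquist/2`.
- **Padding.** Traces are padded to the next power of two ≥ 4T before the
  FFT (reflect by default, zero optional). The generous margin makes the
  circular wrap-around of even the largest analyzed scale negligible
  (envelope tails fall as e^(−d²/2s²)).
- **Cone of influence.** At frame k, a scale is flagged untrustworthy when
  its e-folding time s·√2 exceeds the distance to the nearest record edge.
  The COI is bookkeeping, not a correction: coefficients are computed
  everywhere, but maxima inside the cone are excluded from the activity
  index by default (toggleable).

## Energy and activity indices

From each ROI's scaleogram:

- **Energy density** E(t) = ∫|W(ν,t)|² dν (trapezoid over the grid). On a
  degenerate single-frequency grid the trapezoid is identically zero, so E
  is defined as |W|² there and a warning is logged.
- **Time averages.** The windowed mean of E and its integral (total energy)
  are computed with rectangle weighting, so mean × (n_frames·dt) equals the
  integral exactly — an identity tested to 1e-12.
- **Activity index** I(t) = Σ ν_m·|W(ν_m,t)| over the local maxima ν_m of
  the modulus along the frequency axis at time t. Maxima are found by
  comparing each column with its 3-sample morphological dilation; plateau
  and endpoint artifacts are excluded by requiring a strict drop on at
  least one side. Weighting the modulus (not its square) by ν amplifies the
  high-frequency components that distinguish sharp oscillatory events, which
  is exactly what separates I from the quadratic E. Maxima below a fraction
  (default 0.05) of the column maximum are discarded to reject noise-level
  ridges; setting the fraction to 0 restores the literal unthresholded
  definition. The raw sum is smoothed by a centered moving average (default
  5 s; truncated at the edges), which removes the discontinuities caused by
  ridges appearing and vanishing. Y(n) is the windowed time average of
  I_n(t).

Y is invariant to the trace's DC level, 1-homogeneous in the trace
amplitude, and — on synthetic cohorts — ranks ROIs consistently with the
energy-based alternative (cohort-mean Spearman > 0.8), so conclusions do
not hinge on the particular index.

## Geometry: thickness and surface-to-volume proxy

At a frame where the ratio is spatially homogeneous (spatial CV across ROIs
below 0.05 by default; up to k = 3 best frames averaged, ties to the
earliest), both excitation wavelengths are proportional to the cytosolic
volume under each ROI. With equal ROI areas A, the single-wavelength
intensity is then proportional to local thickness h(n). Approximating the
volume under each ROI as a cylinder whose calcium-exchanging surface is its
top and bottom membrane patches gives S = 2A and V = A·h, hence
sv(n) = 2/h(n). The F380 channel is the default thickness probe (stronger
basal signal at low calcium); F340 is configurable. Only first-order
(flat-membrane) geometry is used. h and sv are arbitrary-unit proxies;
every downstream statistic is invariant to their scale (tested), so no
absolute calibration is needed, and profiles from different cells must not
be mixed without renormalization.

## Compartment statistics

Profiles are max-normalized (x̂ = x / max over ROIs) for display; Pearson
correlations are invariant under positive affine maps of either argument,
so all reported r values are identical for raw and normalized profiles (a
property test and an acceptance check). Per cell, with a user-supplied
boundary (no automatic morphology segmentation) and ≥ 3 ROIs per side:
r_global over all ROIs, r_cn over ROIs 1..boundary, r_s over the rest, each
with compartment-local moments, and D = r_s − r_cn.

Cohort inference bootstraps the per-cell r sets: B = 10,000 resamples with
replacement of the original sample size, percentile CI at 95 % (the CI
method is labelled in every output). The D statistic is bootstrapped on the
per-cell paired differences, preserving pairing. Significance is
cross-checked with a two-sided Wilcoxon signed-rank test: exact enumeration
of the null sign-assignment distribution for up to 25 non-zero differences
(ties share average ranks; zeros handled by the Pratt method — ranked, then
dropped from the signed sum), continuity-corrected normal approximation
above. All randomness flows from one integer seed through NumPy
SeedSequence spawning, so identical seeds give bit-identical resamples.

## Synthetic cells

The generator emulates the phenomenology the pipeline must detect, not
calcium biophysics (no channel/pump/buffer modeling, no CICR):

- **Geometry.** h(n) rises from cone (1.0 a.u.) to soma (4.0 a.u.);
  sigmoid by default (centered on the compartment boundary so both
  compartments see a gradient), with linear and bump variants.
- **Oscillations.** Amplitude-modulated sinusoidal bursts under raised-
  cosine envelopes, in compartment-specific bands (cone 0.03–0.1 Hz, soma
  0.01–0.05 Hz — faster events at the cone, matching slow calcium
  oscillation timescales), three bursts per compartment per recording.
  Every burst contains at least 3 cycles: its envelope stretches to
  3/f when the drawn frequency is low, since a sub-cycle "burst" has
  essentially no in-band spectral content and would not be an oscillation
  at all. Burst timing is shared within a compartment (events span
  neighboring ROIs, as in real recordings), amplitudes vary per ROI.
- **Coupling.** Per-ROI burst amplitude = a·(c·ŝv(n) + (1−c)·u_n) with
  compartment coupling c, independent draws u_n ~ U(0.2, 1), and ŝv the sv
  profile standardized *within each compartment* to mean 0.6 and SD 0.2
  (clipped away from zero). An affine target correlates perfectly with sv
  (so full coupling means r = 1 exactly, noise aside), and fixing the SD
  gives the target the same spread in both compartments whatever the
  curvature of 2/h — coupling to raw or min–max-scaled sv would build a
  spurious compartment asymmetry into the null through that curvature, and
  the null-calibration test would then measure the generator, not the
  pipeline.
- **Acquisition.** The defaults describe a 30-ROI neuron at dt = 1 s for
  480 frames (8 min), boundary after ROI 18. F380 is thickness times a
  factor decreasing in the ratio; F340 = R·F380; both carry multiplicative
  Gaussian noise (SD 2 % of the local level — shot-noise-like, so ratio
  noise is comparable in thin and thick ROIs) and a flat out-of-cell
  background with its own noisy ROI-0 trace. The first 20 s are burst-free,
  planting homogeneous frames so geometry estimation always succeeds.

What passing the synthetic tests shows: the transform, indices, geometry
proxy and inference recover planted couplings and stay calibrated under the
null, end to end. What they do not show: robustness to motion, focus drift,
photobleaching, indicator saturation, or spatially propagating waves — none
of which the generator emulates (registration and bleach correction are
explicitly out of scope).

## Problem sizes used in the shipped checks

The automated checks run cohorts of 20 cells at the default cell size and
150 null replicates (the binomial SD of an empirical coverage estimated
from 150 draws is about 2 %, small against the 5-point margin between the
nominal 95 % level and the 90 % bound being checked); the CWT oracle uses
10 random traces of 256 frames on a
3-octave × 8-voice grid, zero-padded so the FFT and brute-force routes see
the same record. These sizes give stable statistics (bootstrap Monte-Carlo
error well below the tested tolerances) at a few minutes of single-CPU
runtime.

## Known limitations

- The activity index is a heuristic reduction; its absolute scale depends
  on the frequency grid and smoothing window, so only comparisons within a
  run are meaningful.
- Compartment boundaries are user-supplied; mis-specification mixes
  compartments and attenuates D.
- The homogeneity criterion assumes at least one spatially uniform frame;
  recordings that oscillate everywhere throughout need the CV threshold
  raised, at the cost of a noisier thickness estimate.
- Thickness from single-wavelength fluorescence inherits all Fura-2
  caveats: it proxies the cytosol accessible to the dye, net of organelles.
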