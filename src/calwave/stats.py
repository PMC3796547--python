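"""Compartment-split correlation statistics and cohort-level inference.

Per cell: the activity profile Y(n) and the surface-to-volume profile sv(n)
are compared by Pearson product-moment correlation, globally and split at a
user-supplied compartment boundary into a growth-cone/neurite coefficient
``r_cn`` (ROIs up to the boundary) and a soma coefficient ``r_s`` (the
rest), with compartment-local means and standard deviations.  The per-cell
difference ``D = r_s - r_cn`` carries the compartment contrast while
respecting the pairing of the two samples.

Across cells: bootstrap resampling of the per-cell coefficients yields
sampling distributions of their means and percentile confidence intervals;
a Wilcoxon signed-rank test (exact enumeration for small cohorts) checks
the significance of the mean paired difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

MAX_EXACT_WILCOXON = 25


@dataclass(frozen=True)
class CellCorrelation:
    """Global and compartment-split Pearson correlations for one cell."""

    r_global: float
    r_cn: float
    r_s: float
    boundary: int
    n_cn: int
    n_s: int
    cell_id: str = ""

    @property
    def D(self) -> float:
        """Per-cell difference statistic r_s - r_cn."""
        return self.r_s - self.r_cn


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap sampling distribution of a sample mean."""

    statistic_name: str
    sample: np.ndarray
    B: int
    resample_size: int
    means: np.ndarray
    ci_level: float
    ci: tuple[float, float]
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.means))

    @property
    def sd(self) -> float:
        """Bootstrap SD of the mean (estimates the SEM of the sample)."""
        return float(np.std(self.means, ddof=1))

    def histogram(self, bins: int = 40,
                  range_: tuple[float, float] = (-1.0, 1.0)) -> pd.DataFrame:
        counts, edges = np.histogram(self.means, bins=bins, range=range_)
        return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                             "count": counts})


def normalize_profile(x) -> np.ndarray:
    """Adimensional profile x / max(x); the max runs over all ROIs, so the
    result lies in [0, 1] with maximum exactly 1."""
    x = np.asarray(x, dtype=float)
    m = x.max()
    if m <= 0:
        raise ValueError("profile maximum must be positive to normalize")
    return x / m


def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    return float(np.corrcoef(x, y)[0, 1])


def compartment_correlations(Y, sv, boundary: int,
                             cell_id: str = "") -> CellCorrelation:
    """Global and compartment-split correlations between activity and
    surface-to-volume profiles.

    ``boundary`` is the 1-based ROI index of the last cone/neurite ROI:
    ``r_cn`` runs over ROIs ``1..boundary``, ``r_s`` over the rest.  Each
    compartment needs at least 3 ROIs.  The result is invariant to positive
    rescaling (hence to max-normalization) of either profile.
    """
    Y = np.asarray(Y, dtype=float)
    sv = np.asarray(sv, dtype=float)
    if Y.shape != sv.shape:
        raise ValueError("profiles differ in length")
    N = Y.size
    n_cn = int(boundary)
    n_s = N - n_cn
    if n_cn < 3 or n_s < 3:
        raise ValueError("each compartment needs at least 3 ROIs "
                         f"(got {n_cn} and {n_s})")
    return CellCorrelation(
        r_global=pearson(Y, sv),
        r_cn=pearson(Y[:n_cn], sv[:n_cn]),
        r_s=pearson(Y[n_cn:], sv[n_cn:]),
        boundary=n_cn, n_cn=n_cn, n_s=n_s, cell_id=cell_id)


def bootstrap_mean(sample, B: int = 10_000, resample_size: int | None = None,
                   seed: int = 0, ci_level: float = 0.95,
                   statistic_name: str = "mean") -> BootstrapResult:
    """Bootstrap distribution of the sample mean with a percentile CI.

    ``B`` resamples with replacement of ``resample_size`` (default: the
    sample size); fully reproducible from the integer seed.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 2:
        raise ValueError("need at least 2 observations to bootstrap")
    if B < 100:
        raise ValueError("B must be at least 100")
    if resample_size is None:
        resample_size = sample.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, sample.size, size=(B, resample_size))
    means = sample[idx].mean(axis=1)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapResult(statistic_name=statistic_name, sample=sample,
                           B=B, resample_size=resample_size, means=means,
                           ci_level=ci_level, ci=(float(lo), float(hi)),
                           seed=seed)


def wilcoxon_signed_rank(diffs, exact_max: int = MAX_EXACT_WILCOXON) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zeros are handled by the Pratt method (they enter the ranking of the
    absolute values and are then dropped from the signed sum); ties share
    average ranks.  For up to ``exact_max`` non-zero differences the null
    distribution is enumerated exactly over all sign assignments; larger
    samples fall back to the continuity-corrected normal approximation.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("empty sample of differences")
    if np.all(d == 0):
        raise ValueError("all paired differences are zero")
    ranks = scipy.stats.rankdata(np.abs(d))  # zeros included (Pratt)
    nz = d != 0
    r = ranks[nz]
    m = r.size
    if m > exact_max:
        return float(scipy.stats.wilcoxon(
            d, zero_method="pratt", correction=True,
            alternative="two-sided", mode="approx").pvalue)
    # exact null: each non-zero rank is + or - with prob 1/2.  Average ranks
    # are half-integers, so doubling makes every rank an integer and the
    # null distribution of 2*W+ is a subset-sum count built by convolution.
    r2 = np.rint(2.0 * r).astype(np.int64)
    w2 = int(np.rint(2.0 * r[d[nz] > 0].sum()))
    counts = np.zeros(int(r2.sum()) + 1)
    counts[0] = 1.0
    for ri in r2:
        counts[ri:] += counts[: counts.size - ri].copy()
    n_tot = 2.0 ** m
    p_le = counts[: w2 + 1].sum() / n_tot
    p_ge = counts[w2:].sum() / n_tot
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def paired_difference_test(r_s_sample, r_cn_sample, B: int = 10_000,
                           seed: int = 0, ci_level: float = 0.95
                           ) -> tuple[BootstrapResult, float]:
    """Inference on the mean compartment contrast D = r_s - r_cn.

    Per-cell differences keep the pairing of the two samples; returns the
    bootstrap of mean(D) with a percentile CI and the two-sided Wilcoxon
    signed-rank p-value.
    """
    r_s = np.asarray(r_s_sample, dtype=float)
    r_cn = np.asarray(r_cn_sample, dtype=float)
    if r_s.shape != r_cn.shape:
        raise ValueError("paired samples differ in length")
    d = r_s - r_cn
    boot = bootstrap_mean(d, B=B, seed=seed, ci_level=ci_level,
                          statistic_name="D")
    return boot, wilcoxon_signed_rank(d)


def cohort_summary(cells: list[CellCorrelation], B: int = 10_000,
                   seed: int = 0, ci_level: float = 0.95) -> dict:
    """Bootstrap the three per-cell correlation sets and the paired D.

    Returns a dict with ``r_global``, ``r_cn``, ``r_s`` BootstrapResults,
    the ``D`` BootstrapResult, ``wilcoxon_p``, and a per-cell table.
    Sub-seeds are derived deterministically from ``seed``.
    """
    if len(cells) < 2:
        raise ValueError("cohort needs at least 2 cells")
    table = pd.DataFrame({
        "cell": [c.cell_id for c in cells],
        "r_global": [c.r_global for c in cells],
        "r_cn": [c.r_cn for c in cells],
        "r_s": [c.r_s for c in cells],
        "D": [c.D for c in cells],
    })
    ss = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    out: dict = {"cells": table}
    for name, sd in zip(("r_global", "r_cn", "r_s"), sub):
        out[name] = bootstrap_mean(table[name].to_numpy(), B=B, seed=sd,
                                   ci_level=ci_level, statistic_name=name)
    boot_D, p = paired_difference_test(table["r_s"].to_numpy(),
                                       table["r_cn"].to_numpy(),
                                       B=B, seed=sub[3], ci_level=ci_level)
    out["D"] = boot_D
    out["wilcoxon_p"] = p
    return out
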