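"""Matplotlib renderings of the standard figures: space-time activity maps,
spatial profiles of activity vs surface-to-volume ratio, and bootstrap
histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .activity import ActivityProfile
from .geometry import GeometryProfile
from .stats import BootstrapResult, normalize_profile


def plot_activity_map(profile: ActivityProfile, path, which: str = "I"):
    """Space-time map of the activity index (or energy density): time on the
    horizontal axis, ROI position (cone at the bottom) on the vertical."""
    data = profile.I_map if which == "I" else profile.E_map
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.pcolormesh(profile.times, profile.roi_ids, data,
                       shading="nearest", cmap="jet")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ROI n (growth cone → soma)")
    label = "activity index I" if which == "I" else "energy density E"
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_spatial_profile(profile: ActivityProfile,
                         geometry: GeometryProfile | None, path):
    """Y(n) along the cell, optionally with the normalized sv(n) overlay."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.roi_ids, normalize_profile(profile.Y), "o-", color="tab:blue",
            label=r"$\hat{Y}(n)$ activity")
    if geometry is not None:
        ax.plot(geometry.roi_ids, normalize_profile(geometry.sv), "s-",
                color="tab:green", label=r"$\hat{sv}(n)$ surface/volume")
    ax.set_xlabel("ROI n (growth cone → soma)")
    ax.set_ylabel("normalized index")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_thickness(geometry: GeometryProfile, path):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(geometry.roi_ids, geometry.h, "o-", color="tab:red")
    ax.set_xlabel("ROI n (growth cone → soma)")
    ax.set_ylabel("thickness proxy h(n) (a.u.)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bootstrap_hists(results: list[BootstrapResult], path,
                         bins: int = 40):
    """Overlaid bootstrap-mean histograms over [-1, 1]."""
    fig, ax = plt.subplots(figsize=(6, 4))
    lo = min(-1.0, min(r.means.min() for r in results))
    hi = max(1.0, max(r.means.max() for r in results))
    edges = np.linspace(lo, hi, bins + 1)
    for r in results:
        ax.hist(r.means, bins=edges, alpha=0.5, label=r.statistic_name)
    ax.set_xlabel("bootstrap mean")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
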