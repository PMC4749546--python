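"""Figure helpers (matplotlib, Agg-safe): kymographs, profiles, alignments."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .activity import PeriEventProfile, Correlogram
from .motility import Kymograph
from .spatial import BranchProfile


def plot_kymograph(kymo: Kymograph, path=None, ax=None, cmap="gray"):
    """Space (µm, vertical) × time (s, horizontal) intensity map."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    extent = (0, kymo.n_frames * kymo.frame_interval, kymo.path_length, 0)
    ax.imshow(kymo.data, aspect="auto", extent=extent, cmap=cmap)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("position (µm)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_branch_profile(profile: BranchProfile, path=None, ax=None):
    """Normalized mitochondrial density vs distance from branch points."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.step(profile.bin_edges[:-1], profile.normalized, where="post")
    ax.axhline(1.0, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("distance from branch point (µm)")
    ax.set_ylabel("normalized density")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_peri_event(profile: PeriEventProfile, path=None, ax=None):
    """Instantaneous motile fraction aligned on event onsets (mean ± SEM)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    m, s = profile.mean, profile.sem
    ax.plot(profile.lag_centers, m, c="k")
    ax.fill_between(profile.lag_centers, m - s, m + s, alpha=0.3, color="k")
    ax.axvline(0.0, ls="--", c="g", lw=0.8)
    ax.set_xlabel("time from event onset (s)")
    ax.set_ylabel("instantaneous motile fraction")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_correlogram(cg: Correlogram, path=None, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.bar(cg.lags, cg.values, width=cg.bin_s * 0.9, color="k")
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("correlation")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
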