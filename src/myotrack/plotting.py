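"""Matplotlib views of trajectories, fits and summaries.

Each function takes an ``ax`` keyword (created on demand) and returns
it, so the plots compose into panels.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .core import Trajectory
from .ihmm import InferenceResult
from .stepfit import TwoStateStepResults
from .summarize import MixtureFit1D, PeakSummary


def _ax(ax=None):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_trajectory(traj: Trajectory, ax=None, max_points: int = 20_000):
    """Position vs time (ms); ground-truth binding frames highlighted."""
    ax = _ax(ax)
    n = min(len(traj), max_points)
    t_ms = traj.times[:n] / 1000.0
    ax.plot(t_ms, traj.positions[:n], lw=0.3, color="0.4")
    if traj.labels is not None:
        bound = traj.labels[:n] > 0
        ax.plot(t_ms[bound], traj.positions[:n][bound], ".", ms=1.5, color="crimson")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("position (nm)")
    return ax


def plot_step_fit(res: TwoStateStepResults, traj: Trajectory, ax=None):
    """Trajectory with the two fitted state means and the Viterbi path."""
    ax = plot_trajectory(traj, ax=ax)
    t_ms = traj.times / 1000.0
    path_mean = np.where(res.state_path == 0, res.detached_mean, res.bound_mean)
    ax.plot(t_ms, path_mean, lw=1.2, color="k")
    for mean, label in ((res.detached_mean, "detached"), (res.bound_mean, "bound")):
        ax.axhline(mean, ls="--", lw=0.8, color="steelblue")
        ax.annotate(f"{label} {mean:.1f} nm", (t_ms[-1], mean), fontsize=8)
    ax.set_title(f"step = {res.step:.1f} nm")
    return ax


def plot_inference(res: InferenceResult, traj: Trajectory, ax=None):
    """Trajectory overlaid with the inferred detached/binding means."""
    ax = plot_trajectory(traj, ax=ax)
    t_ms = traj.times / 1000.0
    labels = res.segments.to_labels()
    means = np.concatenate(([res.detached_mean], [s.mean for s in res.binding_states]))
    ax.plot(t_ms, means[labels], lw=1.0, color="k")
    ax.axhline(res.detached_mean, ls=":", color="c", lw=1.0)
    for s in res.binding_states:
        ax.axhline(s.mean, ls=":", color="m", lw=0.8)
    return ax


def plot_position_histogram(
    positions: np.ndarray,
    mixture: Optional[MixtureFit1D] = None,
    bin_width: float = 1.0,
    ax=None,
):
    """Pooled binding-position histogram with the mixture overlay."""
    ax = _ax(ax)
    positions = np.asarray(positions, float)
    lo = np.floor(positions.min()) - 2
    hi = np.ceil(positions.max()) + 2
    bins = np.arange(lo, hi + bin_width, bin_width)
    ax.hist(positions, bins=bins, color="0.7", edgecolor="0.4")
    if mixture is not None:
        grid = np.linspace(lo, hi, 500)
        dens = np.zeros_like(grid)
        for m, s, w in zip(mixture.means, mixture.sds, mixture.weights):
            dens += w * np.exp(-0.5 * ((grid - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        ax.plot(grid, dens * len(positions) * bin_width, color="crimson", lw=1.2)
        for m in mixture.means:
            ax.axvline(m, ls=":", lw=0.6, color="crimson")
    ax.set_xlabel("binding position relative to detached mean (nm)")
    ax.set_ylabel("count")
    return ax


def plot_peak_summary(peaks: Sequence[PeakSummary], ax=None):
    """Access ratio (left axis) and dwell time (right axis) vs position."""
    ax = _ax(ax)
    pos = [p.position for p in peaks]
    ax.bar(pos, [p.access_ratio for p in peaks], width=3.0, color="steelblue",
           yerr=[p.access_sd for p in peaks], label="access ratio")
    ax.set_xlabel("binding position (nm)")
    ax.set_ylabel("access ratio", color="steelblue")
    ax2 = ax.twinx()
    kept = [p for p in peaks if not p.excluded]
    ax2.errorbar(
        [p.position for p in kept], [p.dwell for p in kept],
        yerr=[p.dwell_se for p in kept], fmt="o-", color="m", label="dwell",
    )
    ax2.set_ylabel("dwell time (us)", color="m")
    return ax


def plot_rate_line(fit, ax=None):
    """Per-concentration ATP-binding rates with the fitted line."""
    ax = _ax(ax)
    if fit.points is not None:
        ax.errorbar(fit.points[:, 0], fit.points[:, 1], yerr=fit.points[:, 2],
                    fmt="o", color="k")
        grid = np.linspace(0, fit.points[:, 0].max() * 1.05, 50)
    else:
        grid = np.linspace(0, 4000, 50)
    ax.plot(grid, fit.slope * grid + fit.intercept, color="crimson",
            label=f"{fit.slope:.4f} [ATP] + {fit.intercept:.2f}")
    ax.set_xlabel("[ATP] (nM)")
    ax.set_ylabel("ATP binding rate (s$^{-1}$)")
    ax.legend(fontsize=8)
    return ax
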