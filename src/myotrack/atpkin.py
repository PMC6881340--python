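"""ATP-binding kinetics from fluorescent-ATP traces and binding dwells.

A Cy3-ATP spike train reports single ATP binding events at a myosin
head: the dark gap between spikes is the ATP waiting time.  Waiting
times are fitted with a double-exponential survival model whose slower
rate is the ATP binding rate (the faster component reflects events
within one ATPase cycle); Cy3-ATP rates are converted to unlabelled-ATP
rates by a fixed factor (2.8 by default).  Plotting the rate against
[ATP] and fitting a weighted line gives the second-order binding
constant (slope) and the basal rate (intercept).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .core import FluorescenceTrace, ImageStack


@dataclass
class EventList:
    """Detected fluorescence spikes (ATP binding events)."""

    starts: np.ndarray  # s
    durations: np.ndarray  # s (on-times)
    amplitudes: np.ndarray  # counts above baseline
    overlap_warning: bool = False

    def __post_init__(self) -> None:
        order = np.argsort(self.starts)
        self.starts = np.asarray(self.starts, float)[order]
        self.durations = np.asarray(self.durations, float)[order]
        self.amplitudes = np.asarray(self.amplitudes, float)[order]
        ends = self.starts + self.durations
        if np.any(ends[:-1] > self.starts[1:] + 1e-12):
            raise ValueError("events must be non-overlapping")

    def __len__(self) -> int:
        return len(self.starts)

    def waiting_times(self) -> np.ndarray:
        """Dark gaps between consecutive events (start-to-start minus
        on-time), in seconds."""
        if len(self) < 2:
            return np.empty(0)
        return self.starts[1:] - (self.starts[:-1] + self.durations[:-1])


def extract_trace(
    stack: ImageStack, center: Tuple[int, int], roi: int = 7
) -> FluorescenceTrace:
    """ROI-averaged, perimeter-background-corrected intensity time course.

    Per frame: mean of the ``roi x roi`` window centred at ``center``
    (pixel coordinates, (x, y)) minus the mean of the one-pixel
    perimeter ring around the ROI.
    """
    half = roi // 2
    cx, cy = int(round(center[0])), int(round(center[1]))
    _, ny, nx = stack.frames.shape
    if not (half + 1 <= cx < nx - half - 1 and half + 1 <= cy < ny - half - 1):
        raise ValueError("ROI (plus perimeter ring) out of bounds")
    inner = stack.frames[:, cy - half : cy + half + 1, cx - half : cx + half + 1]
    outer = stack.frames[
        :, cy - half - 1 : cy + half + 2, cx - half - 1 : cx + half + 2
    ]
    ring_sum = outer.sum(axis=(1, 2)) - inner.sum(axis=(1, 2))
    ring_n = outer.shape[1] * outer.shape[2] - roi * roi
    corrected = inner.mean(axis=(1, 2)) - ring_sum / ring_n
    frame_rate = 1e6 / stack.frame_interval
    times = (np.arange(len(corrected)) + 0.5) / frame_rate
    return FluorescenceTrace(
        times=times, intensity=corrected, frame_rate=frame_rate, roi=roi
    )


def detect_spikes(
    trace: FluorescenceTrace, threshold_sd: float = 3.0, min_frames: int = 2
) -> EventList:
    """Threshold-based spike detection.

    Frames above ``baseline + threshold_sd * noise`` — baseline the
    median intensity, noise the MAD-based robust SD — for at least
    ``min_frames`` consecutive frames form events.  Deterministic.
    """
    if len(trace) < 100:
        raise ValueError("trace must have at least 100 frames")
    y = trace.intensity
    baseline = float(np.median(y))
    mad = float(np.median(np.abs(y - baseline)))
    noise = 1.4826 * mad if mad > 0 else float(y.std())
    if noise == 0:
        return EventList(np.empty(0), np.empty(0), np.empty(0))
    above = y > baseline + threshold_sd * noise
    dt = 1.0 / trace.frame_rate
    starts, durations, amps = [], [], []
    i = 0
    n = len(y)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_frames:
                starts.append(trace.times[i] - 0.5 * dt)
                durations.append((j - i) * dt)
                amps.append(float(y[i:j].mean() - baseline))
            i = j
        else:
            i += 1
    return EventList(
        starts=np.asarray(starts),
        durations=np.asarray(durations),
        amplitudes=np.asarray(amps),
        overlap_warning=trace.overlap_warning,
    )


@dataclass
class WaitingTimeFit:
    """Double-exponential waiting-time (survival) fit.

    ``slow_rate`` is designated the ATP binding rate (it closes the
    ATPase cycle).  When the two rates are within 10% the fit collapses
    to a flagged single exponential.
    """

    slow_rate: float  # s^-1  (ATP binding rate)
    fast_rate: float  # s^-1
    slow_se: float
    fast_se: float
    slow_weight: float
    single_exponential: bool = False

    @property
    def atp_binding_rate(self) -> float:
        return self.slow_rate


def fit_waiting_times(waits: Sequence[float]) -> WaitingTimeFit:
    """Fit the waiting-time survival curve with a two-exponential mixture."""
    w = np.asarray(waits, dtype=float)
    w = w[w > 0]
    if len(w) < 20:
        raise ValueError("need at least 20 waiting times")
    ws = np.sort(w)
    surv = 1.0 - np.arange(1, len(ws) + 1) / len(ws)
    # evaluate on log-spaced support to weight the tail sensibly
    grid = np.unique(
        np.searchsorted(ws, np.geomspace(ws[0], ws[-1], min(200, len(ws))))
    )
    grid = grid[grid < len(ws)]
    t_fit, s_fit = ws[grid], surv[grid]
    # initialise from a 2-means split of log waits
    logw = np.log(w)
    thr = np.median(logw)
    lo, hi = w[logw <= thr], w[logw > thr]
    k_fast = 1.0 / max(lo.mean(), 1e-12)
    k_slow = 1.0 / max(hi.mean(), 1e-12)

    def model(p):
        a, k1, k2 = p
        return a * np.exp(-k1 * t_fit) + (1 - a) * np.exp(-k2 * t_fit) - s_fit

    fallback = False
    try:
        res = least_squares(
            model,
            [0.5, k_slow, k_fast],
            bounds=([0.0, 1e-12, 1e-12], [1.0, np.inf, np.inf]),
            max_nfev=5000,
        )
        a, k1, k2 = res.x
        ok = res.success
    except Exception:
        ok = False
        a, k1, k2 = 0.5, k_slow, k_fast
    if ok:
        slow, fast = sorted((k1, k2))
        a_slow = a if k1 < k2 else 1 - a
        # near-degenerate rates, or a vanishing component, mean the data
        # carry no evidence of a second timescale
        if (fast - slow) / fast < 0.10 or min(a_slow, 1 - a_slow) < 0.05:
            fallback = True
    else:
        fallback = True
    if fallback:
        rate = 1.0 / w.mean()
        se = rate / np.sqrt(len(w))
        return WaitingTimeFit(
            slow_rate=rate,
            fast_rate=rate,
            slow_se=se,
            fast_se=se,
            slow_weight=1.0,
            single_exponential=True,
        )
    # SEs from the Jacobian at the solution
    try:
        J = res.jac
        dof = max(len(t_fit) - 3, 1)
        cov = np.linalg.pinv(J.T @ J) * (res.fun @ res.fun) / dof
        ses = np.sqrt(np.diag(cov))
        se_map = {k1: ses[1], k2: ses[2]}
        slow_se, fast_se = se_map[min(k1, k2)], se_map[max(k1, k2)]
    except Exception:
        slow_se = fast_se = np.nan
    return WaitingTimeFit(
        slow_rate=float(slow),
        fast_rate=float(fast),
        slow_se=float(slow_se),
        fast_se=float(fast_se),
        slow_weight=float(a_slow),
    )


def correct_cy3_rate(rate: float, factor: float = 2.8) -> float:
    """Convert a Cy3-ATP binding rate to the unlabelled-ATP rate."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if factor <= 0:
        raise ValueError("factor must be positive")
    return rate * factor


@dataclass
class RateFit:
    """ATP-binding-rate line: rate = slope * [ATP] + intercept."""

    slope: float  # s^-1 nM^-1
    intercept: float  # s^-1
    slope_se: float = 0.0
    intercept_se: float = 0.0
    points: Optional[np.ndarray] = None  # (n, 3): conc nM, rate s^-1, sd

    def predict(self, atp_nM: float) -> float:
        return self.slope * atp_nM + self.intercept

    def plot(self, ax=None):
        """Per-concentration rates with the fitted line."""
        from .plotting import plot_rate_line

        return plot_rate_line(self, ax=ax)

    def summary(self) -> str:
        return (
            "ATP-binding rate line\n"
            "---------------------\n"
            f"slope     {self.slope:.4g} +/- {self.slope_se:.2g} s^-1 nM^-1\n"
            f"intercept {self.intercept:.4g} +/- {self.intercept_se:.2g} s^-1"
        )


def fit_rate_line(points: Sequence[Tuple[float, float, float]]) -> RateFit:
    """Weighted least-squares line through (concentration, rate, sd) points.

    Weights are ``1 / sd^2`` when every sd is positive, otherwise
    ordinary least squares.  Requires at least two distinct
    concentrations.
    """
    import statsmodels.api as sm

    arr = np.array(
        [(p[0], p[1], p[2] if len(p) > 2 else 0.0) for p in points], dtype=float
    )
    if len(np.unique(arr[:, 0])) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    X = sm.add_constant(arr[:, 0])
    if np.all(arr[:, 2] > 0):
        model = sm.WLS(arr[:, 1], X, weights=1.0 / arr[:, 2] ** 2)
    else:
        model = sm.OLS(arr[:, 1], X)
    res = model.fit()
    return RateFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        points=arr,
    )


def rate_from_binding_dwells(dwells_s: Sequence[float]) -> Tuple[float, float]:
    """ATP-binding rate from strong-binding dwell times (seconds).

    Dwells are fitted by a single-exponential cumulative frequency plot;
    the rate is ``1 / tau`` with its standard error propagated.
    """
    d = np.asarray(dwells_s, dtype=float)
    if len(d) < 20:
        raise ValueError("need at least 20 dwells")
    ds = np.sort(d)
    ecdf = np.arange(1, len(ds) + 1) / len(ds)

    def model(t, tau):
        return 1.0 - np.exp(-t / tau)

    popt, pcov = curve_fit(model, ds, ecdf, p0=[ds.mean()], maxfev=10_000)
    tau = float(popt[0])
    tau_se = float(np.sqrt(pcov[0, 0]))
    return 1.0 / tau, tau_se / tau**2
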