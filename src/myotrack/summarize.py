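"""Pooling repeated inferences into binding-position peaks and dwell times.

Across many independently seeded iHMM chains, the retained binding-state
positions (relative to the inferred detached mean) pile up at the true
actin-binding positions.  This module fits that pooled distribution with a
K-component Gaussian mixture, assigns each inferred state to the peak
whose +/-1 SD window contains it, and summarises per-peak accessibility
(fraction of binding events) and dwell time (left-truncated exponential
fit).  It also provides the weak-to-strong dwell-prolongation ratio and
the two-step powerstroke decomposition arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .atpkin import RateFit
from .ihmm import InferenceResult


@dataclass
class MixtureFit1D:
    """K-component 1D Gaussian mixture (means sorted ascending)."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    n_samples: int
    bin_width: float = 1.0  # display-histogram bin width (nm); fit uses raw samples

    def plot(self, positions, ax=None):
        """Histogram of the pooled positions with the fit overlaid."""
        from .plotting import plot_position_histogram

        return plot_position_histogram(
            positions, mixture=self, bin_width=self.bin_width, ax=ax
        )

    def summary(self) -> str:
        lines = ["1D Gaussian mixture fit", "-----------------------"]
        for m, s, w in zip(self.means, self.sds, self.weights):
            lines.append(f"  mean {m:+8.2f} nm   sd {s:5.2f} nm   weight {w:.3f}")
        lines.append(f"log-likelihood {self.log_likelihood:.1f}  (n = {self.n_samples})")
        return "\n".join(lines)


def fit_gaussian_mixture_1d(
    samples: Sequence[float], K: int, seed: int = 0, n_init: int = 10
) -> MixtureFit1D:
    """Maximum-likelihood K-component Gaussian mixture by EM.

    Uses k-means++-style seeded initialisation with ``n_init`` restarts,
    keeping the best likelihood; components are reported in ascending
    order of mean.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(samples, dtype=float).reshape(-1, 1)
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(x) < 10 * K:
        raise ValueError(f"need at least {10 * K} samples for K = {K}")
    if np.ptp(x) == 0 and K > 1:
        raise ValueError("all samples identical; cannot fit K > 1 components")
    gm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        n_init=n_init,
        init_params="k-means++",
        random_state=seed,
        max_iter=500,
        reg_covar=1e-6,
    ).fit(x)
    order = np.argsort(gm.means_.ravel())
    return MixtureFit1D(
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.ravel()[order]),
        weights=gm.weights_[order],
        log_likelihood=float(gm.score(x) * len(x)),
        n_samples=len(x),
    )


@dataclass
class DwellFit:
    """Left-truncated exponential dwell-time fit.

    ``tau`` is the time constant from a least-squares fit of the
    empirical CDF to ``1 - A * exp(-(t - truncation) / tau)``; the free
    amplitude absorbs the point mass that frame quantisation puts at the
    observability floor, so the fit tracks the tail decay.  ``tau_mle``
    is the closed-form cross-check ``mean(dwells) - truncation``.
    """

    tau: float
    se: float
    amplitude: float
    tau_mle: float
    n: int
    truncation: float


def fit_exponential_dwell(
    dwells: Sequence[float], truncation: float = 40.0
) -> DwellFit:
    """Fit dwell times with a left-truncated single-exponential CDF."""
    d = np.asarray(dwells, dtype=float)
    n = len(d)
    if n < 10:
        raise ValueError("need at least 10 dwells")
    if np.any(d < truncation):
        raise ValueError("all dwells must be >= the truncation point")
    # collapse ties (frame-quantised dwells produce many): evaluate the
    # right-continuous ECDF at unique values, weighted by multiplicity
    ts, mult = np.unique(d, return_counts=True)
    ecdf = np.cumsum(mult) / n
    w = np.sqrt(mult.astype(float))
    tau0 = max(float(d.mean() - truncation), truncation * 0.1, 1e-6)

    from scipy.optimize import least_squares

    def resid(p):
        tau, amp = p
        return w * (1.0 - amp * np.exp(-(ts - truncation) / tau) - ecdf)

    res = least_squares(
        resid, [tau0, 1.0], bounds=([1e-9, 1e-6], [np.inf, 1.0]), max_nfev=10_000
    )
    tau, amp = res.x
    # weighted-LS parameter covariance; residual dof counts all n points
    try:
        J = res.jac
        s2 = 2.0 * res.cost / max(n - 2, 1)
        cov = np.linalg.pinv(J.T @ J) * s2
        se = float(np.sqrt(cov[0, 0]))
    except Exception:
        se = np.nan
    return DwellFit(
        tau=float(tau),
        se=se,
        amplitude=float(amp),
        tau_mle=float(d.mean() - truncation),
        n=n,
        truncation=truncation,
    )


@dataclass
class PeakSummary:
    """One binding-position peak pooled over chains."""

    position: float  # nm, mixture mean
    position_sd: float  # nm, mixture SD
    access_ratio: float  # mean across chains
    access_sd: float  # SD across chains
    dwell: Optional[float]  # us, pooled CDF fit (None when excluded)
    dwell_se: Optional[float]
    n_states: int  # inferred states assigned to this peak
    n_events: int  # pooled binding events
    excluded: bool = False
    reason: str = ""

    def summary(self) -> str:
        dwell = f"{self.dwell:7.0f} +/- {self.dwell_se:.0f} us" if self.dwell else "-"
        tag = f"  [excluded: {self.reason}]" if self.excluded else ""
        return (
            f"peak {self.position:+7.1f} nm (SD {self.position_sd:.1f})  "
            f"access {self.access_ratio:.3f} +/- {self.access_sd:.3f}  "
            f"dwell {dwell}{tag}"
        )


def summarize_peaks(
    results: Sequence[InferenceResult],
    mixture: MixtureFit1D,
    access_floor: float = 0.02,
    truncation: float = 40.0,
    point_fraction: bool = False,
) -> List[PeakSummary]:
    """Assign inferred states to mixture peaks and summarise access/dwell.

    A retained state belongs to the peak whose mean +/- 1 SD window
    contains its relative position (nearest peak mean wins when windows
    overlap; states in no window are unassigned).  Per chain, a peak's
    access ratio is the fraction of that chain's assigned binding events
    (visits) in states assigned to the peak — or the fraction of bound
    *frames* when ``point_fraction`` is set — so access ratios sum to
    one over peaks; the reported ratio is the mean +/- SD across chains.  Dwell events are pooled across chains and
    fitted with :func:`fit_exponential_dwell`; peaks whose access ratio
    falls below ``access_floor`` are excluded from dwell reporting
    (their accessibility is too low to infer a dwell time).
    """
    K = len(mixture.means)
    per_chain_access = np.zeros((len(results), K))
    chain_has_events = np.zeros(len(results), dtype=bool)
    pooled_dwells: List[list] = [[] for _ in range(K)]
    n_states = np.zeros(K, dtype=int)

    for ci, res in enumerate(results):
        weights = np.zeros(K)
        total = 0.0
        for state, rel in zip(res.binding_states, res.relative_positions):
            inside = np.abs(rel - mixture.means) <= mixture.sds
            if not inside.any():
                continue
            cand = np.flatnonzero(inside)
            k = cand[np.argmin(np.abs(rel - mixture.means[cand]))]
            size = state.occupancy * res.n_frames if point_fraction else state.n_visits
            weights[k] += size
            n_states[k] += 1
            pooled_dwells[k].extend(state.dwells.tolist())
        # normalise over the chain's *assigned* events so access ratios
        # sum to one over peaks
        total = weights.sum()
        if total > 0:
            per_chain_access[ci] = weights / total
            chain_has_events[ci] = True

    active = per_chain_access[chain_has_events]
    out: List[PeakSummary] = []
    for k in range(K):
        acc = active[:, k] if len(active) else np.zeros(1)
        access = float(acc.mean())
        access_sd = float(acc.std(ddof=1)) if len(acc) > 1 else 0.0
        dwell = dwell_se = None
        excluded, reason = False, ""
        if access < access_floor:
            excluded, reason = True, "access ratio below floor"
        elif len(pooled_dwells[k]) < 10:
            excluded, reason = True, "too few dwell events"
        else:
            fit = fit_exponential_dwell(pooled_dwells[k], truncation=truncation)
            dwell, dwell_se = fit.tau, fit.se
        out.append(
            PeakSummary(
                position=float(mixture.means[k]),
                position_sd=float(mixture.sds[k]),
                access_ratio=access,
                access_sd=access_sd,
                dwell=dwell,
                dwell_se=dwell_se,
                n_states=int(n_states[k]),
                n_events=len(pooled_dwells[k]),
                excluded=excluded,
                reason=reason,
            )
        )
    if all(p.n_states == 0 for p in out):
        for p in out:
            p.excluded, p.reason = True, "no states assigned"
    return out


def pooled_relative_positions(results: Sequence[InferenceResult]) -> np.ndarray:
    """Concatenate retained binding-state positions across chains (nm,
    relative to each chain's detached mean)."""
    parts = [res.relative_positions for res in results if res.n_binding_states]
    return np.concatenate(parts) if parts else np.empty(0)


def dwell_ratio(weak_dwell_us: float, strong_rate_fit: RateFit, atp_nM: float) -> float:
    """Fold-prolongation of the dwell time from weak to strong binding.

    The strong-binding mean dwell at ``atp_nM`` is the reciprocal of the
    ATP-binding rate predicted by the rate line; the ratio is that dwell
    over the weak-binding dwell (``weak_dwell_us`` in microseconds).
    """
    if weak_dwell_us <= 0:
        raise ValueError("weak dwell must be positive")
    rate = strong_rate_fit.predict(atp_nM)  # s^-1
    if rate <= 0:
        raise ValueError("predicted strong-binding rate must be positive")
    strong_dwell_us = 1e6 / rate
    return strong_dwell_us / weak_dwell_us


@dataclass
class PowerstrokeDecomposition:
    second_mean: float
    second_sd: Optional[float]
    sd_flagged: bool
    convention: str = "independence: sd = sqrt(total_sd^2 - first_sd^2)"


def powerstroke_decompose(
    first_mean: float, first_sd: float, total_mean: float, total_sd: float
) -> PowerstrokeDecomposition:
    """Decompose the two-step powerstroke: second step = total - first.

    The second-step SD assumes the first step and the total are
    independent measurements (``sqrt(total_sd^2 - first_sd^2)``); when
    ``total_sd <= first_sd`` that difference is undefined and the SD is
    flagged instead.
    """
    if total_mean < first_mean:
        raise ValueError("total step must be at least the first step")
    second = total_mean - first_mean
    if total_sd > first_sd:
        sd = float(np.sqrt(total_sd**2 - first_sd**2))
        return PowerstrokeDecomposition(second_mean=second, second_sd=sd, sd_flagged=False)
    return PowerstrokeDecomposition(second_mean=second, second_sd=None, sd_flagged=True)
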