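"""Constrained infinite-HMM (HDP-HMM) inference of transient binding states.

The trajectory is modelled with one *detached* state (Gaussian emission,
SD fixed at 12.5 nm, free mean) and an unbounded pool of *binding*
states sharing a fixed emission SD (4.7 nm) with distinct free means.
Transitions out of a binding state can only return to the detached
state or self-persist: all binding-to-binding transition probabilities
are zero (after a weak binding the head must release before rebinding).
Under the hierarchical Dirichlet process prior this means new binding
states are only ever entered from the detached state.

Inference is by beam (slice) sampling: per MCMC iteration the
transition rows are resampled from their Dirichlet conditionals (the
constrained rows reduce to two-entry Dirichlets by the aggregation
property), slice variables truncate the state space to a finite set,
the state path is redrawn exactly by forward-filter backward-sampling
(FFBS, compiled with numba), state means get conjugate Gaussian
updates, and the two HDP concentration parameters are resampled under
vague Gamma hyperpriors by the standard auxiliary-variable schemes.
The reported result of a chain is its final sample; posterior spread
comes from many independently seeded chains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from numba import njit

from .core import SegmentList, Trajectory

_SQRT2PI = np.sqrt(2.0 * np.pi)
_MAX_STATES = 64  # hard cap on instantiated states (never reached in practice)


@dataclass
class IHMMConfig:
    """Configuration of the constrained iHMM.

    ``sd_detached`` / ``sd_bound`` are the fixed emission SDs (nm);
    ``mcmc_iterations`` MCMC sweeps per chain; ``n_inferences``
    independent chains; ``window_frames`` the exact trajectory length
    consumed (longer records are windowed by the caller);
    ``min_occupancy`` / ``min_dwell`` the state filters (a retained
    binding state must occupy at least this fraction of frames and have
    mean dwell at least ``min_dwell`` us).  ``alpha_prior`` /
    ``gamma_prior`` are (shape, rate) of the Gamma hyperpriors on the
    HDP concentrations; ``mean_prior_sd`` is the SD of the Gaussian
    prior on state means, centred on ``mean_prior_center`` (window mean
    when None).
    """

    sd_detached: float = 12.5
    sd_bound: float = 4.7
    mcmc_iterations: int = 1000
    n_inferences: int = 1000
    window_frames: int = 10_000
    min_occupancy: float = 0.01
    min_dwell: float = 40.0
    alpha_prior: Tuple[float, float] = (1.0, 1.0)
    gamma_prior: Tuple[float, float] = (1.0, 1.0)
    mean_prior_center: Optional[float] = None
    mean_prior_sd: float = 50.0
    init_states: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_occupancy < 1:
            raise ValueError("min_occupancy must lie in (0, 1)")
        if self.mcmc_iterations < 1:
            raise ValueError("mcmc_iterations must be >= 1")
        if self.sd_detached <= 0 or self.sd_bound <= 0:
            raise ValueError("emission SDs must be positive")


@dataclass
class BindingState:
    """One retained binding state of a single inference."""

    mean: float  # nm, absolute
    occupancy: float  # fraction of window frames
    dwells: np.ndarray  # us, maximal runs in the sampled path
    n_visits: int
    frame_interval: float = 40.0  # us

    @property
    def mean_dwell(self) -> float:
        return float(np.mean(self.dwells)) if len(self.dwells) else 0.0

    @property
    def dwell_time_constant(self) -> float:
        """Exponential dwell time constant (us) implied by the state's
        self-transition fraction, ``-dt / ln(pi_kk)``.

        This is the filtering statistic: a state whose visits are almost
        all single frames has essentially no self-persistence and a time
        constant near zero, far below the 40 us observability floor,
        whereas a genuine binding state's time constant approximates its
        generating dwell.  (The raw run-length mean cannot fall below one
        frame, so it could never trip the floor.)
        """
        if self.n_visits == 0:
            return 0.0
        frames = float(np.sum(self.dwells)) / self.frame_interval
        p_self = 1.0 - self.n_visits / frames
        if p_self <= 0.0:
            return 0.0
        return -self.frame_interval / np.log(p_self)


@dataclass
class InferenceResult:
    """Result of one iHMM chain (its final MCMC sample, filtered)."""

    detached_mean: float
    binding_states: List[BindingState]
    segments: SegmentList
    seed: int
    n_frames: int
    transition_counts: Optional[np.ndarray] = None  # (K+1, K+1), diagnostics

    @property
    def relative_positions(self) -> np.ndarray:
        """Binding-state means relative to the detached mean (nm)."""
        return np.array([s.mean - self.detached_mean for s in self.binding_states])

    @property
    def n_binding_states(self) -> int:
        return len(self.binding_states)

    def all_dwells(self) -> np.ndarray:
        if not self.binding_states:
            return np.empty(0)
        return np.concatenate([s.dwells for s in self.binding_states])

    def plot(self, traj: Trajectory, ax=None):
        """Trajectory with the inferred state means overlaid."""
        from .plotting import plot_inference

        return plot_inference(self, traj, ax=ax)

    def summary(self) -> str:
        lines = [
            f"iHMM inference (seed {self.seed}): detached mean "
            f"{self.detached_mean:.2f} nm, {self.n_binding_states} binding state(s)",
        ]
        for s, rel in zip(self.binding_states, self.relative_positions):
            lines.append(
                f"  pos {rel:+7.2f} nm  occupancy {s.occupancy:6.3f}  "
                f"visits {s.n_visits:4d}  mean dwell {s.mean_dwell:7.1f} us"
            )
        return "\n".join(lines)


@njit(cache=True)
def _ffbs(lik, P, init_row, u, rand):  # pragma: no cover - exercised via wrapper
    """Forward-filter backward-sample under slice truncation.

    lik : (T, K) per-frame emission likelihoods
    P : (K, K) transition probabilities (zeros on forbidden entries)
    init_row : (K,) initial-state probabilities
    u : (T,) slice variables; transition j->k is admissible at t iff
        P[j, k] > u[t] (u of zeros disables slicing)
    rand : (T,) uniforms driving the backward draws
    """
    T, K = lik.shape
    alpha = np.zeros((T, K))
    tot = 0.0
    for k in range(K):
        if init_row[k] > u[0]:
            alpha[0, k] = lik[0, k]
            tot += alpha[0, k]
    if tot > 0:
        for k in range(K):
            alpha[0, k] /= tot
    for t in range(1, T):
        tot = 0.0
        for k in range(K):
            s = 0.0
            for j in range(K):
                if P[j, k] > u[t]:
                    s += alpha[t - 1, j]
            val = s * lik[t, k]
            alpha[t, k] = val
            tot += val
        if tot > 0:
            for k in range(K):
                alpha[t, k] /= tot
    path = np.empty(T, dtype=np.int64)
    # sample s_{T-1}
    r = rand[T - 1]
    acc = 0.0
    path[T - 1] = K - 1
    for k in range(K):
        acc += alpha[T - 1, k]
        if r < acc:
            path[T - 1] = k
            break
    for t in range(T - 2, -1, -1):
        tot = 0.0
        for j in range(K):
            if P[j, path[t + 1]] > u[t + 1]:
                tot += alpha[t, j]
        r = rand[t] * tot
        acc = 0.0
        path[t] = 0
        for j in range(K):
            if P[j, path[t + 1]] > u[t + 1]:
                acc += alpha[t, j]
                if r < acc:
                    path[t] = j
                    break
    return path


@njit(cache=True)
def _ffbs_exact(lik, P, init_row, rand):  # pragma: no cover - exercised via wrapper
    """Standard (unsliced) FFBS: exact draw from the path posterior."""
    T, K = lik.shape
    alpha = np.zeros((T, K))
    tot = 0.0
    for k in range(K):
        alpha[0, k] = init_row[k] * lik[0, k]
        tot += alpha[0, k]
    for k in range(K):
        alpha[0, k] /= tot
    for t in range(1, T):
        tot = 0.0
        for k in range(K):
            s = 0.0
            for j in range(K):
                s += alpha[t - 1, j] * P[j, k]
            alpha[t, k] = s * lik[t, k]
            tot += alpha[t, k]
        for k in range(K):
            alpha[t, k] /= tot
    path = np.empty(T, dtype=np.int64)
    r = rand[T - 1]
    acc = 0.0
    path[T - 1] = K - 1
    for k in range(K):
        acc += alpha[T - 1, k]
        if r < acc:
            path[T - 1] = k
            break
    for t in range(T - 2, -1, -1):
        tot = 0.0
        for j in range(K):
            tot += alpha[t, j] * P[j, path[t + 1]]
        r = rand[t] * tot
        acc = 0.0
        path[t] = 0
        for j in range(K):
            acc += alpha[t, j] * P[j, path[t + 1]]
            if r < acc:
                path[t] = j
                break
    return path


def ffbs_sample(
    lik: np.ndarray,
    P: np.ndarray,
    init_row: np.ndarray,
    rng: np.random.Generator,
    u: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Draw one state path by FFBS.

    With slice variables ``u`` the transition factor is the beam
    indicator ``P[j, k] > u_t`` (marginally over ``u ~ U(0, P)`` this
    reproduces ``P``); without them, the exact P-weighted sampler is
    used.
    """
    lik = np.ascontiguousarray(lik, dtype=np.float64)
    P = np.ascontiguousarray(P, dtype=np.float64)
    init = np.ascontiguousarray(init_row, dtype=np.float64)
    T = lik.shape[0]
    rand = rng.random(T)
    if u is None:
        return _ffbs_exact(lik, P, init, rand)
    return _ffbs(lik, P, init, u, rand)


def _crt_count(n: int, conc: float, rng: np.random.Generator) -> int:
    """Number of tables seating n customers in a CRP with mass ``conc``."""
    if n <= 0:
        return 0
    return int(np.sum(rng.random(n) < conc / (conc + np.arange(n))))


class BindingStateIHMM:
    """Constrained HDP-HMM model of transient binding states.

    Parameters
    ----------
    traj : Trajectory
        1D trajectory whose length equals ``config.window_frames``.
    config : IHMMConfig
    """

    def __init__(self, traj: Trajectory, config: Optional[IHMMConfig] = None):
        self.config = config or IHMMConfig()
        if len(traj) != self.config.window_frames:
            raise ValueError(
                f"trajectory length {len(traj)} != window_frames "
                f"{self.config.window_frames}; window the input first"
            )
        if self.config.min_dwell < traj.frame_interval:
            raise ValueError("min_dwell must be >= the frame interval")
        if np.ptp(traj.positions) == 0:
            raise ValueError("all positions identical; nothing to infer")
        self.traj = traj

    # ---------------------------------------------------------------- sampler
    def _sample_chain(
        self, seed: int, trace: Optional[list] = None
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Run one chain; return (path, means, transition counts) of the
        final sample.  State 0 is detached, 1..K are binding states."""
        cfg = self.config
        rng = np.random.default_rng(seed)
        x = self.traj.positions
        T = len(x)
        prior_mu = (
            float(np.mean(x))
            if cfg.mean_prior_center is None
            else cfg.mean_prior_center
        )
        prior_var = cfg.mean_prior_sd**2
        a_al, b_al = cfg.alpha_prior
        a_ga, b_ga = cfg.gamma_prior

        alpha, gamma = 1.0, 1.0
        # Initialise with a pool of candidate binding states spread over the
        # data range (slightly jittered per chain) and a per-frame MAP path;
        # a cold all-detached start cannot mix, because the slice sampler
        # gives newborn states a negligible entry probability.  The sampler
        # rapidly prunes unused candidates; the stationary distribution is
        # unaffected by the start.
        K = max(int(cfg.init_states), 1)
        q = (np.arange(K) + 0.5) / K
        init_means = np.quantile(x, q) + rng.normal(0.0, 1.0, K)
        means = np.concatenate(([np.mean(x)], init_means))
        sds0 = np.concatenate(([cfg.sd_detached], np.full(K, cfg.sd_bound)))
        loglik0 = -0.5 * ((x[:, None] - means[None, :]) / sds0[None, :]) ** 2 - np.log(
            sds0[None, :]
        )
        path = np.argmax(loglik0, axis=1).astype(np.int64)
        beta = np.full(K + 1, 1.0 / (K + 2))
        beta_rest = 1.0 / (K + 2)

        for _ in range(cfg.mcmc_iterations):
            # --- transition counts (frame -1 treated as detached)
            counts = np.zeros((K + 1, K + 1))
            prev = np.concatenate(([0], path[:-1]))
            np.add.at(counts, (prev, path), 1.0)

            # --- sample transition rows from Dirichlet conditionals
            # detached row keeps an explicit "rest" column; binding rows are
            # two-entry (to-detached, self) by the constraint + aggregation.
            row0 = rng.dirichlet(
                np.concatenate((alpha * beta + counts[0], [alpha * beta_rest]))
            )
            P = np.zeros((K + 1, K + 1))
            P[0] = row0[:-1]
            p0_rest = row0[-1]
            for j in range(1, K + 1):
                d = rng.dirichlet(
                    [alpha * beta[0] + counts[j, 0], alpha * beta[j] + counts[j, j]]
                )
                P[j, 0], P[j, j] = d[0], d[1]

            # --- slice variables from the current (valid) path
            trans_p = np.empty(T)
            trans_p[0] = P[0, path[0]]
            trans_p[1:] = P[path[:-1], path[1:]]
            u = rng.random(T) * trans_p
            min_u = u.min()

            # --- expand represented states until the detached row's
            # unrepresented mass is below the smallest slice
            while p0_rest > min_u and K + 1 < _MAX_STATES:
                b = rng.beta(1.0, gamma)
                beta_new = b * beta_rest
                beta_rest = (1.0 - b) * beta_rest
                v = rng.beta(max(alpha * beta_new, 1e-12), max(alpha * beta_rest, 1e-12))
                p_new = v * p0_rest
                p0_rest = (1.0 - v) * p0_rest
                d = rng.dirichlet([alpha * beta[0], max(alpha * beta_new, 1e-12)])
                K += 1
                beta = np.append(beta, beta_new)
                means = np.append(means, rng.normal(prior_mu, cfg.mean_prior_sd))
                newP = np.zeros((K + 1, K + 1))
                newP[:K, :K] = P
                newP[0, K] = p_new
                newP[K, 0], newP[K, K] = d[0], d[1]
                P = newP

            # --- FFBS path update
            sds = np.concatenate(([cfg.sd_detached], np.full(K, cfg.sd_bound)))
            lik = (
                np.exp(-0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2)
                / (sds[None, :] * _SQRT2PI)
            )
            path = _ffbs(
                np.ascontiguousarray(lik),
                np.ascontiguousarray(P),
                np.ascontiguousarray(P[0]),
                u,
                rng.random(T),
            )

            # --- drop unused binding states, fold their beta into the rest
            used = np.unique(path)
            keep = np.concatenate(([0], used[used > 0]))
            relabel = -np.ones(K + 1, dtype=np.int64)
            relabel[keep] = np.arange(len(keep))
            dropped_mass = beta[np.setdiff1d(np.arange(1, K + 1), keep)].sum()
            beta_rest += float(dropped_mass)
            beta = beta[keep]
            means = means[keep]
            path = relabel[path]
            K = len(keep) - 1

            # --- conjugate Gaussian mean updates (emission SDs stay fixed)
            sds = np.concatenate(([cfg.sd_detached], np.full(K, cfg.sd_bound)))
            for k in range(K + 1):
                xk = x[path == k]
                prec = 1.0 / prior_var + len(xk) / sds[k] ** 2
                m = (prior_mu / prior_var + xk.sum() / sds[k] ** 2) / prec
                means[k] = rng.normal(m, 1.0 / np.sqrt(prec))

            # --- auxiliary table counts and beta update
            counts = np.zeros((K + 1, K + 1))
            prev = np.concatenate(([0], path[:-1]))
            np.add.at(counts, (prev, path), 1.0)
            m_tab = np.zeros((K + 1, K + 1))
            for j in range(K + 1):
                for k in range(K + 1):
                    n_jk = int(counts[j, k])
                    if n_jk > 0:
                        m_tab[j, k] = max(
                            1, _crt_count(n_jk, alpha * max(beta[k], 1e-12), rng)
                        )
            m_col = m_tab.sum(axis=0)
            draw = rng.dirichlet(np.concatenate((m_col + 1e-12, [gamma])))
            beta, beta_rest = draw[:-1], float(draw[-1])

            # --- resample HDP concentrations
            m_tot = float(m_tab.sum())
            n_rows = counts.sum(axis=1)
            s_sum, logw_sum = 0.0, 0.0
            for nj in n_rows[n_rows > 0]:
                logw_sum += np.log(rng.beta(alpha + 1.0, nj))
                s_sum += rng.random() < nj / (nj + alpha)
            alpha = rng.gamma(a_al + m_tot - s_sum, 1.0 / (b_al - logw_sum))
            alpha = float(np.clip(alpha, 1e-3, 1e3))
            k_rep = K + 1
            eta = rng.beta(gamma + 1.0, max(m_tot, 1.0))
            odds = (a_ga + k_rep - 1.0) / (max(m_tot, 1.0) * (b_ga - np.log(eta)))
            if rng.random() < odds / (1.0 + odds):
                gamma = rng.gamma(a_ga + k_rep, 1.0 / (b_ga - np.log(eta)))
            else:
                gamma = rng.gamma(a_ga + k_rep - 1.0, 1.0 / (b_ga - np.log(eta)))
            gamma = float(np.clip(gamma, 1e-3, 1e3))
            if trace is not None:
                trace.append((K, alpha, gamma, float(np.mean(path == 0))))

        counts = np.zeros((K + 1, K + 1))
        prev = np.concatenate(([0], path[:-1]))
        np.add.at(counts, (prev, path), 1.0)
        return path, means, counts

    # ----------------------------------------------------------------- public
    def fit(self, seed: Optional[int] = None) -> InferenceResult:
        """Run one chain and return its filtered final sample."""
        seed = self.config.seed if seed is None else seed
        path, means, counts = self._sample_chain(int(seed) % 2**31)
        result = self._build_result(path, means, counts, int(seed))
        return filter_states(result, self.config)

    def fit_repeated(
        self, n_inferences: Optional[int] = None, base_seed: Optional[int] = None
    ) -> List[InferenceResult]:
        """Run independent chains with seeds base_seed, base_seed + 1, ...

        Chains are seed-indexed, so the pooled output is identical
        regardless of execution order.
        """
        n = self.config.n_inferences if n_inferences is None else n_inferences
        base = self.config.seed if base_seed is None else base_seed
        return [self.fit(seed=(base + i) % 2**31) for i in range(n)]

    def _build_result(
        self, path: np.ndarray, means: np.ndarray, counts: np.ndarray, seed: int
    ) -> InferenceResult:
        dt = self.traj.frame_interval
        segments = SegmentList.from_labels(path, dt)
        states = []
        for k in range(1, len(means)):
            dwells = segments.dwells(k)
            states.append(
                BindingState(
                    mean=float(means[k]),
                    occupancy=float(np.mean(path == k)),
                    dwells=dwells,
                    n_visits=len(dwells),
                    frame_interval=dt,
                )
            )
        return InferenceResult(
            detached_mean=float(means[0]),
            binding_states=states,
            segments=segments,
            seed=seed,
            n_frames=len(path),
            transition_counts=counts,
        )


def filter_states(result: InferenceResult, cfg: IHMMConfig) -> InferenceResult:
    """Apply the state filters: drop binding states occupying less than
    ``min_occupancy`` of the window or whose dwell time constant (from
    the self-transition fraction) is below ``min_dwell`` us; their
    frames are reassigned to the detached state."""

    def _keep(s: BindingState) -> bool:
        return s.occupancy >= cfg.min_occupancy and s.dwell_time_constant >= cfg.min_dwell

    if all(_keep(s) for s in result.binding_states):
        return result
    labels = result.segments.to_labels()
    kept_ids = {i + 1 for i, s in enumerate(result.binding_states) if _keep(s)}
    relabel = np.zeros(len(result.binding_states) + 1, dtype=int)
    for new_id, old_id in enumerate(sorted(kept_ids), start=1):
        relabel[old_id] = new_id
    new_labels = relabel[labels]
    segments = SegmentList.from_labels(new_labels, result.segments.frame_interval)
    # Dwells are re-derived from the relabelled path (merging runs that were
    # separated only by removed states).
    new_states = []
    for new_id, old_id in enumerate(sorted(kept_ids), start=1):
        old = result.binding_states[old_id - 1]
        dwells = segments.dwells(new_id)
        new_states.append(
            BindingState(
                mean=old.mean,
                occupancy=float(np.mean(new_labels == new_id)),
                dwells=dwells,
                n_visits=len(dwells),
                frame_interval=result.segments.frame_interval,
            )
        )
    return InferenceResult(
        detached_mean=result.detached_mean,
        binding_states=new_states,
        segments=segments,
        seed=result.seed,
        n_frames=result.n_frames,
        transition_counts=result.transition_counts,
    )


def run_ihmm(traj: Trajectory, cfg: IHMMConfig) -> InferenceResult:
    """Functional wrapper around :meth:`BindingStateIHMM.fit`."""
    return BindingStateIHMM(traj, cfg).fit()


def run_repeated(traj: Trajectory, cfg: IHMMConfig) -> List[InferenceResult]:
    """Functional wrapper around :meth:`BindingStateIHMM.fit_repeated`."""
    return BindingStateIHMM(traj, cfg).fit_repeated()
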