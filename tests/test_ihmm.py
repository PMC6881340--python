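"""Constrained HDP-iHMM: FFBS exactness against brute-force path
enumeration, constraint preservation, filters, determinism, null
calibration, and parameter recovery on simulated trajectories."""

import itertools

import numpy as np
import pytest

import myotrack as mt
from myotrack.core import SegmentList
from myotrack.ihmm import BindingState, BindingStateIHMM, IHMMConfig, ffbs_sample


def _enumeration_instance(seed=0):
    """Pinned 3-state instance (detached + 2 binding, T = 8) with the
    binding-to-binding transitions zeroed."""
    rng = np.random.default_rng(seed)
    means = np.array([0.0, 25.0, -25.0])
    sds = np.array([12.5, 4.7, 4.7])
    P = np.array([[0.90, 0.06, 0.04], [0.45, 0.55, 0.0], [0.35, 0.0, 0.65]])
    true_path = [0, 1, 1, 0, 0, 2, 2, 0]
    x = np.array([means[s] + sds[s] * rng.standard_normal() for s in true_path])
    lik = np.exp(-0.5 * ((x[:, None] - means) / sds) ** 2) / (sds * np.sqrt(2 * np.pi))
    return lik, P, P[0]


def exact_path_posterior(lik, P, init):
    T, K = lik.shape
    probs = {}
    for path in itertools.product(range(K), repeat=T):
        p = init[path[0]] * lik[0, path[0]]
        for t in range(1, T):
            p *= P[path[t - 1], path[t]] * lik[t, path[t]]
        if p > 0:
            probs[path] = p
    Z = sum(probs.values())
    return {k: v / Z for k, v in probs.items()}


class TestFFBS:
    def test_matches_enumeration(self):
        lik, P, init = _enumeration_instance()
        exact = exact_path_posterior(lik, P, init)
        n = 100_000
        rng = np.random.default_rng(123)
        counts = {}
        for _ in range(n):
            path = tuple(ffbs_sample(lik, P, init, rng))
            counts[path] = counts.get(path, 0) + 1
        tv = 0.5 * sum(abs(counts.get(k, 0) / n - p) for k, p in exact.items())
        tv += 0.5 * sum(c / n for k, c in counts.items() if k not in exact)
        assert tv < 0.02

    def test_forbidden_transitions_never_sampled(self):
        lik, P, init = _enumeration_instance(seed=1)
        rng = np.random.default_rng(7)
        for _ in range(2000):
            path = ffbs_sample(lik, P, init, rng)
            pairs = set(zip(path[:-1], path[1:]))
            assert (1, 2) not in pairs and (2, 1) not in pairs


@pytest.fixture(scope="module")
def four_site_chains(four_site_traj):
    cfg = IHMMConfig(mcmc_iterations=1000, window_frames=10_000, seed=0)
    model = BindingStateIHMM(four_site_traj, cfg)
    return model.fit_repeated(n_inferences=6, base_seed=0), cfg


class TestSampler:
    def test_seed_determinism(self, four_site_traj):
        cfg = IHMMConfig(mcmc_iterations=120, window_frames=10_000, seed=0)
        model = BindingStateIHMM(four_site_traj, cfg)
        a = model.fit(seed=11)
        b = model.fit(seed=11)
        assert a.detached_mean == b.detached_mean
        assert np.array_equal(a.segments.segments, b.segments.segments)
        assert np.array_equal(a.relative_positions, b.relative_positions)

    def test_repeated_pooled_multiset_determinism(self, four_site_traj):
        cfg = IHMMConfig(mcmc_iterations=120, window_frames=10_000, seed=3)
        model = BindingStateIHMM(four_site_traj, cfg)
        r1 = model.fit_repeated(n_inferences=3)
        r2 = model.fit_repeated(n_inferences=3)
        p1 = sorted(np.concatenate([r.relative_positions for r in r1]).tolist())
        p2 = sorted(np.concatenate([r.relative_positions for r in r2]).tolist())
        assert p1 == p2

    def test_single_inference_equals_run_ihmm(self, four_site_traj):
        cfg = IHMMConfig(mcmc_iterations=120, window_frames=10_000, seed=4)
        model = BindingStateIHMM(four_site_traj, cfg)
        lst = model.fit_repeated(n_inferences=1)
        one = mt.run_ihmm(four_site_traj, cfg)
        assert len(lst) == 1
        assert np.array_equal(lst[0].relative_positions, one.relative_positions)

    def test_no_binding_to_binding_transitions(self, four_site_chains):
        results, _ = four_site_chains
        for res in results:
            c = res.transition_counts
            if c.shape[0] > 2:
                off = c[1:, 1:] - np.diag(np.diag(c[1:, 1:]))
                assert np.all(off == 0)

    def test_null_calibration(self, detached_only_traj):
        # pure detached data: after filtering, >= 90% of chains report
        # zero binding states
        cfg = IHMMConfig(mcmc_iterations=1000, window_frames=10_000, seed=0)
        model = BindingStateIHMM(detached_only_traj, cfg)
        results = model.fit_repeated(n_inferences=10, base_seed=0)
        false_pos = sum(r.n_binding_states > 0 for r in results)
        assert false_pos <= 1

    def test_pooled_dwell_recovery(self, four_site_chains):
        # generating transient dwell 100 us; pooled estimate within 25%
        results, _ = four_site_chains
        pooled = np.concatenate([r.all_dwells() for r in results])
        fit = mt.fit_exponential_dwell(pooled, truncation=40.0)
        assert abs(fit.tau - 100.0) / 100.0 < 0.25

    def test_position_recovery_well_separated_sites(self):
        # longer-dwell sites: pooled positions cluster at the generators
        true_pos = np.array([-26.0, -13.0, 10.0, 23.0])
        sites = [mt.WeakSite(p, 0.25, 300.0) for p in true_pos]
        scheme = mt.KineticScheme(sites=sites, encounter_rate=700.0, duration=400_000.0)
        traj = mt.simulate_trajectory(scheme, seed=21)
        cfg = IHMMConfig(mcmc_iterations=1000, window_frames=10_000, seed=0)
        results = BindingStateIHMM(traj, cfg).fit_repeated(n_inferences=5, base_seed=0)
        pooled = mt.pooled_relative_positions(results)
        assert len(pooled) >= 4
        for p in true_pos:
            near = pooled[np.abs(pooled - p) < 6.0]
            assert len(near) > 0, f"no inferred state near {p} nm"
            assert abs(near.mean() - p) < 2.0

    def test_errors(self, four_site_traj):
        cfg = IHMMConfig(mcmc_iterations=10, window_frames=5000)
        with pytest.raises(ValueError, match="window"):
            BindingStateIHMM(four_site_traj, cfg)
        flat = mt.Trajectory(np.arange(100) * 40.0, np.zeros(100), 40.0)
        with pytest.raises(ValueError):
            BindingStateIHMM(flat, IHMMConfig(mcmc_iterations=10, window_frames=100))


def _result_from(states, n_frames=10_000, dt=40.0):
    labels = np.zeros(n_frames, dtype=int)
    return mt.InferenceResult(
        detached_mean=0.0,
        binding_states=states,
        segments=SegmentList.from_labels(labels, dt),
        seed=0,
        n_frames=n_frames,
    )


def _state(mean, occ, dwells):
    dwells = np.asarray(dwells, float)
    return BindingState(
        mean=mean, occupancy=occ, dwells=dwells, n_visits=len(dwells), frame_interval=40.0
    )


class TestFilterStates:
    def test_low_occupancy_removed(self):
        # 0.5% of a 10,000-frame window, below the 1% floor
        st = _state(10.0, 0.005, [120.0] * 50)
        res = _result_from([st])
        out = mt.filter_states(res, IHMMConfig())
        assert out.n_binding_states == 0

    def test_empty_unchanged(self):
        res = _result_from([])
        out = mt.filter_states(res, IHMMConfig())
        assert out.n_binding_states == 0
        assert out.detached_mean == res.detached_mean

    def test_matches_brute_force_predicates(self):
        cfg = IHMMConfig()
        states = [
            _state(5.0, 0.03, [120.0] * 60),   # keep: persistent, occupied
            _state(-8.0, 0.004, [200.0] * 10),  # drop: occupancy
            _state(15.0, 0.05, [40.0] * 500),   # drop: no self-persistence
            _state(22.0, 0.02, [160.0] * 40),   # keep
        ]
        res = _result_from(states)
        out = mt.filter_states(res, cfg)
        brute = [
            s
            for s in states
            if s.occupancy >= cfg.min_occupancy
            and s.dwell_time_constant >= cfg.min_dwell
        ]
        assert [s.mean for s in out.binding_states] == [s.mean for s in brute]

    def test_dwell_time_constant(self):
        # 60 visits totalling 180 frames: self-transition fraction 2/3,
        # time constant -40/ln(2/3) ~ 98.7 us
        st = _state(5.0, 0.018, [120.0] * 60)
        assert st.dwell_time_constant == pytest.approx(-40.0 / np.log(2 / 3), rel=1e-9)
        # all single-frame visits: no persistence at all
        st2 = _state(5.0, 0.01, [40.0] * 100)
        assert st2.dwell_time_constant == 0.0
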