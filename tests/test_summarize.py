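"""Mixture fitting, peak summarisation, dwell fits and the ratio /
decomposition arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import myotrack as mt
from myotrack.core import SegmentList
from myotrack.ihmm import BindingState

# the five-peak layout of the pooled weak-binding position histogram:
# (mean nm, SD nm, access weight, dwell us)
FIVE_PEAKS = {
    "means": np.array([-26.0, -12.9, -1.1, 9.9, 22.8]),
    "sds": np.array([0.8, 0.8, 0.7, 0.7, 1.2]),
    "weights": np.array([0.014, 0.184, 0.493, 0.245, 0.064]),
    "dwells": np.array([322.0, 237.0, 160.0, 238.0, 513.0]),
}


def sample_five_peak_positions(n, seed):
    rng = np.random.default_rng(seed)
    comp = rng.choice(5, size=n, p=FIVE_PEAKS["weights"])
    return rng.normal(FIVE_PEAKS["means"][comp], FIVE_PEAKS["sds"][comp])


class TestMixture:
    def test_single_cluster(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 0.5, 200)
        fit = mt.fit_gaussian_mixture_1d(x, K=1, seed=0)
        assert fit.means[0] == pytest.approx(x.mean(), abs=1e-6)
        assert fit.weights[0] == pytest.approx(1.0)

    def test_five_component_recovery(self):
        x = sample_five_peak_positions(4660, seed=1)
        fit = mt.fit_gaussian_mixture_1d(x, K=5, seed=0)
        for k in range(5):
            n_k = 4660 * FIVE_PEAKS["weights"][k]
            se = FIVE_PEAKS["sds"][k] / np.sqrt(n_k)
            assert abs(fit.means[k] - FIVE_PEAKS["means"][k]) < 3 * se

    def test_two_component_weights(self):
        rng = np.random.default_rng(2)
        comp = rng.random(10_000) < 0.7
        x = np.where(comp, rng.normal(20.0, 1.0, 10_000), rng.normal(0.0, 1.0, 10_000))
        fit = mt.fit_gaussian_mixture_1d(x, K=2, seed=0)
        assert fit.weights[0] == pytest.approx(0.3, abs=0.02)
        assert fit.weights[1] == pytest.approx(0.7, abs=0.02)

    def test_errors(self):
        with pytest.raises(ValueError):
            mt.fit_gaussian_mixture_1d(np.zeros(100), K=0, seed=0)
        with pytest.raises(ValueError):
            mt.fit_gaussian_mixture_1d(np.arange(10.0), K=5, seed=0)
        with pytest.raises(ValueError):
            mt.fit_gaussian_mixture_1d(np.ones(100), K=2, seed=0)


class TestDwellFit:
    def test_continuous_truncated_exponential(self):
        rng = np.random.default_rng(3)
        d = 40.0 + rng.exponential(160.0, 708)
        fit = mt.fit_exponential_dwell(d, truncation=40.0)
        assert abs(fit.tau - 160.0) < 3 * max(fit.se, 160.0 / np.sqrt(708))
        assert fit.amplitude == pytest.approx(1.0, abs=0.05)
        assert fit.tau_mle == pytest.approx(d.mean() - 40.0)

    def test_cdf_and_mle_agree(self):
        rng = np.random.default_rng(4)
        d = rng.exponential(500.0, 10_000)
        fit = mt.fit_exponential_dwell(d, truncation=0.0)
        assert abs(fit.tau - fit.tau_mle) / fit.tau_mle < 0.02

    def test_frame_quantised_dwells_recover_tau(self):
        # dwells quantised to 40-us frames (min one frame): the free
        # amplitude lets the fit track the geometric tail decay
        rng = np.random.default_rng(5)
        d = 40.0 * np.maximum(1, np.round(rng.exponential(100.0, 5000) / 40.0))
        fit = mt.fit_exponential_dwell(d, truncation=40.0)
        assert abs(fit.tau - 100.0) / 100.0 < 0.1

    def test_order_invariance_and_duplication(self):
        rng = np.random.default_rng(6)
        d = 40.0 + rng.exponential(200.0, 300)
        f1 = mt.fit_exponential_dwell(d)
        f2 = mt.fit_exponential_dwell(d[::-1])
        assert f1.tau == pytest.approx(f2.tau, rel=1e-9)
        f3 = mt.fit_exponential_dwell(np.tile(d, 2))
        assert f3.tau == pytest.approx(f1.tau, rel=1e-6)
        assert f3.se < f1.se

    def test_degenerate_mle(self):
        fit = mt.fit_exponential_dwell([100.0] * 10, truncation=0.0)
        assert fit.tau_mle == pytest.approx(100.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            mt.fit_exponential_dwell([50.0] * 5)
        with pytest.raises(ValueError):
            mt.fit_exponential_dwell([30.0] * 20, truncation=40.0)


def _chain(states, n_frames=10_000):
    return mt.InferenceResult(
        detached_mean=0.0,
        binding_states=states,
        segments=SegmentList.from_labels(np.zeros(n_frames, int), 40.0),
        seed=0,
        n_frames=n_frames,
    )


def _state(mean, dwells, occ=0.05):
    dwells = np.asarray(dwells, float)
    return BindingState(mean=mean, occupancy=occ, dwells=dwells, n_visits=len(dwells))


class TestSummarizePeaks:
    def _mixture(self, means, sds):
        means = np.asarray(means, float)
        sds = np.asarray(sds, float)
        return mt.MixtureFit1D(
            means=means, sds=sds, weights=np.full(len(means), 1 / len(means)),
            log_likelihood=0.0, n_samples=100,
        )

    def test_single_site_access_one(self):
        mix = self._mixture([10.0], [1.0])
        chains = [_chain([_state(10.2, [120.0] * 30)]) for _ in range(4)]
        peaks = mt.summarize_peaks(chains, mix)
        assert peaks[0].access_ratio == pytest.approx(1.0)
        assert peaks[0].access_sd == pytest.approx(0.0)

    def test_access_matches_brute_force(self):
        mix = self._mixture([-10.0, 0.0, 10.0], [1.0, 1.0, 1.0])
        chains = [
            _chain([
                _state(-10.1, [120.0] * 30),  # 30 events at peak 0
                _state(0.3, [160.0] * 50),    # 50 events at peak 1
                _state(9.8, [200.0] * 20),    # 20 events at peak 2
            ]),
            _chain([
                _state(-9.5, [120.0] * 10),
                _state(0.0, [160.0] * 30),
            ]),
        ]
        peaks = mt.summarize_peaks(chains, mix, access_floor=0.0)
        expect = np.array([[30 / 100, 50 / 100, 20 / 100], [10 / 40, 30 / 40, 0.0]])
        for k in range(3):
            assert peaks[k].access_ratio == pytest.approx(expect[:, k].mean())
        # access ratios over peaks sum to one
        assert sum(p.access_ratio for p in peaks) == pytest.approx(1.0, abs=0.01)

    def test_low_access_peak_excluded_from_dwell(self):
        mix = self._mixture([0.0, 20.0], [1.0, 1.0])
        chains = [
            _chain([_state(0.0, [160.0] * 99), _state(20.0, [320.0] * 1)])
            for _ in range(3)
        ]
        peaks = mt.summarize_peaks(chains, mix, access_floor=0.02)
        assert not peaks[0].excluded
        assert peaks[1].excluded and peaks[1].dwell is None

    def test_access_normalised_over_assigned_events(self):
        # a state outside every peak window does not enter the
        # normalisation: ratios stay a partition of assigned events
        mix = self._mixture([0.0], [1.0])
        chains = [_chain([_state(0.0, [160.0] * 50), _state(30.0, [160.0] * 50)])]
        peaks = mt.summarize_peaks(chains, mix, access_floor=0.0)
        assert peaks[0].access_ratio == pytest.approx(1.0)


class TestRatioAndDecomposition:
    def test_equal_dwells_ratio_one(self):
        line = mt.RateFit(slope=0.0, intercept=10.0)
        assert mt.dwell_ratio(1e5, line, 1000.0) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        line = mt.RateFit(slope=0.0, intercept=10.0)
        # strong dwell 0.1 s = 1e5 us; weak dwell 10 ms -> ratio 10
        assert mt.dwell_ratio(10_000.0, line, 500.0) == pytest.approx(10.0)

    def test_fitted_line_at_2uM(self):
        line = mt.RateFit(slope=0.0038, intercept=0.17)
        ratio = mt.dwell_ratio(513.0, line, 2000.0)
        assert round(ratio, -1) == 250

    def test_invalid(self):
        line = mt.RateFit(slope=0.0, intercept=-1.0)
        with pytest.raises(ValueError):
            mt.dwell_ratio(100.0, line, 10.0)
        with pytest.raises(ValueError):
            mt.dwell_ratio(0.0, mt.RateFit(slope=0.0, intercept=1.0), 10.0)

    def test_powerstroke_printed_values(self):
        d = mt.powerstroke_decompose(3.9, 1.1, 7.9, 2.6)
        assert d.second_mean == pytest.approx(4.0)
        assert d.second_sd == pytest.approx(np.sqrt(2.6**2 - 1.1**2))
        assert not d.sd_flagged

    def test_powerstroke_degenerate(self):
        d = mt.powerstroke_decompose(5.0, 1.0, 5.0, 1.0)
        assert d.second_mean == 0.0
        assert d.sd_flagged

    def test_powerstroke_hand_computation(self):
        d = mt.powerstroke_decompose(2.0, 1.0, 5.0, 2.0)
        assert d.second_mean == pytest.approx(3.0)
        assert d.second_sd == pytest.approx(np.sqrt(3.0))

    @given(
        first=st.floats(0.0, 50.0),
        extra=st.floats(0.0, 50.0),
        s1=st.floats(0.1, 5.0),
        s2=st.floats(0.1, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_powerstroke_additivity(self, first, extra, s1, s2):
        d = mt.powerstroke_decompose(first, s1, first + extra, s2)
        assert d.second_mean == pytest.approx(extra, abs=1e-9)
        assert d.sd_flagged == (s2 <= s1)
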