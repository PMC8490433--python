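"""Generator correctness: Gillespie paths, rendering, titrations, mixtures."""

import numpy as np
import pytest
from scipy import stats

import nanokin as nk
from nanokin.errors import ConfigurationError, SingleCycleWarning
from nanokin.simulate import RELOAD_STATE

from conftest import make_acq


class TestStatePath:
    def test_zero_concentration_is_single_baseline_segment(self, two_state):
        path = nk.sample_state_path(two_state, 0.0, 30.0, seed=0)
        assert len(path.segments) == 1
        seg = path.segments[0]
        assert seg.state == "baseline"
        assert seg.t_start == 0.0 and seg.t_end == 30.0

    def test_occupancy_matches_two_state_equilibrium(self, two_state):
        # closed form: bound fraction = cK_b/(1+cK_b) = 2/3 at c = 1 mM
        fracs = []
        for seed in range(10):
            path = nk.sample_state_path(two_state, 1e-3, 600.0, seed=seed)
            bound = sum(s.duration for s in path.segments if s.state == "bound")
            fracs.append(bound / path.duration)
        assert abs(np.mean(fracs) - 2.0 / 3.0) < 0.02

    def test_bound_dwell_mean_matches_exponential_law(self, two_state):
        path = nk.sample_state_path(two_state, 1e-3, 600.0, seed=3)
        dwells = [s.duration for s in path.segments[1:-1] if s.state == "bound"]
        mean, sem = np.mean(dwells), np.std(dwells) / np.sqrt(len(dwells))
        assert abs(mean - 0.2) < 3 * sem

    def test_dwell_distribution_is_exponential(self, two_state):
        # KS test of interior bound dwells against Exp(1/k_off), alpha = 0.01
        rng_seeds = range(4)
        dwells = []
        for seed in rng_seeds:
            path = nk.sample_state_path(two_state, 1e-3, 800.0, seed=seed)
            dwells.extend(s.duration for s in path.segments[1:-1] if s.state == "bound")
        assert len(dwells) >= 10_000
        res = stats.kstest(dwells, "expon", args=(0, 0.2))
        assert res.pvalue > 0.01

    def test_negative_rate_and_unknown_state_rejected(self):
        with pytest.raises(ConfigurationError):
            nk.KineticScheme(
                states={"a": 0.0, "b": 1.0},
                rates=(nk.RateEntry("a", "b", -1.0),),
                baseline_state="a",
            )
        with pytest.raises(ConfigurationError):
            nk.KineticScheme(
                states={"a": 0.0},
                rates=(nk.RateEntry("a", "zz", 1.0),),
                baseline_state="a",
            )

    def test_path_segments_are_contiguous_and_cover_duration(self, two_state):
        path = nk.sample_state_path(two_state, 5e-4, 120.0, seed=5)
        starts = [s.t_start for s in path.segments]
        ends = [s.t_end for s in path.segments]
        assert starts[0] == 0.0
        np.testing.assert_allclose(starts[1:], ends[:-1])
        assert ends[-1] == pytest.approx(120.0)


class TestRenderTrace:
    def test_noiseless_render_is_exact_piecewise_constant(self, two_state, quiet_noise):
        acq = make_acq(10.0, corner=None)
        path = nk.sample_state_path(two_state, 1e-3, acq.duration, seed=1)
        trace = nk.render_trace(path, two_state, quiet_noise, acq, seed=2)
        idx = path.state_indices(acq.sampling_rate, trace.samples.size)
        expected = np.array([two_state.states[s.state] for s in path.segments])[idx]
        assert np.array_equal(trace.samples, expected)

    def test_configured_minus60_amplitude_is_recovered(self, snr10_trace, calibration_baseline):
        # the configured I_b - I_p separation (-60 pA, the Ni2+ scale) is
        # recovered as the mean per-event amplitude measured on the trace
        table = nk.detect_events(snr10_trace, calibration_baseline, -60.0)
        assert len(table) > 50
        assert abs(np.mean([ev.delta_I for ev in table]) + 60.0) < 1.0

    def test_white_noise_sd_preserved_without_filter(self, two_state):
        acq = make_acq(4.0, corner=None)  # 1e5 samples
        noise = nk.NoiseModel(baseline_sd=2.0)
        trace = nk.simulate_trace(two_state, 0.0, noise, acq, seed=7)
        assert trace.samples.size == 100_000
        assert np.std(trace.samples) == pytest.approx(2.0, rel=0.02)

    def test_sample_count_matches_duration(self, two_state, quiet_noise):
        acq = make_acq(1.7, corner=None)
        trace = nk.simulate_trace(two_state, 0.0, quiet_noise, acq, seed=0)
        assert trace.samples.size == round(1.7 * 25_000)

    def test_unknown_state_mean_rejected(self, two_state, quiet_noise):
        path = nk.sample_state_path(two_state, 1e-3, 1.0, seed=0)
        with pytest.raises(ConfigurationError):
            nk.render_trace(path, {"baseline": 0.0}, quiet_noise, make_acq(1.0), seed=0)


class TestConcentrationSeries:
    def test_master_seed_determinism_is_bitwise(self, two_state, snr10_noise):
        acq = make_acq(5.0)
        concs = [2e-4, 6e-4, 1e-3]
        a = nk.simulate_concentration_series(two_state, concs, snr10_noise, acq, seed=42)
        b = nk.simulate_concentration_series(two_state, concs, snr10_noise, acq, seed=42)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.samples, tb.samples)

    def test_zero_concentration_trace_has_no_bound_segments(self, two_state, quiet_noise):
        (trace,) = nk.simulate_concentration_series(
            two_state, [0.0], quiet_noise, make_acq(5.0, corner=None), seed=1
        )
        assert trace.truth.events("baseline") == []

    def test_event_counts_scale_with_concentration(self, two_state, quiet_noise):
        concs = [2e-4, 4e-4, 6e-4, 8e-4, 1e-3]
        traces = nk.simulate_concentration_series(
            two_state, concs, quiet_noise, make_acq(240.0, corner=None), seed=9
        )
        for c, tr in zip(concs, traces):
            events = tr.truth.events("baseline")
            unbound = sum(
                s.duration for s in tr.truth.segments if s.state == "baseline"
            )
            expected = 1e4 * c * unbound
            assert abs(len(events) - expected) < 4 * np.sqrt(expected)

    def test_empty_concentration_list_rejected(self, two_state, quiet_noise):
        with pytest.raises(ConfigurationError):
            nk.simulate_concentration_series(two_state, [], quiet_noise, make_acq(1.0), seed=0)


class TestIrreversibleRun:
    @staticmethod
    def scheme(k_absorb=2.0):
        return nk.two_state_scheme(120.0, 60.0, 1e4, 10.0, k_absorb=k_absorb)

    def test_schedule_with_4_reloads_gives_5_cycles(self, quiet_noise):
        acq = make_acq(50.0, corner=None)
        trace = nk.simulate_irreversible_run(
            self.scheme(), 1e-3, quiet_noise, acq, seed=0,
            reload_times=[10.0, 20.0, 30.0, 40.0],
        )
        assert trace.truth.n_cycles == 5
        cycles = {s.cycle for s in trace.truth.segments}
        assert cycles == {0, 1, 2, 3, 4}

    def test_no_events_after_absorption_within_cycle(self, quiet_noise):
        acq = make_acq(50.0, corner=None)
        trace = nk.simulate_irreversible_run(
            self.scheme(), 1e-3, quiet_noise, acq, seed=1,
            reload_times=[10.0, 20.0, 30.0, 40.0],
        )
        for cycle in range(trace.truth.n_cycles):
            segs = [
                s for s in trace.truth.segments
                if s.cycle == cycle and s.state != RELOAD_STATE
            ]
            seen_absorbed = False
            for s in segs:
                if s.state == "terminated":
                    seen_absorbed = True
                elif seen_absorbed:
                    pytest.fail(f"state {s.state} after absorption in cycle {cycle}")

    def test_post_absorption_segment_is_quiet(self, quiet_noise):
        acq = make_acq(50.0, corner=None)
        trace = nk.simulate_irreversible_run(
            self.scheme(k_absorb=5.0), 1e-3, quiet_noise, acq, seed=2,
            reload_times=[25.0],
        )
        fs = acq.sampling_rate
        absorbed = [s for s in trace.truth.segments if s.state == "terminated"]
        assert absorbed
        seg = absorbed[0]
        chunk = trace.samples[int(seg.t_start * fs) + 1 : int(seg.t_end * fs)]
        assert np.std(chunk) == 0.0  # baseline_sd = 0: absorbing state is silent

    def test_zero_absorption_rate_is_rejected_as_unreachable(self, two_state, quiet_noise):
        with pytest.raises(ConfigurationError):
            nk.simulate_irreversible_run(
                two_state, 1e-3, quiet_noise, make_acq(10.0), seed=0, reload_times=[5.0]
            )

    def test_missing_reload_rule_warns_single_cycle(self, quiet_noise):
        with pytest.warns(SingleCycleWarning):
            trace = nk.simulate_irreversible_run(
                self.scheme(), 1e-3, quiet_noise, make_acq(5.0, corner=None), seed=3
            )
        assert trace.truth.n_cycles == 1

    def test_absorption_time_is_exponential_in_bound_clock(self):
        # competing risks: with exits k_off and k_ox from the bound state,
        # the cumulative bound time before absorption is Exp(k_ox)
        k_ox = 5.0
        scheme = nk.two_state_scheme(120.0, 60.0, 1e4, 20.0, k_absorb=k_ox)
        bound_clocks = []
        for seed in range(500):
            path = nk.sample_state_path(scheme, 1e-3, 200.0, seed=seed)
            if path.segments[-1].state != "terminated":
                continue
            bound_clocks.append(
                sum(s.duration for s in path.segments if s.state == "bound")
            )
        assert len(bound_clocks) >= 490
        res = stats.kstest(bound_clocks, "expon", args=(0, 1.0 / k_ox))
        assert res.pvalue > 0.01


class TestMixture:
    @staticmethod
    def schemes():
        return {
            "pos": nk.two_state_scheme(100.0, 120.0, 1e4, 5.0),
            "neg": nk.two_state_scheme(100.0, 70.0, 1e4, 5.0),
            "mid": nk.two_state_scheme(100.0, 85.0, 1e4, 5.0),
        }

    def test_single_class_mixture_contains_only_that_class(self, quiet_noise):
        schemes = {"pos": self.schemes()["pos"]}
        trace, labels = nk.simulate_mixture(
            schemes, {"pos": 1.0}, 1e-3, quiet_noise, make_acq(30.0, corner=None), seed=0
        )
        assert set(labels) == {"pos"}
        states = {s.state for s in trace.truth.segments}
        assert states <= {"baseline", "bound:pos"}
        assert len(trace.truth.events("baseline")) == len(labels)

    def test_class_counts_follow_multinomial(self, quiet_noise):
        props = {"pos": 1 / 3, "neg": 1 / 3, "mid": 1 / 3}
        trace, labels = nk.simulate_mixture(
            self.schemes(), props, 1e-3, quiet_noise, make_acq(180.0, corner=None), seed=4
        )
        assert len(labels) >= 600
        counts = [labels.count(k) for k in props]
        res = stats.chisquare(counts)
        assert res.pvalue > 0.01  # inside the multinomial 99% region

    def test_negative_going_class_renders_below_baseline(self, quiet_noise):
        trace, labels = nk.simulate_mixture(
            {"neg": self.schemes()["neg"]}, {"neg": 1.0}, 1e-3, quiet_noise,
            make_acq(20.0, corner=None), seed=5,
        )
        fs = trace.sampling_rate
        for seg in trace.truth.events("baseline"):
            chunk = trace.samples[int(seg.t_start * fs) + 1 : int(seg.t_end * fs)]
            if chunk.size:
                assert chunk.mean() < 100.0

    def test_mismatched_baselines_rejected(self, quiet_noise):
        schemes = {
            "a": nk.two_state_scheme(100.0, 80.0, 1e4, 5.0),
            "b": nk.two_state_scheme(90.0, 70.0, 1e4, 5.0),
        }
        with pytest.raises(ConfigurationError):
            nk.simulate_mixture(
                schemes, {"a": 0.5, "b": 0.5}, 1e-3, quiet_noise, make_acq(1.0), seed=0
            )

    def test_proportions_must_sum_to_one(self, quiet_noise):
        with pytest.raises(ConfigurationError):
            nk.simulate_mixture(
                self.schemes(), {"pos": 0.5, "neg": 0.2, "mid": 0.2}, 1e-3,
                quiet_noise, make_acq(1.0), seed=0,
            )
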