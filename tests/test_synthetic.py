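"""Generator statistics: Poisson oracles, quadrature oracle, determinism."""

import numpy as np
import pytest


from optoresp import (
    SimSweepConfig,
    SimUnitConfig,
    make_cohort,
    simulate_spike_train,
    simulate_sweep,
    single_pulse_protocol,
    train_protocol,
)
from optoresp.epsc import measure_epsc
from optoresp.synthetic import ground_truth_rate


def null_config(rate=10.0, **kw):
    return SimUnitConfig(
        baseline_rate=rate, response_class="NR", evoked_extra_spikes=0.0,
        inhibition_depth=0.0, **kw,
    )


class TestSpikeTrains:
    def test_total_count_matches_poisson_mean(self):
        # 10 Hz x 200 s -> 2000 expected spikes, 3 sigma tolerance
        proto = single_pulse_protocol(39, start=5.0)  # spans ~200 s
        cfg = null_config(seed=42)
        train = simulate_spike_train(cfg, proto, duration=200.0)
        assert abs(train.n_spikes - 2000) < 3 * np.sqrt(2000)

    def test_null_response_rate_in_post_stimulus_window(self):
        # with all evoked parameters zero the post-stimulus window holds
        # baseline-rate spikes only (aggregate z-test over 30 seeds)
        proto = single_pulse_protocol(40)
        counts = []
        for seed in range(30):
            train = simulate_spike_train(null_config(seed=seed), proto)
            for onset in proto.onsets:
                lo, hi = np.searchsorted(train.spike_times, [onset, onset + 0.03])
                counts.append(hi - lo)
        expected = 10.0 * 0.03
        z = (np.mean(counts) - expected) / np.sqrt(expected / len(counts))
        assert abs(z) < 4

    def test_mean_evoked_spikes_match_rate_integral(self):
        # area 1.0 on 10 Hz baseline: 1.0 + 10 * 0.03 = 1.3 spikes/trial
        proto = single_pulse_protocol(40)
        cfg = SimUnitConfig(
            baseline_rate=10.0, response_class="Ex", evoked_extra_spikes=1.0,
            inhibition_depth=0.0, seed=11,
        )
        train = simulate_spike_train(cfg, proto)
        per_trial = [
            np.diff(np.searchsorted(train.spike_times, [o, o + 0.03]))[0]
            for o in proto.onsets
        ]
        sem = np.sqrt(1.3 / 40)
        assert np.mean(per_trial) == pytest.approx(1.3, abs=3 * sem)

    @pytest.mark.parametrize("label", ["Ex", "Ex+In", "In"])
    def test_window_counts_match_quadrature_oracle(self, label):
        # expected count in any window = integral of the ground-truth rate
        # (numeric quadrature on a 1-us trapezoid grid)
        proto = single_pulse_protocol(15)
        cfg = SimUnitConfig(
            baseline_rate=25.0, response_class=label, evoked_extra_spikes=1.5,
            inhibition_onset=0.006, inhibition_duration=0.03,
            inhibition_depth=0.8,
        )
        rate = ground_truth_rate(cfg, proto)
        windows = [(0.0, 0.03), (0.003, 0.01), (0.0, 0.1)]
        for w0, w1 in windows:
            expected = 0.0
            for o in proto.onsets:
                grid = np.linspace(o + w0, o + w1, int((w1 - w0) * 1e6) + 1)
                expected += np.trapezoid(rate(grid), grid)
            observed = []
            for rep in range(25):
                train = simulate_spike_train(cfg, proto, rng=np.random.default_rng(
                    np.random.SeedSequence((99, rep))))
                observed.append(sum(
                    np.diff(np.searchsorted(train.spike_times, [o + w0, o + w1]))[0]
                    for o in proto.onsets
                ))
            z = (np.mean(observed) - expected) / np.sqrt(expected / 25)
            assert abs(z) < 4, (w0, w1)

    def test_spike_times_strictly_increasing(self):
        proto = train_protocol(20)
        cfg = SimUnitConfig(baseline_rate=50.0, evoked_extra_spikes=3.0)
        train = simulate_spike_train(cfg, proto, rng=np.random.default_rng(5))
        assert np.all(np.diff(train.spike_times) > 0)

    def test_empty_protocol_needs_duration_and_gives_baseline_only(self):
        proto = single_pulse_protocol(0)
        with pytest.raises(ValueError):
            simulate_spike_train(null_config(), proto)
        train = simulate_spike_train(null_config(rate=20.0, seed=1), proto,
                                     duration=50.0)
        assert abs(train.n_spikes - 1000) < 4 * np.sqrt(1000)


class TestSweeps:
    def test_single_pulse_peak_equals_configured_amplitude(self):
        cfg = SimSweepConfig(epsc_amplitude=100.0, noise_sd=0.0,
                             oscillation_amplitude=0.0,
                             depression_factors=(1.0,))
        sweep = simulate_sweep(cfg, [0.05])
        amp, base, flags = measure_epsc(sweep, 0.05)
        assert base == 0.0
        # kernel is peak-normalized; only sample-grid discretization remains
        assert amp == pytest.approx(100.0, abs=0.05)

    def test_zero_amplitude_gives_baseline_plus_noise_only(self):
        cfg = SimSweepConfig(epsc_amplitude=0.0, noise_sd=2.0,
                             oscillation_amplitude=0.0, holding_baseline=-20.0)
        sweep = simulate_sweep(cfg, [0.05], rng=np.random.default_rng(0))
        assert sweep.samples.mean() == pytest.approx(-20.0, abs=0.5)
        assert sweep.samples.std() == pytest.approx(2.0, abs=0.3)

    def test_noise_free_peaks_in_depression_ratios(self):
        factors = (1.0, 0.67, 0.5, 0.4, 0.33)
        cfg = SimSweepConfig(epsc_amplitude=150.0, noise_sd=0.0,
                             oscillation_amplitude=0.0,
                             depression_factors=factors)
        pulses = [0.05 + 0.05 * k for k in range(5)]
        sweep = simulate_sweep(cfg, pulses)
        amps = np.array([measure_epsc(sweep, p)[0] for p in pulses])
        np.testing.assert_allclose(amps / amps[0], factors, atol=5e-3)

    def test_pulse_spacing_below_sample_interval_rejected(self):
        cfg = SimSweepConfig()
        with pytest.raises(ValueError, match="spacing"):
            simulate_sweep(cfg, [0.05, 0.05 + 2e-5])


class TestCohortsAndDeterminism:
    def test_cohort_composition_and_ground_truth(self):
        units = make_cohort({"Ex": 7, "Ex+In": 21, "In": 5, "NR": 10}, seed=0)
        assert len(units) == 43
        labels = [u.label for u in units]
        assert labels.count("Ex") == 7 and labels.count("Ex+In") == 21
        assert labels.count("In") == 5 and labels.count("NR") == 10
        nr = [u for u in units if u.label == "NR"]
        assert all(u.config.evoked_extra_spikes == 0 for u in nr)
        assert all(u.config.inhibition_depth == 0 for u in nr)

    def test_same_seed_regenerates_identically_different_seed_differs(self):
        a = make_cohort({"Ex": 2, "NR": 1}, seed=7)
        b = make_cohort({"Ex": 2, "NR": 1}, seed=7)
        c = make_cohort({"Ex": 2, "NR": 1}, seed=8)
        for ua, ub in zip(a, b):
            np.testing.assert_array_equal(ua.train.spike_times, ub.train.spike_times)
        assert any(
            ua.train.n_spikes != uc.train.n_spikes
            or not np.array_equal(ua.train.spike_times, uc.train.spike_times)
            for ua, uc in zip(a, c)
        )

    def test_sweep_determinism(self):
        cfg = SimSweepConfig(seed=3)
        s1 = simulate_sweep(cfg, [0.05, 0.1])
        s2 = simulate_sweep(cfg, [0.05, 0.1])
        np.testing.assert_array_equal(s1.samples, s2.samples)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimUnitConfig(depression_factors=(0.9, 1.0))
        with pytest.raises(ValueError):
            SimUnitConfig(inhibition_depth=1.5)
        with pytest.raises(ValueError):
            SimSweepConfig(rise_tau=0.01, decay_tau=0.001)
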