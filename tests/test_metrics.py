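"""Extra spikes, train profiles and graded-intensity curves."""

import numpy as np
import pytest

from optoresp import (
    SpikeTrain,
    extra_spikes,
    graded_response,
    train_profile,
)
from optoresp.synthetic import (
    SimUnitConfig,
    simulate_spike_train,
    single_pulse_protocol,
)


def brute_force_extra_spikes(train, onsets, rate, window):
    total = 0
    for onset in onsets:
        for t in train.spike_times:
            if onset <= t < onset + window:
                total += 1
    return total / len(onsets) - rate * window


class TestExtraSpikes:
    def test_arithmetic_oracle(self):
        # one spike per trial in the window, baseline 10 Hz: 1 - 0.3 = 0.7
        onsets = 10.0 + 5.0 * np.arange(40)
        train = SpikeTrain("u", np.sort(onsets + 0.005), 250.0)
        val = extra_spikes(train, onsets, baseline_mean_rate=10.0)
        assert val == pytest.approx(0.7)

    def test_equals_brute_force_loop(self, rng):
        spikes = np.sort(rng.uniform(0, 100, 800))
        train = SpikeTrain("u", spikes, 100.0)
        onsets = np.sort(rng.uniform(5, 95, 12))
        fast = extra_spikes(train, onsets, baseline_mean_rate=8.0)
        slow = brute_force_extra_spikes(train, onsets, 8.0, 0.030)
        assert fast == pytest.approx(slow, abs=1e-12)

    def test_null_expectation_is_zero(self):
        # homogeneous Poisson: mean over many simulated units ~ 0
        proto = single_pulse_protocol(40)
        cfg = SimUnitConfig(baseline_rate=10.0, response_class="NR",
                            evoked_extra_spikes=0.0, inhibition_depth=0.0)
        vals = [
            extra_spikes(
                simulate_spike_train(cfg, proto, rng=np.random.default_rng(
                    np.random.SeedSequence((17, k)))),
                proto.onsets,
            )
            for k in range(100)
        ]
        sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * sem + 1e-9

    def test_additivity_of_evoked_area(self):
        # doubling the evoked kernel area doubles recovered extra spikes
        proto = single_pulse_protocol(40)
        means = {}
        for area in (0.75, 1.5):
            cfg = SimUnitConfig(baseline_rate=10.0, response_class="Ex",
                                evoked_extra_spikes=area, inhibition_depth=0.0)
            vals = [
                extra_spikes(
                    simulate_spike_train(cfg, proto, rng=np.random.default_rng(
                        np.random.SeedSequence((31, area == 1.5, k)))),
                    proto.onsets,
                )
                for k in range(30)
            ]
            means[area] = np.mean(vals)
        assert means[1.5] / means[0.75] == pytest.approx(2.0, abs=0.15)

    def test_window_validation(self):
        train = SpikeTrain("u", np.array([1.0]), 10.0)
        with pytest.raises(ValueError):
            extra_spikes(train, np.array([5.0]), 10.0, window=0.0)
        with pytest.raises(ValueError):
            extra_spikes(train, np.array([]), 10.0)


class TestTrainProfile:
    def _train_with_counts(self, per_pulse_spikes, n_trains=10):
        """Deterministic spikes: per_pulse_spikes[k] spikes per pulse k."""
        onsets = 10.0 + 10.0 * np.arange(n_trains)
        spikes = []
        for o in onsets:
            for k, n in enumerate(per_pulse_spikes):
                for j in range(n):
                    spikes.append(o + 0.05 * k + 0.002 + 1e-4 * j)
        return SpikeTrain("u", np.sort(spikes), onsets[-1] + 10.0), onsets

    def test_depression_percentages(self):
        # per-pulse extra spikes [1.0, .9, .85, .82, .79] (baseline 0):
        # dep 1->2 = 10%, 1->last = 21%
        train, onsets = self._train_with_counts([100, 90, 85, 82, 79], 1)
        p = train_profile(train, onsets, baseline_mean_rate=0.0)
        np.testing.assert_allclose(
            p.normalized, [1.0, 0.9, 0.85, 0.82, 0.79], atol=1e-9
        )
        assert p.depression_1_to_2 == pytest.approx(10.0)
        assert p.depression_1_to_last == pytest.approx(21.0)

    def test_constant_response_has_zero_depression(self):
        train, onsets = self._train_with_counts([3, 3, 3, 3, 3])
        p = train_profile(train, onsets, baseline_mean_rate=0.0)
        assert p.depression_1_to_2 == pytest.approx(0.0)
        assert p.depression_1_to_last == pytest.approx(0.0)

    def test_nonpositive_first_pulse_is_flagged(self):
        train, onsets = self._train_with_counts([0, 2, 2, 2, 2])
        p = train_profile(train, onsets, baseline_mean_rate=0.0)
        assert "undefined-normalization" in p.flags
        assert np.isnan(p.depression_1_to_last)

    def test_window_capped_at_pulse_interval(self):
        # with 20-ms spacing the 30-ms window must shrink to avoid overlap
        onsets = np.array([10.0])
        spikes = [10.0 + 0.002, 10.0 + 0.021]  # second spike belongs to pulse 2
        train = SpikeTrain("u", np.array(spikes), 20.0)
        p = train_profile(train, onsets, baseline_mean_rate=0.0,
                          pulse_interval=0.020)
        assert p.per_pulse_extra_spikes[0] == pytest.approx(1.0)
        assert p.per_pulse_extra_spikes[1] == pytest.approx(1.0)

    def test_recovers_simulated_depression_factors(self):
        from optoresp.synthetic import train_protocol

        factors = (1.0, 0.85, 0.75, 0.7, 0.65)
        proto = train_protocol(40)
        cfg = SimUnitConfig(baseline_rate=10.0, response_class="Ex",
                            evoked_extra_spikes=1.0, inhibition_depth=0.0,
                            depression_factors=factors)
        mats = [
            train_profile(
                simulate_spike_train(cfg, proto, rng=np.random.default_rng(
                    np.random.SeedSequence((53, k)))),
                proto.onsets,
            ).normalized
            for k in range(25)
        ]
        mean = np.mean(mats, axis=0)
        assert np.all(np.abs(mean - np.array(factors)) < 0.05)


class TestGradedResponse:
    def _unit_with_power_scaling(self, powers, seed=0, n_per_power=40):
        proto_onsets = {}
        t = 10.0
        events = []
        for p in powers:
            ons = []
            for _ in range(n_per_power):
                ons.append(t)
                t += 5.0
            proto_onsets[p] = np.array(ons)
        from optoresp.io import StimulusEvent, StimulusProtocol

        for p, ons in proto_onsets.items():
            events += [StimulusEvent(o, "single", p) for o in ons]
        events.sort(key=lambda e: e.onset)
        proto = StimulusProtocol(events=tuple(events))
        cfg = SimUnitConfig(baseline_rate=10.0, response_class="Ex",
                            evoked_extra_spikes=1.0, inhibition_depth=0.0)
        train = simulate_spike_train(cfg, proto, rng=np.random.default_rng(
            np.random.SeedSequence((61, seed))))
        return train, proto_onsets

    def test_proportional_responses_normalize_linearly(self):
        # evoked area proportional to power -> normalized curve through (1, 1)
        powers = (0.5, 1.0, 2.0)
        g_vals = []
        for seed in range(10):
            train, by_power = self._unit_with_power_scaling(powers, seed)
            g = graded_response(train, by_power)
            g_vals.append(g.normalized_to_1mW)
        mean = np.mean(g_vals, axis=0)
        np.testing.assert_allclose(mean, [0.5, 1.0, 2.0], atol=0.12)

    def test_reference_interpolated_between_bracketing_powers(self):
        # the paper-style low/medium/high powers bracket 1 mW
        powers = (0.92, 1.14, 1.33)
        vals = []
        for seed in range(10):
            train, by_power = self._unit_with_power_scaling(powers, seed)
            g = graded_response(train, by_power)
            vals.append(g.extra_spikes)
        mean = np.mean(vals, axis=0)
        sem = np.std(vals, axis=0, ddof=1) / np.sqrt(len(vals))
        # evoked areas are proportional to power with unit gain at 1 mW
        for m, s, expected in zip(mean, sem, powers):
            assert abs(m - expected) < 3 * s + 0.02

    def test_one_sided_powers_flagged(self):
        train, by_power = self._unit_with_power_scaling((2.0, 3.0, 4.0))
        g = graded_response(train, by_power)
        assert "reference-extrapolated" in g.flags

    def test_requires_three_powers(self):
        train, by_power = self._unit_with_power_scaling((0.5, 1.0))
        with pytest.raises(ValueError):
            graded_response(train, by_power)
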