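"""Synthetic spike trains and voltage-clamp sweeps with known ground truth.

Spike trains are drawn from an inhomogeneous Poisson process: a constant
baseline rate, plus — per light pulse — a transient excitatory rate bump
and/or a multiplicative suppression window:

* the bump is Gaussian with SD equal to the latency jitter, centered at
  ``onset + evoked_latency``, truncated to non-negative post-stimulus lag;
  its *area* directly parameterizes the expected evoked (extra) spikes, so
  recovery tests are self-calibrating.  Per pulse the area is scaled by the
  train-position depression factor and by the light-power gain;
* inhibition multiplies the *baseline* rate by ``1 - inhibition_depth`` over
  ``[onset + inhibition_onset, onset + inhibition_onset + duration)``.

Sweeps are a holding baseline plus per-pulse difference-of-exponential EPSC
kernels (peak-normalized, so the configured amplitude is the actual peak
deflection), scaled by depression factors, with an optional sinusoidal
subthreshold oscillation and white noise.  Inward current is a negative
deflection.

Reproducibility: every unit gets its own generator seeded from
``(master seed, unit index)``, so cohorts regenerate identically unit by
unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .io import SpikeTrain, StimulusEvent, StimulusProtocol, Sweep

__all__ = [
    "SimUnitConfig",
    "SimSweepConfig",
    "CohortUnit",
    "simulate_spike_train",
    "simulate_sweep",
    "make_cohort",
    "ground_truth_rate",
    "single_pulse_protocol",
    "train_protocol",
]

LABELS = ("Ex", "Ex+In", "In", "NR")


@dataclass(frozen=True)
class SimUnitConfig:
    """Generative parameters of one simulated unit.

    Spontaneous rates of the recorded populations are not pinned down by the
    experimental summaries; the 5-30 Hz default range used by
    :func:`make_cohort` is an assumption (configurable), with
    inhibition-bearing classes drawn from more active cells since suppression
    below baseline-minus-SD is only observable when the baseline is high
    enough.
    """

    baseline_rate: float = 20.0  # Hz
    response_class: str = "Ex"  # Ex | Ex+In | In | NR
    evoked_latency: float = 0.00239  # s, mean evoked-spike latency
    latency_jitter_sd: float = 0.0003  # s
    evoked_extra_spikes: float = 1.0  # expected evoked spikes per pulse
    inhibition_onset: float = 0.0028  # s after pulse onset
    inhibition_duration: float = 0.030  # s
    inhibition_depth: float = 0.9  # fraction of baseline suppressed
    depression_factors: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    power_reference_mW: float = 1.0  # power at which the gain is 1
    power_exponent: float = 1.0  # evoked area scales as (P/Pref)**exponent
    seed: int = 0

    def __post_init__(self):
        if self.response_class not in LABELS:
            raise ValueError(f"unknown response_class {self.response_class!r}")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.evoked_extra_spikes < 0:
            raise ValueError("evoked_extra_spikes must be >= 0")
        if not 0 <= self.inhibition_depth <= 1:
            raise ValueError("inhibition_depth must be in [0, 1]")
        if self.inhibition_duration <= 0:
            raise ValueError("inhibition_duration must be > 0")
        f = tuple(float(x) for x in self.depression_factors)
        object.__setattr__(self, "depression_factors", f)
        if not f or f[0] != 1.0:
            raise ValueError("depression_factors[0] must be 1")
        if any(not 0 < x <= 1 for x in f):
            raise ValueError("depression_factors must lie in (0, 1]")

    def power_gain(self, power_mW: float | None) -> float:
        """Evoked-area scale for a pulse at ``power_mW`` (1.0 if unspecified)."""
        if power_mW is None:
            return 1.0
        return (power_mW / self.power_reference_mW) ** self.power_exponent

    @property
    def excites(self) -> bool:
        return self.response_class in ("Ex", "Ex+In") and self.evoked_extra_spikes > 0

    @property
    def inhibits(self) -> bool:
        return self.response_class in ("In", "Ex+In") and self.inhibition_depth > 0


@dataclass(frozen=True)
class SimSweepConfig:
    """Generative parameters of one simulated voltage-clamp cell.

    Kinetics (1-ms rise, 8-ms decay) and the 10-pA, 3-Hz subthreshold
    oscillation emulate olivary EPSC sweeps; sampling is 10 kHz.
    """

    epsc_amplitude: float = 150.0  # pA, peak of the first-pulse EPSC
    rise_tau: float = 0.001  # s
    decay_tau: float = 0.008  # s
    noise_sd: float = 5.0  # pA
    depression_factors: tuple[float, ...] = (1.0, 0.67, 0.55, 0.45, 0.33)
    oscillation_amplitude: float = 10.0  # pA
    oscillation_freq: float = 3.0  # Hz
    holding_baseline: float = 0.0  # pA
    sampling_rate: float = 10_000.0  # Hz
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.rise_tau < self.decay_tau:
            raise ValueError("rise_tau must be < decay_tau")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(
            self, "depression_factors",
            tuple(float(x) for x in self.depression_factors),
        )


@dataclass(frozen=True)
class CohortUnit:
    """One simulated unit with its protocol and ground truth."""

    unit_id: str
    label: str  # ground-truth response class
    config: SimUnitConfig
    protocol: StimulusProtocol
    train: SpikeTrain


# ---------------------------------------------------------------------------
# protocol builders


def single_pulse_protocol(
    n_events: int = 40,
    spacing: float = 5.0,
    start: float = 5.0,
    power_mW: float | None = None,
) -> StimulusProtocol:
    """Single 1-ms pulses at 5-s intervals (>= 40 trials by default)."""
    events = tuple(
        StimulusEvent(onset=start + k * spacing, kind="single", power_mW=power_mW)
        for k in range(n_events)
    )
    return StimulusProtocol(events=events)


def train_protocol(
    n_trains: int = 40,
    spacing: float = 10.0,
    start: float = 5.0,
    power_mW: float | None = None,
) -> StimulusProtocol:
    """Five-pulse 20-Hz trains at 10-s interstimulus intervals."""
    events = tuple(
        StimulusEvent(onset=start + k * spacing, kind="train", power_mW=power_mW)
        for k in range(n_trains)
    )
    return StimulusProtocol(events=events)


# ---------------------------------------------------------------------------
# spike trains


def _pulses_with_scales(cfg: SimUnitConfig, protocol: StimulusProtocol):
    """(pulse_onset, evoked_area) pairs over all protocol events."""
    out = []
    for ev in protocol.events:
        gain = cfg.power_gain(ev.power_mW)
        onsets = protocol.pulse_onsets(ev)
        for pos, onset in enumerate(onsets):
            factor = (
                cfg.depression_factors[pos]
                if pos < len(cfg.depression_factors)
                else cfg.depression_factors[-1]
            )
            out.append((float(onset), cfg.evoked_extra_spikes * factor * gain))
    return out


def _truncated_normal_offsets(
    n: int, mean: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw evoked-spike lags ~ N(mean, sd) truncated at lag >= 0."""
    if sd == 0:
        return np.full(n, mean)
    lags = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = lags < 0
        if not bad.any():
            break
        lags[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(lags, 0.0, None)


def simulate_spike_train(
    cfg: SimUnitConfig,
    protocol: StimulusProtocol,
    duration: float | None = None,
    rng: np.random.Generator | None = None,
    unit_id: str = "sim",
) -> SpikeTrain:
    """Draw one spike train under ``cfg`` for ``protocol``.

    ``duration`` defaults to the last pulse onset plus the single-event
    spacing (and is the baseline-only recording length when the protocol is
    empty, in which case it must be given).  Spike times are strictly
    increasing.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pulses = _pulses_with_scales(cfg, protocol)
    if duration is None:
        if not pulses:
            raise ValueError("duration is required for an empty protocol")
        duration = pulses[-1][0] + protocol.single_event_spacing
    if pulses and pulses[-1][0] >= duration:
        raise ValueError("protocol events extend beyond the recording duration")

    # baseline: homogeneous Poisson, then thinned inside suppression windows
    n_base = rng.poisson(cfg.baseline_rate * duration)
    base = rng.uniform(0.0, duration, size=n_base)
    if cfg.inhibits:
        keep = np.ones(base.size, dtype=bool)
        for onset, _ in pulses:
            w0 = onset + cfg.inhibition_onset
            w1 = w0 + cfg.inhibition_duration
            inside = (base >= w0) & (base < w1)
            keep[inside] &= rng.random(int(inside.sum())) >= cfg.inhibition_depth
        base = base[keep]

    evoked = []
    if cfg.excites:
        for onset, area in pulses:
            n_ev = rng.poisson(area)
            if n_ev:
                lags = _truncated_normal_offsets(
                    n_ev, cfg.evoked_latency, cfg.latency_jitter_sd, rng
                )
                evoked.append(onset + lags)
    spikes = np.sort(np.concatenate([base] + evoked))
    spikes = spikes[(spikes >= 0) & (spikes <= duration)]
    # enforce strictly increasing times (ties have measure zero but guard anyway)
    if spikes.size > 1:
        dup = np.flatnonzero(np.diff(spikes) <= 0)
        while dup.size:
            spikes[dup + 1] = np.nextafter(spikes[dup + 1], np.inf)
            spikes = np.sort(spikes)
            dup = np.flatnonzero(np.diff(spikes) <= 0)
    return SpikeTrain(unit_id=unit_id, spike_times=spikes, duration=float(duration))


def ground_truth_rate(
    cfg: SimUnitConfig, protocol: StimulusProtocol
) -> Callable[[np.ndarray], np.ndarray]:
    """The exact rate function (Hz) the simulator draws from.

    Useful as a numeric-quadrature oracle: the expected spike count in any
    window is the integral of this function over it.
    """
    from scipy import stats

    pulses = _pulses_with_scales(cfg, protocol)

    def rate(t):
        t = np.asarray(t, dtype=float)
        r = np.full(t.shape, float(cfg.baseline_rate))
        if cfg.inhibits:
            for onset, _ in pulses:
                w0 = onset + cfg.inhibition_onset
                inside = (t >= w0) & (t < w0 + cfg.inhibition_duration)
                r[inside] *= 1.0 - cfg.inhibition_depth
        if cfg.excites:
            sd = cfg.latency_jitter_sd
            for onset, area in pulses:
                if sd > 0:
                    a = (0.0 - cfg.evoked_latency) / sd
                    r += area * stats.truncnorm.pdf(
                        t - onset, a, np.inf, loc=cfg.evoked_latency, scale=sd
                    )
        return r

    return rate


# ---------------------------------------------------------------------------
# sweeps


def _epsc_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak."""
    t_peak = (
        np.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)
    )
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = (np.exp(-t[pos] / decay_tau) - np.exp(-t[pos] / rise_tau)) / peak
    return out


def simulate_sweep(
    cfg: SimSweepConfig,
    pulse_times: Sequence[float],
    duration: float | None = None,
    rng: np.random.Generator | None = None,
) -> Sweep:
    """Draw one voltage-clamp sweep with EPSCs at ``pulse_times``.

    The oscillation phase is randomized per sweep; noise is white Gaussian.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pulse_times = sorted(float(t) for t in pulse_times)
    dt = 1.0 / cfg.sampling_rate
    if pulse_times and any(
        b - a < dt for a, b in zip(pulse_times, pulse_times[1:])
    ):
        raise ValueError("pulse spacing shorter than the sample interval")
    if duration is None:
        last = pulse_times[-1] if pulse_times else 0.0
        duration = last + 8 * cfg.decay_tau + 0.05
    t = np.arange(int(round(duration * cfg.sampling_rate))) * dt
    trace = np.full(t.size, cfg.holding_baseline)
    if cfg.oscillation_amplitude:
        phase = rng.uniform(0, 2 * np.pi)
        trace = trace + cfg.oscillation_amplitude * np.sin(
            2 * np.pi * cfg.oscillation_freq * t + phase
        )
    for k, p in enumerate(pulse_times):
        factor = (
            cfg.depression_factors[k]
            if k < len(cfg.depression_factors)
            else cfg.depression_factors[-1]
        )
        # inward current: negative deflection
        trace = trace - cfg.epsc_amplitude * factor * _epsc_kernel(
            t - p, cfg.rise_tau, cfg.decay_tau
        )
    if cfg.noise_sd:
        trace = trace + rng.normal(0.0, cfg.noise_sd, size=t.size)
    return Sweep(
        samples=trace,
        sampling_rate=cfg.sampling_rate,
        pulse_times=tuple(pulse_times),
    )


# ---------------------------------------------------------------------------
# cohorts


#: spontaneous-rate ranges (Hz) drawn per response class: inhibition-bearing
#: classes come from more active cells (suppression is unobservable otherwise)
BASELINE_RANGES = {
    "Ex": (5.0, 30.0),
    "NR": (5.0, 30.0),
    "Ex+In": (20.0, 40.0),
    "In": (20.0, 40.0),
}


def _class_config(label: str, template: SimUnitConfig, rate: float) -> SimUnitConfig:
    cfg = replace(template, response_class=label, baseline_rate=rate)
    if label == "NR":
        cfg = replace(cfg, evoked_extra_spikes=0.0, inhibition_depth=0.0)
    elif label == "Ex":
        cfg = replace(cfg, inhibition_depth=0.0)
    elif label == "In":
        cfg = replace(cfg, evoked_extra_spikes=0.0)
    elif label == "Ex+In":
        # suppression follows the excitatory transient
        onset = max(template.inhibition_onset, template.evoked_latency + 0.003)
        cfg = replace(cfg, inhibition_onset=onset)
    return cfg


def make_cohort(
    class_counts: dict[str, int],
    template: SimUnitConfig | None = None,
    seed: int = 0,
    n_trials: int = 40,
    baseline_ranges: dict[str, tuple[float, float]] | None = None,
) -> list[CohortUnit]:
    """Simulate one unit per requested cell with ground truth attached.

    ``class_counts`` maps labels to unit counts, e.g.
    ``{"Ex": 7, "Ex+In": 21, "In": 5, "NR": 10}``.  Each unit receives a
    single-pulse protocol of ``n_trials`` events and its own generator seeded
    from ``(seed, unit index)``, so the cohort regenerates byte-identically.
    """
    if template is None:
        template = SimUnitConfig(evoked_extra_spikes=1.2)
    ranges = dict(BASELINE_RANGES)
    if baseline_ranges:
        ranges.update(baseline_ranges)
    for label, count in class_counts.items():
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        if count < 0:
            raise ValueError("class counts must be >= 0")
    units = []
    index = 0
    protocol = single_pulse_protocol(n_events=n_trials)
    for label in LABELS:
        for _ in range(class_counts.get(label, 0)):
            rng = np.random.default_rng(np.random.SeedSequence((seed, index)))
            lo, hi = ranges[label]
            rate = float(rng.uniform(lo, hi))
            cfg = _class_config(label, template, rate)
            unit_id = f"u{index:03d}_{label.replace('+', '')}"
            train = simulate_spike_train(cfg, protocol, rng=rng, unit_id=unit_id)
            units.append(
                CohortUnit(
                    unit_id=unit_id, label=label, config=cfg,
                    protocol=protocol, train=train,
                )
            )
            index += 1
    return units
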