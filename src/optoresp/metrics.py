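"""Evoked-response magnitudes: extra spikes, train profiles, graded curves.

The central statistic is *extra spikes*: the mean number of spikes per trial
in the 30 ms following stimulus onset, minus the number expected had the cell
kept firing at its pre-stimulus baseline rate (3-s average).  Train profiles
apply it per pulse position within five-pulse 20-Hz trains and normalize to
the first pulse; graded curves apply it per light power and normalize to the
1-mW response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SpikeTrain
from .psth import DEFAULT_BASELINE_SPAN

__all__ = [
    "TrainResponseProfile",
    "GradedResponse",
    "extra_spikes",
    "baseline_rate_before",
    "train_profile",
    "graded_response",
]

EXTRA_SPIKES_WINDOW = 0.030  # s
TRAIN_PULSE_COUNT = 5
TRAIN_INTERVAL = 0.05  # s, 20 Hz


@dataclass(frozen=True)
class TrainResponseProfile:
    """Per-pulse extra spikes within a pulse train, normalized to pulse 1.

    ``depression_1_to_k = (1 - normalized[k]) * 100`` per cent.  When the
    first-pulse response is not positive the normalization is undefined and
    the profile is flagged ``undefined-normalization`` (normalized values are
    NaN).
    """

    per_pulse_extra_spikes: np.ndarray
    normalized: np.ndarray
    depression_1_to_2: float
    depression_1_to_last: float
    flags: tuple[str, ...] = ()

    @property
    def n_pulses(self) -> int:
        return int(self.per_pulse_extra_spikes.size)


@dataclass(frozen=True)
class GradedResponse:
    """Extra spikes per light power, normalized to the 1-mW response."""

    powers_mW: np.ndarray
    extra_spikes: np.ndarray
    normalized_to_1mW: np.ndarray
    flags: tuple[str, ...] = ()


def _window_counts(train: SpikeTrain, onsets: np.ndarray, window: float) -> int:
    spikes = train.spike_times
    lo = np.searchsorted(spikes, onsets, side="left")
    hi = np.searchsorted(spikes, onsets + window, side="left")
    return int(np.sum(hi - lo))


def baseline_rate_before(
    train: SpikeTrain, onsets: np.ndarray, span: float = DEFAULT_BASELINE_SPAN
) -> float:
    """Mean firing rate (Hz) over the ``span`` seconds before each onset."""
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    spikes = train.spike_times
    lo = np.searchsorted(spikes, onsets - span, side="left")
    hi = np.searchsorted(spikes, onsets, side="left")
    return float(np.sum(hi - lo)) / (span * onsets.size)


def extra_spikes(
    train: SpikeTrain,
    onsets: np.ndarray,
    baseline_mean_rate: float | None = None,
    window: float = EXTRA_SPIKES_WINDOW,
) -> float:
    """Mean evoked spikes per trial above the baseline expectation.

    ``(spikes in [onset, onset + window) summed over trials) / n_trials
    - baseline_mean_rate * window``.  When ``baseline_mean_rate`` is None it
    is measured from the 3 s preceding each onset.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    if onsets.size == 0:
        raise ValueError("at least one stimulus onset is required")
    if baseline_mean_rate is None:
        baseline_mean_rate = baseline_rate_before(train, onsets)
    if baseline_mean_rate < 0:
        raise ValueError("baseline_mean_rate must be >= 0")
    observed = _window_counts(train, onsets, window) / onsets.size
    return observed - baseline_mean_rate * window


def train_profile(
    train: SpikeTrain,
    train_onsets: np.ndarray,
    baseline_mean_rate: float | None = None,
    n_pulses: int = TRAIN_PULSE_COUNT,
    pulse_interval: float = TRAIN_INTERVAL,
    window: float = EXTRA_SPIKES_WINDOW,
) -> TrainResponseProfile:
    """Per-pulse extra-spike profile of repeated pulse trains.

    ``train_onsets`` are the first-pulse onsets of each train presentation.
    The per-pulse window never overlaps the next pulse (it is capped at the
    inter-pulse interval; at the standard 30 ms < 50 ms spacing the full
    window is used).  The baseline for subtraction is measured before the
    first pulse of each train.
    """
    train_onsets = np.atleast_1d(np.asarray(train_onsets, dtype=float))
    if train_onsets.size == 0:
        raise ValueError("at least one train presentation is required")
    window = min(window, pulse_interval)
    if baseline_mean_rate is None:
        baseline_mean_rate = baseline_rate_before(train, train_onsets)
    per_pulse = np.array(
        [
            extra_spikes(
                train,
                train_onsets + k * pulse_interval,
                baseline_mean_rate=baseline_mean_rate,
                window=window,
            )
            for k in range(n_pulses)
        ]
    )
    flags: tuple[str, ...] = ()
    if per_pulse[0] <= 0:
        flags = ("undefined-normalization",)
        normalized = np.full(n_pulses, np.nan)
        dep12 = deplast = float("nan")
    else:
        normalized = per_pulse / per_pulse[0]
        dep12 = (1.0 - normalized[1]) * 100.0 if n_pulses > 1 else 0.0
        deplast = (1.0 - normalized[-1]) * 100.0
    return TrainResponseProfile(
        per_pulse_extra_spikes=per_pulse,
        normalized=normalized,
        depression_1_to_2=dep12,
        depression_1_to_last=deplast,
        flags=flags,
    )


def graded_response(
    train: SpikeTrain,
    events_by_power: dict[float, np.ndarray],
    baseline_mean_rate: float | None = None,
    window: float = EXTRA_SPIKES_WINDOW,
    reference_power_mW: float = 1.0,
) -> GradedResponse:
    """Extra spikes as a function of light power, normalized to 1 mW.

    ``events_by_power`` maps light power (mW) to the stimulus onsets delivered
    at that power; at least three distinct powers are required.  The reference
    response is the measured 1-mW value when present, otherwise linearly
    interpolated between the bracketing powers; if all powers lie on one side
    of 1 mW the nearest power is used and the result is flagged
    ``reference-extrapolated``.
    """
    if len(events_by_power) < 3:
        raise ValueError("graded analysis requires >= 3 distinct powers")
    powers = np.array(sorted(events_by_power), dtype=float)
    if np.any(np.diff(powers) <= 0):
        raise ValueError("powers must be strictly increasing")
    values = np.array(
        [
            extra_spikes(
                train,
                np.asarray(events_by_power[p], dtype=float),
                baseline_mean_rate=baseline_mean_rate,
                window=window,
            )
            for p in powers
        ]
    )
    flags: tuple[str, ...] = ()
    if reference_power_mW in powers:
        ref = values[np.flatnonzero(powers == reference_power_mW)[0]]
    elif powers[0] < reference_power_mW < powers[-1]:
        ref = float(np.interp(reference_power_mW, powers, values))
    else:
        nearest = 0 if powers[0] > reference_power_mW else -1
        ref = values[nearest]
        flags = ("reference-extrapolated",)
    if ref == 0:
        flags = flags + ("undefined-normalization",)
        normalized = np.full(powers.size, np.nan)
    else:
        normalized = values / ref
    return GradedResponse(
        powers_mW=powers, extra_spikes=values, normalized_to_1mW=normalized,
        flags=flags,
    )
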