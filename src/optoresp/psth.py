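"""Trial alignment, PSTH construction and baseline statistics.

The PSTH aggregates spike counts across trials into half-open bins (default
2 ms) on a window around each stimulus onset.  Baseline statistics are taken
over the 3 s preceding the stimulus: the mean firing rate, and the mean and SD
of per-bin *trial-summed* counts, which are what the excitation/inhibition
threshold tests operate on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SpikeTrain

__all__ = ["Psth", "BaselineStats", "compute_psth", "baseline_stats"]

DEFAULT_BIN_WIDTH = 0.002  # s
DEFAULT_BASELINE_SPAN = 3.0  # s of pre-stimulus activity


@dataclass(frozen=True)
class Psth:
    """Peristimulus time histogram.

    ``counts[k]`` is the total number of spikes, summed over all trials, whose
    event-aligned time falls in ``[bin_starts[k], bin_starts[k] + bin_width)``.
    The window spans ``[-pre, post)`` around the event onset.
    """

    bin_width: float
    window: tuple[float, float]  # (pre, post), both positive spans in s
    counts: np.ndarray
    n_trials: int

    def __post_init__(self):
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bin_starts(self) -> np.ndarray:
        """Leading edge of each bin, in seconds relative to event onset."""
        pre, _ = self.window
        return -pre + self.bin_width * np.arange(self.n_bins)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_starts + self.bin_width / 2

    @property
    def rate(self) -> np.ndarray:
        """Per-bin firing rate in Hz: counts / (n_trials * bin_width)."""
        return self.counts / (self.n_trials * self.bin_width)


@dataclass(frozen=True)
class BaselineStats:
    """Pre-stimulus firing statistics of one unit.

    ``bin_mean``/``bin_sd`` are the mean and SD of trial-summed per-bin counts
    over the baseline bins, i.e. on the same scale as ``Psth.counts``;
    ``mean_rate`` is in Hz.
    """

    mean_rate: float
    bin_mean: float
    bin_sd: float
    span: float  # s of baseline used
    n_trials: int


def compute_psth(
    train: SpikeTrain,
    events: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    window: tuple[float, float] = (DEFAULT_BASELINE_SPAN, 0.1),
) -> Psth:
    """Build a PSTH of ``train`` aligned to ``events``.

    Parameters
    ----------
    events : array-like
        Stimulus onsets in seconds; each defines one trial.
    window : (pre, post)
        Positive spans before and after the onset; aligned times in
        ``[-pre, post)`` are counted.
    """
    events = np.atleast_1d(np.asarray(events, dtype=float))
    if events.size == 0:
        raise ValueError("at least one event is required")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    pre, post = window
    if pre < 0 or post < 0 or pre + post <= 0:
        raise ValueError("window spans must be non-negative and non-empty")
    n_bins = int(round((pre + post) / bin_width))
    counts = np.zeros(n_bins)
    spikes = train.spike_times
    for onset in events:
        lo = np.searchsorted(spikes, onset - pre, side="left")
        hi = np.searchsorted(spikes, onset + post, side="left")
        aligned = spikes[lo:hi] - onset
        idx = np.floor((aligned + pre) / bin_width).astype(int)
        # guard against float round-off at the right edge
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(counts, idx, 1)
    return Psth(bin_width=bin_width, window=(pre, post), counts=counts,
                n_trials=int(events.size))


def baseline_stats(psth: Psth, span: float = DEFAULT_BASELINE_SPAN) -> BaselineStats:
    """Baseline statistics from the last ``span`` seconds of pre-stimulus bins.

    Raises ``ValueError`` when the PSTH holds less pre-stimulus time than
    ``span`` (the default 3 s matches the convention the response criteria
    assume).
    """
    pre, _ = psth.window
    if pre + 1e-12 < span:
        raise ValueError(
            f"PSTH has only {pre} s of pre-stimulus time; {span} s required"
        )
    starts = psth.bin_starts
    sel = (starts >= -span - 1e-12) & (starts < -1e-12)
    base = psth.counts[sel]
    if base.size == 0:
        raise ValueError("no baseline bins in PSTH")
    total = float(base.sum())
    mean_rate = total / (base.size * psth.bin_width * psth.n_trials)
    bin_mean = total / base.size
    bin_sd = float(np.std(base, ddof=1)) if base.size > 1 else 0.0
    return BaselineStats(
        mean_rate=mean_rate,
        bin_mean=bin_mean,
        bin_sd=bin_sd,
        span=base.size * psth.bin_width,
        n_trials=psth.n_trials,
    )
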