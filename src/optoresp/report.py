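"""Cohort-level summaries: class fractions, latency statistics, train means.

Conventions follow the usual reporting of opsin-mapping cohorts: class
percentages are rounded to the nearest integer (pie-chart style; raw
fractions are kept alongside), excitation latencies pool Ex cells with the
excitatory peak of Ex+In cells, and train profiles are summarized per pulse
as mean +/- SEM of the per-cell normalized responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ResponseClassification
from .metrics import TrainResponseProfile

__all__ = [
    "CohortSummary",
    "summarize_cohort",
    "latency_histogram",
    "summarize_train",
    "pooled_train_depression",
]

LABELS = ("Ex", "Ex+In", "In", "NR")


@dataclass(frozen=True)
class CohortSummary:
    """Aggregate of per-unit classifications.

    ``percentages`` are nearest-integer; ``fractions`` keep full precision.
    Latency statistics (seconds) pool excitation latencies of Ex and Ex+In
    cells; inhibition onsets are summarized separately.
    """

    counts: dict[str, int]
    percentages: dict[str, int]
    fractions: dict[str, float]
    responsive_percent: int
    n_cells: int
    latency_mean: float | None = None
    latency_sd: float | None = None
    latency_sem: float | None = None
    inhibition_latency_mean: float | None = None
    inhibition_latency_sd: float | None = None
    n_animals: int | None = None  # metadata only

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "counts": dict(self.counts),
            "percentages": dict(self.percentages),
            "fractions": dict(self.fractions),
            "responsive_percent": self.responsive_percent,
            "latency_mean_s": self.latency_mean,
            "latency_sd_s": self.latency_sd,
            "latency_sem_s": self.latency_sem,
            "inhibition_latency_mean_s": self.inhibition_latency_mean,
            "inhibition_latency_sd_s": self.inhibition_latency_sd,
            "n_animals": self.n_animals,
        }


def _stats(values: list[float]):
    if not values:
        return None, None, None
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    sem = sd / np.sqrt(arr.size)
    return mean, sd, float(sem)


def summarize_cohort(
    classifications: Sequence[ResponseClassification],
    n_animals: int | None = None,
) -> CohortSummary:
    """Counts, rounded percentages, responsive percentage, latency stats."""
    classifications = list(classifications)
    if not classifications:
        raise ValueError("at least one classification is required")
    n = len(classifications)
    counts = {lab: 0 for lab in LABELS}
    for c in classifications:
        counts[c.label] += 1
    fractions = {lab: counts[lab] / n for lab in LABELS}
    percentages = {lab: int(round(100.0 * fractions[lab])) for lab in LABELS}
    responsive = int(round(100.0 * (n - counts["NR"]) / n))
    ex_lat = [
        c.excitation_latency
        for c in classifications
        if c.label in ("Ex", "Ex+In") and c.excitation_latency is not None
    ]
    in_lat = [
        c.inhibition_onset
        for c in classifications
        if c.label in ("In", "Ex+In") and c.inhibition_onset is not None
    ]
    lat_mean, lat_sd, lat_sem = _stats(ex_lat)
    inh_mean, inh_sd, _ = _stats(in_lat)
    return CohortSummary(
        counts=counts,
        percentages=percentages,
        fractions=fractions,
        responsive_percent=responsive,
        n_cells=n,
        latency_mean=lat_mean,
        latency_sd=lat_sd,
        latency_sem=lat_sem,
        inhibition_latency_mean=inh_mean,
        inhibition_latency_sd=inh_sd,
        n_animals=n_animals,
    )


def latency_histogram(
    latencies: Sequence[float], bin_width: float = 0.0005
) -> pd.DataFrame:
    """Half-open latency histogram as a table (bin_start_s, bin_end_s, count)."""
    latencies = np.asarray(list(latencies), dtype=float)
    if latencies.size == 0:
        raise ValueError("at least one latency is required")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    idx = np.floor(latencies / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    starts = (np.arange(lo, hi + 1)) * bin_width
    return pd.DataFrame(
        {"bin_start_s": starts, "bin_end_s": starts + bin_width, "count": counts}
    )


def summarize_train(
    profiles: Sequence[TrainResponseProfile],
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Per-pulse mean and SEM of per-cell normalized train responses.

    Profiles with undefined normalization are excluded (flagged).  A single
    profile yields SEM 0 with a ``single-profile`` flag.
    """
    usable = [p for p in profiles if "undefined-normalization" not in p.flags]
    flags: tuple[str, ...] = ()
    if len(usable) < len(list(profiles)):
        flags += ("excluded-undefined-profiles",)
    if not usable:
        raise ValueError("no usable train profiles")
    mat = np.vstack([p.normalized for p in usable])
    mean = mat.mean(axis=0)
    if mat.shape[0] == 1:
        sem = np.zeros(mat.shape[1])
        flags += ("single-profile",)
    else:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    return mean, sem, flags


def pooled_train_depression(
    profiles: Sequence[TrainResponseProfile],
) -> tuple[float, float]:
    """Depression percentages from pooled (cohort-mean) per-pulse responses.

    Normalizing the cohort-mean per-pulse extra spikes by the cohort-mean
    first-pulse response avoids the small-sample ratio bias (+CV^2 of the
    per-cell pulse-1 estimate) that per-cell normalization carries, so it is
    the estimator of choice for parameter recovery.  Returns
    ``(depression_1_to_2, depression_1_to_last)`` in per cent.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles")
    mat = np.vstack([p.per_pulse_extra_spikes for p in profiles])
    mean = mat.mean(axis=0)
    if mean[0] <= 0:
        return float("nan"), float("nan")
    normalized = mean / mean[0]
    dep12 = (1.0 - normalized[1]) * 100.0 if mean.size > 1 else 0.0
    return float(dep12), float((1.0 - normalized[-1]) * 100.0)
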