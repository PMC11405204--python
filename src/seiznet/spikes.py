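"""Spike extraction and firing-rate / population-burst summaries.

Spike detection uses the de facto MEA convention: a per-channel
threshold at ``k`` times the robust noise SD (median absolute value /
0.6745), crossed in either polarity, with events closer than a dead
time merged to the larger absolute peak. The threshold is relative, so
detection is invariant to positive rescaling of the trace.

Population bursts are detected directly in functional-connectivity bin
space: a bin is a burst bin when the population spike count exceeds
``mean + rate_sd · SD`` *and* at least ``frac_active`` of electrodes
fire in it. Runs of burst bins are merged into intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal as _signal

from .preprocess import VoltageRecording

if TYPE_CHECKING:  # pragma: no cover
    from .connectivity import BinnedSpikeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrainSet",
    "MFRSummary",
    "BurstMask",
    "detect_spikes",
    "mean_firing_rate",
    "normalize_mfr",
    "detect_population_bursts",
]


@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike times over a common duration.

    ``trains`` maps positionally to ``electrode_ids``; every time lies in
    ``[0, duration)`` and each train is sorted ascending.
    """

    trains: list
    duration: float
    electrode_ids: np.ndarray = None
    provenance: str = "loaded"  # detected | loaded | simulated
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        self.trains = [np.asarray(t, dtype=float).ravel() for t in self.trains]
        for t in self.trains:
            if t.size and (t.min() < 0 or t.max() >= self.duration):
                raise ValueError("spike times must lie in [0, duration)")
            if t.size > 1 and np.any(np.diff(t) < 0):
                raise ValueError("spike times must be sorted ascending")
        if self.electrode_ids is None:
            self.electrode_ids = np.arange(len(self.trains))
        self.electrode_ids = np.asarray(self.electrode_ids)
        if len(self.electrode_ids) != len(self.trains):
            raise ValueError("electrode_ids length must match trains")

    @property
    def n_electrodes(self) -> int:
        return len(self.trains)

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.trains])


@dataclass
class MFRSummary:
    """Mean firing rate per electrode plus the well-level mean."""

    per_electrode_hz: np.ndarray
    well_mean_hz: float
    normalized_ratio: float | None = None
    baseline_undefined: bool = False


@dataclass
class BurstMask:
    """Burst intervals plus the per-bin flags at FC bin resolution."""

    intervals: np.ndarray  # (n_intervals, 2) start/end seconds
    bin_flags: np.ndarray  # bool per bin
    bin_width: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        self.bin_flags = np.asarray(self.bin_flags, dtype=bool)
        if self.intervals.shape[0] > 1:
            starts = self.intervals[:, 0]
            if np.any(np.diff(starts) < 0):
                raise ValueError("burst intervals must be sorted")
            if np.any(self.intervals[1:, 0] < self.intervals[:-1, 1]):
                raise ValueError("burst intervals must not overlap")

    @property
    def n_bursts(self) -> int:
        return self.intervals.shape[0]


def detect_spikes(
    rec: VoltageRecording,
    k: float = 5.5,
    dead_time: float = 0.001,
) -> SpikeTrainSet:
    """Extract multi-unit spike times by robust-SD threshold crossing.

    Parameters
    ----------
    rec : VoltageRecording
        Must be conditioned (stage ``filtered`` or ``zscored``).
    k : float
        Threshold multiplier on the robust noise SD
        ``median(|x|) / 0.6745`` of each channel.
    dead_time : float
        Minimum separation between events in seconds; closer events are
        merged to the larger absolute peak.
    """
    if rec.stage not in ("filtered", "zscored"):
        raise ValueError(
            f"detect_spikes requires a conditioned recording "
            f"(stage 'filtered' or 'zscored'), got stage '{rec.stage}'"
        )
    min_dist = max(1, int(round(dead_time * rec.fs)))
    trains = []
    for ch in range(rec.n_channels):
        x = rec.data[ch]
        noise_sd = np.median(np.abs(x)) / 0.6745
        if noise_sd == 0:
            trains.append(np.empty(0))
            continue
        thr = k * noise_sd
        peaks, _ = _signal.find_peaks(np.abs(x), height=thr, distance=min_dist)
        trains.append(peaks / rec.fs)
    return SpikeTrainSet(
        trains=trains,
        duration=rec.duration,
        electrode_ids=rec.electrode_ids,
        provenance="detected",
    )


def mean_firing_rate(trains: SpikeTrainSet) -> MFRSummary:
    """Per-electrode spike count / duration, and the well mean."""
    rates = trains.counts() / trains.duration
    return MFRSummary(per_electrode_hz=rates, well_mean_hz=float(rates.mean()))


def normalize_mfr(day: MFRSummary, baseline: MFRSummary) -> MFRSummary:
    """Normalize a day's well-mean MFR to a pre-treatment baseline.

    A zero baseline makes the ratio undefined; the result is flagged
    rather than silently divided.
    """
    out = MFRSummary(
        per_electrode_hz=day.per_electrode_hz.copy(),
        well_mean_hz=day.well_mean_hz,
    )
    if baseline.well_mean_hz <= 0:
        out.baseline_undefined = True
        out.normalized_ratio = None
        logger.warning("normalize_mfr: zero baseline well mean; ratio undefined")
    else:
        out.normalized_ratio = day.well_mean_hz / baseline.well_mean_hz
    return out


def detect_population_bursts(
    binned: "BinnedSpikeMatrix",
    frac_active: float = 0.25,
    rate_sd: float = 3.0,
) -> BurstMask:
    """Flag bins of highly synchronous population firing.

    A bin is a burst bin when the population count exceeds
    ``mean + rate_sd · SD`` of the per-bin population count *and* the
    fraction of electrodes with ≥ 1 spike is at least ``frac_active``.
    """
    counts = binned.counts
    n_elec, n_bins = counts.shape
    pop = counts.sum(axis=0)
    active_frac = (counts > 0).sum(axis=0) / n_elec
    thr = pop.mean() + rate_sd * pop.std()
    flags = (pop > thr) & (active_frac >= frac_active)
    intervals = []
    w = binned.width
    in_burst = False
    for b in range(n_bins):
        if flags[b] and not in_burst:
            start = b * w
            in_burst = True
        elif not flags[b] and in_burst:
            intervals.append((start, b * w))
            in_burst = False
    if in_burst:
        intervals.append((start, n_bins * w))
    return BurstMask(
        intervals=np.array(intervals, dtype=float).reshape(-1, 2),
        bin_flags=flags,
        bin_width=w,
        params={"frac_active": frac_active, "rate_sd": rate_sd},
    )
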