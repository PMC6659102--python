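"""Single-unit firing metrics: ISI-based burst detection and rate decomposition.

A burst is two or more action potentials at an instantaneous rate of at
least 20 Hz, i.e. maximal runs of consecutive inter-spike intervals no longer
than ``max_isi_s`` (20-50 ms by convention; 50 ms — the reciprocal of the
20 Hz criterion — is the default). Firing is decomposed into total, single
(out-of-burst), and burst rates, plus the mean intra-burst rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import TimeSeries
from .exceptions import ParameterError, ShapeError
from .spikefield import SpikeTrain

__all__ = [
    "Burst",
    "BurstSet",
    "FiringMetrics",
    "detect_bursts",
    "firing_metrics",
    "spike_half_width",
]

ISI_RANGE_S = (0.02, 0.05)


@dataclass(frozen=True)
class Burst:
    start_s: float
    end_s: float
    n_spikes: int


@dataclass
class BurstSet:
    bursts: list[Burst]
    max_isi_s: float
    source: str = ""

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def n_spikes_in_bursts(self) -> int:
        return sum(b.n_spikes for b in self.bursts)


@dataclass
class FiringMetrics:
    total_rate: float  # Hz, all spikes
    single_rate: float  # Hz, spikes outside bursts
    burst_rate: float  # Hz, bursts as events
    intraburst_rate: float  # Hz, mean of (n-1)/(end-start) over bursts; NaN if none
    duration_s: float
    n_spikes: int
    n_bursts: int


def detect_bursts(spikes: SpikeTrain, max_isi_s: float = 0.05) -> BurstSet:
    """Greedy left-to-right run-length burst detection on the ISI sequence.

    Maximal runs of consecutive ISIs <= ``max_isi_s`` become bursts (>= 2
    spikes each); burst boundaries are the first/last spike of the run, with
    no padding. Values of ``max_isi_s`` outside the conventional 20-50 ms
    range are accepted with a warning.
    """
    if max_isi_s <= 0:
        raise ParameterError("max_isi_s must be positive")
    if not ISI_RANGE_S[0] <= max_isi_s <= ISI_RANGE_S[1]:
        warnings.warn(
            f"max_isi_s={max_isi_s} s outside the conventional "
            f"{ISI_RANGE_S[0]}-{ISI_RANGE_S[1]} s range",
            stacklevel=2,
        )
    t = spikes.times
    bursts: list[Burst] = []
    if t.size >= 2:
        in_burst = np.diff(t) <= max_isi_s
        i = 0
        while i < in_burst.size:
            if in_burst[i]:
                j = i
                while j < in_burst.size and in_burst[j]:
                    j += 1
                bursts.append(Burst(float(t[i]), float(t[j]), j - i + 1))
                i = j + 1
            else:
                i += 1
    return BurstSet(bursts=bursts, max_isi_s=max_isi_s, source=spikes.source_id)


def firing_metrics(
    spikes: SpikeTrain, bursts: BurstSet, duration_s: float
) -> FiringMetrics:
    """Decompose firing into total/single/burst rates over ``duration_s``."""
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    n_total = spikes.n
    n_in_bursts = bursts.n_spikes_in_bursts
    if n_in_bursts > n_total:
        raise ParameterError("bursts contain more spikes than the train")
    intraburst = [
        (b.n_spikes - 1) / (b.end_s - b.start_s)
        for b in bursts.bursts
        if b.end_s > b.start_s
    ]
    return FiringMetrics(
        total_rate=n_total / duration_s,
        single_rate=(n_total - n_in_bursts) / duration_s,
        burst_rate=bursts.n_bursts / duration_s,
        intraburst_rate=float(np.mean(intraburst)) if intraburst else float("nan"),
        duration_s=duration_s,
        n_spikes=n_total,
        n_bursts=bursts.n_bursts,
    )


def spike_half_width(waveform: TimeSeries) -> float:
    """Full width at half amplitude of a single spike waveform, in ms.

    Baseline is the median of the first 20 % of the window; polarity is
    auto-detected from the larger absolute deviation. Crossing times are
    linearly interpolated between samples.
    """
    x = waveform.samples
    n_base = max(1, int(0.2 * x.size))
    baseline = float(np.median(x[:n_base]))
    dev = x - baseline
    if np.abs(dev).max() == 0:
        raise ShapeError("waveform has no peak above baseline")
    if np.abs(dev.min()) > np.abs(dev.max()):
        dev = -dev
    peak_idx = int(np.argmax(dev))
    half = 0.5 * dev[peak_idx]
    if half <= 0:
        raise ShapeError("non-positive peak amplitude")
    # walk left and right from the peak to the half-amplitude crossings
    left = peak_idx
    while left > 0 and dev[left] > half:
        left -= 1
    if dev[left] > half:
        raise ShapeError("left flank never drops to half amplitude")
    right = peak_idx
    while right < dev.size - 1 and dev[right] > half:
        right += 1
    if dev[right] > half:
        raise ShapeError("right flank never drops to half amplitude")
    t_left = left + (half - dev[left]) / (dev[left + 1] - dev[left])
    t_right = right - 1 + (half - dev[right - 1]) / (dev[right] - dev[right - 1])
    return float((t_right - t_left) / waveform.sampling_rate * 1e3)
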