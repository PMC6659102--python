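"""Spike extraction from extracellular traces and spike-field coupling.

Multi-unit spike times are pulled from the high-pass (or 300-4500 Hz
band-pass) filtered trace by a threshold of 5 robust standard deviations
(median absolute deviation / 0.6745, which unlike the raw sd is not inflated
by the spikes themselves). Each supra-threshold excursion contributes one
spike at the time of its extremum; detections within a refractory interval
are merged.

The spike-triggered average (STA) aligns 1-s windows of the 0.2-50 Hz LFP on
every spike; the means of the STA over the 250 ms before and after the spike
summarise spike-locked slow-wave deflections. Recordings with spike rates
below 1 Hz are flagged excluded, mirroring the sparse-MUA exclusion rule.
Peri-spike band power is tracked in twenty 100-ms bins spanning [-1, +1] s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FilterSpec, TimeSeries, apply_filter
from .emd import BandSignal
from .exceptions import DataError, DegenerateInputError, EmptyResultError
from .spectral import relative_amplitude

__all__ = [
    "SpikeTrain",
    "STAResult",
    "SpikePowerProfile",
    "detect_spikes",
    "robust_sd",
    "spike_triggered_average",
    "spike_power_profile",
    "MUA_BANDPASS",
    "MUA_HIGHPASS",
    "STA_LFP_BAND",
]

#: Band-pass used for spike-time extraction from raw extracellular signals.
MUA_BANDPASS = FilterSpec("bandpass", (300.0, 4500.0))
#: High-pass variant used when aligning MUA to the STA.
MUA_HIGHPASS = FilterSpec("highpass", (500.0,))
#: LFP band for the spike-triggered average.
STA_LFP_BAND = (0.2, 50.0)


@dataclass
class SpikeTrain:
    """Ordered spike times (seconds) with detection provenance."""

    times: np.ndarray
    source_id: str = ""
    detection: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        if t.ndim != 1:
            raise DataError("spike times must be 1-D")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise DataError("spike times must be strictly increasing")
        self.times = t

    @property
    def n(self) -> int:
        return self.times.size

    def rate(self, duration_s: float) -> float:
        return self.n / duration_s


@dataclass
class STAResult:
    lags: np.ndarray  # seconds, symmetric about 0
    mean_lfp: np.ndarray  # mV per lag
    n_spikes: int
    pre_mean: float  # mean over [-0.25, 0) s
    post_mean: float  # mean over [0, 0.25) s
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class SpikePowerProfile:
    band: str
    bin_edges: np.ndarray  # 21 edges, -1..+1 s in 0.1 s steps
    power_per_bin: np.ndarray  # 20 values, dimensionless
    n_spikes: int


def robust_sd(x: np.ndarray) -> float:
    """MAD-based sd estimate: median(|x - median|) / 0.6745."""
    med = np.median(x)
    return float(np.median(np.abs(x - med)) / 0.6745)


def detect_spikes(
    trace: TimeSeries,
    filter: FilterSpec = MUA_BANDPASS,
    threshold_sd: float = 5.0,
    refractory_s: float = 0.001,
    robust: bool = True,
) -> SpikeTrain:
    """Threshold spike detection on the filtered trace.

    The threshold is ``threshold_sd`` times the (robust) sd of the filtered
    signal; each contiguous supra-threshold excursion of either polarity
    yields one spike at its absolute extremum, and extrema closer than
    ``refractory_s`` are merged keeping the larger one.
    """
    filt = apply_filter(trace, filter)
    x = filt.samples
    sd = robust_sd(x) if robust else float(x.std())
    if sd == 0.0:
        raise DegenerateInputError("filtered trace has zero spread; no threshold")
    thr = threshold_sd * sd
    above = np.abs(x) > thr
    if not above.any():
        return SpikeTrain(
            np.empty(0),
            source_id=trace.channel_id,
            detection=_provenance(filter, threshold_sd, refractory_s, sd),
        )
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, x.size]
    peak_idx = np.array(
        [a + int(np.argmax(np.abs(x[a:b]))) for a, b in zip(starts, stops)]
    )
    peak_amp = np.abs(x[peak_idx])
    # merge detections within the refractory interval, keeping the larger
    min_gap = int(round(refractory_s * trace.sampling_rate))
    keep: list[int] = []
    for i in np.argsort(-peak_amp):
        if all(abs(peak_idx[i] - peak_idx[j]) > min_gap for j in keep):
            keep.append(i)
    idx = np.sort(peak_idx[keep])
    times = trace.t0 + idx / trace.sampling_rate
    return SpikeTrain(
        times,
        source_id=trace.channel_id,
        detection=_provenance(filter, threshold_sd, refractory_s, sd),
    )


def _provenance(
    filter: FilterSpec, threshold_sd: float, refractory_s: float, sd: float
) -> dict:
    return {
        "filter": {"kind": filter.kind, "cutoffs": filter.cutoffs, "order": filter.order},
        "threshold_sd": threshold_sd,
        "refractory_s": refractory_s,
        "estimated_sd": sd,
    }


def _usable_indices(
    lfp: TimeSeries, spikes: SpikeTrain, window_s: float
) -> np.ndarray:
    """Center indices for spikes whose full window lies inside the trace."""
    half = int(round(window_s * lfp.sampling_rate))
    centers = np.round((spikes.times - lfp.t0) * lfp.sampling_rate).astype(int)
    ok = (centers - half >= 0) & (centers + half < lfp.n)
    return centers[ok]


def spike_triggered_average(
    lfp: TimeSeries,
    spikes: SpikeTrain,
    window_s: float = 1.0,
    lfp_band: tuple[float, float] = STA_LFP_BAND,
    min_rate_hz: float = 1.0,
    summary_window_s: float = 0.25,
) -> STAResult:
    """Average 0.2-50 Hz LFP segments aligned on spikes.

    Spikes within one window of either trace edge are skipped. The result is
    flagged ``excluded`` (but still returned) when the spike rate over the
    trace is below ``min_rate_hz``.
    """
    if spikes.n == 0:
        raise EmptyResultError("no spikes to average")
    filtered = apply_filter(lfp, FilterSpec("bandpass", lfp_band))
    half = int(round(window_s * lfp.sampling_rate))
    centers = _usable_indices(lfp, spikes, window_s)
    if centers.size == 0:
        raise EmptyResultError("no spike has a full window inside the trace")
    offsets = np.arange(-half, half + 1)
    segs = filtered.samples[centers[:, None] + offsets[None, :]]
    mean_lfp = segs.mean(axis=0)
    lags = offsets / lfp.sampling_rate
    pre = (lags >= -summary_window_s) & (lags < 0)
    post = (lags >= 0) & (lags < summary_window_s)
    rate = spikes.n / lfp.duration
    excluded = rate < min_rate_hz
    return STAResult(
        lags=lags,
        mean_lfp=mean_lfp,
        n_spikes=int(centers.size),
        pre_mean=float(mean_lfp[pre].mean()),
        post_mean=float(mean_lfp[post].mean()),
        excluded=excluded,
        exclusion_reason=(
            f"spike rate {rate:.3g} Hz below {min_rate_hz} Hz" if excluded else ""
        ),
    )


def spike_power_profile(
    band: BandSignal,
    spikes: SpikeTrain,
    window_s: float = 1.0,
    bin_s: float = 0.1,
    t0: float = 0.0,
) -> SpikePowerProfile:
    """Average relative band power in 100-ms bins around each spike.

    For every spike with a full [-1, +1] s window inside the trace, the band
    signal restricted to each bin is z-scored against the raw-LFP sd and its
    mean square taken; bins are then averaged across spikes. Windows of
    nearby spikes may overlap; each spike contributes independently.
    """
    if spikes.n == 0:
        raise EmptyResultError("no spikes")
    rate = band.sampling_rate
    half = int(round(window_s * rate))
    per_bin = int(round(bin_s * rate))
    n_bins = int(round(2 * window_s / bin_s))
    centers = np.round((spikes.times - t0) * rate).astype(int)
    centers = centers[(centers - half >= 0) & (centers + half < band.samples.size)]
    if centers.size == 0:
        raise EmptyResultError("no spike has a full window inside the band signal")
    if band.source_sd <= 0:
        raise DegenerateInputError("source_sd must be positive")
    power = np.zeros(n_bins)
    for c in centers:
        seg = band.samples[c - half : c - half + n_bins * per_bin]
        bins = seg.reshape(n_bins, per_bin)
        z = (bins - bins.mean(axis=1, keepdims=True)) / band.source_sd
        power += np.mean(z * z, axis=1)
    power /= centers.size
    edges = -window_s + bin_s * np.arange(n_bins + 1)
    return SpikePowerProfile(
        band=band.band.label,
        bin_edges=edges,
        power_per_bin=power,
        n_spikes=int(centers.size),
    )
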