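"""Welch PSD, relative band power, and band occurrence frequency.

Two band statistics quantify oscillatory content of a decomposed LFP:

* **average relative power** — the band signal is z-scored against the
  standard deviation of the *raw* LFP (normalising out across-animal
  variations in overall signal size), squared, and averaged over samples.
  A band identical to its source scores 1; a band carrying half the source
  amplitude scores 0.25.
* **band occurrence frequency** — the band signal is z-scored against its
  *own* sd, cycles are delimited by consecutive upward zero crossings, and a
  cycle counts when its peak |z| exceeds a threshold (default 2 sd: a pure
  sinusoid peaks at z = sqrt(2) < 2, so a constant-amplitude tone scores ~0
  and only amplitude excursions — bursts — are counted). Count / duration
  gives the occurrence frequency in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .core import TimeSeries
from .emd import BandSignal
from .exceptions import DegenerateInputError, ParameterError

__all__ = [
    "PSDEstimate",
    "BandPowerResult",
    "OccurrenceResult",
    "welch_psd",
    "relative_amplitude",
    "average_relative_power",
    "band_occurrence_frequency",
    "spectrogram",
]


@dataclass
class PSDEstimate:
    freqs: np.ndarray
    density: np.ndarray  # power per Hz
    window_len: int
    overlap: float
    window_kind: str

    def total_power(self, f_low: float = 0.0, f_high: float | None = None) -> float:
        """Integral of the density over [f_low, f_high] (trapezoid rule)."""
        hi = self.freqs[-1] if f_high is None else f_high
        mask = (self.freqs >= f_low) & (self.freqs <= hi)
        return float(np.trapezoid(self.density[mask], self.freqs[mask]))


@dataclass
class BandPowerResult:
    band: str
    relative_amplitude: np.ndarray  # z-scored, dimensionless
    average_relative_power: float
    duration: float


@dataclass
class OccurrenceResult:
    band: str
    cycle_count: int
    duration: float
    occurrence_frequency: float  # Hz = cycle_count / duration
    threshold_sd: float


def welch_psd(
    trace: TimeSeries,
    window_len: int = 2048,
    overlap: float = 0.5,
    window_kind: str = "hann",
) -> PSDEstimate:
    """Welch power spectral density with a Hann(2048), 50 %-overlap default.

    At 10 kHz sampling the default window gives a ~4.88 Hz bin width.
    """
    if trace.n < window_len:
        raise ParameterError(
            f"trace ({trace.n} samples) shorter than one window ({window_len})"
        )
    if not 0 <= overlap < 1:
        raise ParameterError("overlap must be in [0, 1)")
    freqs, density = _sig.welch(
        trace.samples,
        fs=trace.sampling_rate,
        window=window_kind,
        nperseg=window_len,
        noverlap=int(round(overlap * window_len)),
        detrend="constant",
    )
    return PSDEstimate(freqs, density, window_len, overlap, window_kind)


def relative_amplitude(band: BandSignal) -> np.ndarray:
    """Band samples centred on their mean, divided by the raw-LFP sd."""
    if band.source_sd <= 0:
        raise DegenerateInputError("source_sd must be positive")
    return (band.samples - band.samples.mean()) / band.source_sd


def average_relative_power(band: BandSignal) -> float:
    """Mean of squared relative amplitude (sum z^2 / N); dimensionless."""
    z = relative_amplitude(band)
    return float(np.mean(z * z))


def band_power_result(band: BandSignal) -> BandPowerResult:
    z = relative_amplitude(band)
    return BandPowerResult(
        band=band.band.label,
        relative_amplitude=z,
        average_relative_power=float(np.mean(z * z)),
        duration=band.duration,
    )


def _upward_crossings(z: np.ndarray) -> np.ndarray:
    neg = z < 0
    return np.flatnonzero(neg[:-1] & ~neg[1:]) + 1


def band_occurrence_frequency(
    band: BandSignal, threshold_sd: float = 2.0
) -> OccurrenceResult:
    """Count cycles whose peak |z| exceeds ``threshold_sd`` own-sd units.

    A cycle spans consecutive upward zero crossings of the band z-scored
    against its own mean and sd (this statistic, unlike relative power, is
    normalised per band).
    """
    x = band.samples
    sd = x.std()
    if sd == 0.0:
        raise DegenerateInputError("flat band signal")
    z = (x - x.mean()) / sd
    ups = _upward_crossings(z)
    if ups.size < 2:
        raise DegenerateInputError("band has fewer than 2 upward zero crossings")
    count = 0
    for a, b in zip(ups[:-1], ups[1:]):
        if np.abs(z[a:b]).max() > threshold_sd:
            count += 1
    duration = band.duration
    return OccurrenceResult(
        band=band.band.label,
        cycle_count=count,
        duration=duration,
        occurrence_frequency=count / duration,
        threshold_sd=threshold_sd,
    )


def spectrogram(
    trace: TimeSeries, window_s: float = 0.5, overlap: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Basic running-window spectrogram (display utility).

    Returns (freqs, times, power). Hann-tapered; for multitaper-grade leakage
    control use a dedicated package.
    """
    nper = max(16, int(round(window_s * trace.sampling_rate)))
    f, t, s = _sig.spectrogram(
        trace.samples,
        fs=trace.sampling_rate,
        nperseg=nper,
        noverlap=int(round(overlap * nper)),
    )
    return f, t, s
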