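"""Core domain types, trace I/O, filtering and segmentation.

Conventions used throughout the package:

* time is in seconds, ``t = 0`` at trace start (``t0`` records an offset);
* sample indices are 0-based; every time window is half-open ``[start, end)``;
* voltages are mV, currents are pA.

Two on-disk formats are supported, both plain text or raw little-endian
binary with a JSON sidecar so they stay language-agnostic:

* ``csv``    — two columns ``time_s,value`` with a header, plus
  ``<stem>.meta.json`` carrying ``sampling_rate_hz``, ``units``, ``channel_id``;
* ``rawbin`` — ``<stem>.f64`` little-endian float64 samples plus the same
  sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import signal as _sig

from .exceptions import BoundsError, DataError, FormatError, ParameterError

__all__ = [
    "TimeSeries",
    "BandDefinition",
    "FilterSpec",
    "CANONICAL_BANDS",
    "read_trace",
    "write_trace",
    "bandpass_filter",
    "apply_filter",
    "segment",
]

Units = Literal["mV", "pA"]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled voltage (mV) or current (pA) trace.

    Parameters
    ----------
    samples : ndarray
        Finite float64 samples, length >= 2.
    sampling_rate : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds (default 0).
    units : {"mV", "pA"}
    channel_id : str
        Free-form provenance label.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    units: Units = "mV"
    channel_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", arr)
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if arr.ndim != 1 or arr.size < 2:
            raise DataError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(arr)):
            raise DataError("samples contain non-finite values")
        if self.units not in ("mV", "pA"):
            raise ParameterError(f"unsupported units {self.units!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n / rate; the trailing sample's bin counts)."""
        return self.n / self.sampling_rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.sampling_rate

    @property
    def nyquist(self) -> float:
        return self.sampling_rate / 2.0

    def with_samples(self, samples: np.ndarray) -> "TimeSeries":
        """Same metadata, new sample values (must keep the length)."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass(frozen=True)
class BandDefinition:
    """A named LFP frequency band [f_low, f_high] in Hz."""

    label: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ParameterError("require 0 < f_low < f_high")

    def contains(self, freq_hz: float) -> bool:
        return self.f_low <= freq_hz <= self.f_high


#: The three oscillation bands used for hippocampal LFP analysis.
CANONICAL_BANDS: dict[str, BandDefinition] = {
    "theta": BandDefinition("theta", 5.0, 14.0),
    "low_gamma": BandDefinition("low_gamma", 25.0, 55.0),
    "high_gamma": BandDefinition("high_gamma", 56.0, 120.0),
}


@dataclass(frozen=True)
class FilterSpec:
    """An IIR filter specification applied zero-phase by default.

    ``cutoffs`` is a single frequency for lowpass/highpass and an ordered pair
    for bandpass, all in Hz and strictly below the Nyquist frequency of the
    trace the filter is applied to.
    """

    kind: Literal["lowpass", "highpass", "bandpass"]
    cutoffs: tuple[float, ...]
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in np.atleast_1d(self.cutoffs))
        object.__setattr__(self, "cutoffs", cuts)
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        want = 2 if self.kind == "bandpass" else 1
        if len(cuts) != want:
            raise ParameterError(f"{self.kind} filter needs {want} cutoff(s)")
        if any(c <= 0 for c in cuts):
            raise ParameterError("cutoffs must be positive")
        if want == 2 and not cuts[0] < cuts[1]:
            raise ParameterError("bandpass cutoffs must be ordered")
        if self.order < 1:
            raise ParameterError("order must be >= 1")

    def sos(self, sampling_rate: float) -> np.ndarray:
        nyq = sampling_rate / 2.0
        if max(self.cutoffs) >= nyq:
            raise ParameterError(
                f"cutoff {max(self.cutoffs)} Hz not below Nyquist {nyq} Hz"
            )
        wn = self.cutoffs[0] if len(self.cutoffs) == 1 else list(self.cutoffs)
        return _sig.butter(self.order, wn, btype=self.kind, fs=sampling_rate, output="sos")


# ---------------------------------------------------------------------------
# I/O


def _sidecar_path(path: Path) -> Path:
    return path.parent / (path.stem + ".meta.json")


def _read_sidecar(path: Path) -> dict:
    meta_path = _sidecar_path(path)
    if not meta_path.exists():
        raise FormatError(f"missing sidecar metadata file {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"unparseable sidecar {meta_path}: {exc}") from exc
    if "sampling_rate_hz" not in meta or "units" not in meta:
        raise FormatError(f"sidecar {meta_path} lacks sampling_rate_hz/units")
    return meta


def read_trace(path: str | Path, format: str = "csv") -> TimeSeries:
    """Read a trace plus its JSON sidecar metadata.

    ``format="csv"`` expects two header columns ``time_s,value``;
    ``format="rawbin"`` expects little-endian float64 samples in ``<stem>.f64``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta = _read_sidecar(path)
    if format == "csv":
        data = np.genfromtxt(path, delimiter=",", names=True)
        if data.dtype.names is None or "value" not in data.dtype.names:
            raise FormatError(f"{path} lacks a 'value' column")
        samples = np.asarray(data["value"], dtype=np.float64)
    elif format == "rawbin":
        samples = np.fromfile(path, dtype="<f8")
    else:
        raise ParameterError(f"unknown format {format!r}")
    if samples.size and not np.all(np.isfinite(samples)):
        raise DataError(f"{path} contains non-finite samples")
    try:
        return TimeSeries(
            samples=samples,
            sampling_rate=float(meta["sampling_rate_hz"]),
            t0=float(meta.get("t0_s", 0.0)),
            units=meta["units"],
            channel_id=str(meta.get("channel_id", path.stem)),
        )
    except (TypeError, ValueError) as exc:
        raise FormatError(f"invalid metadata for {path}: {exc}") from exc


def write_trace(trace: TimeSeries, path: str | Path, format: str = "csv") -> Path:
    """Write a trace and its sidecar; round-trips bit-exactly for both formats."""
    path = Path(path)
    meta = {
        "sampling_rate_hz": trace.sampling_rate,
        "units": trace.units,
        "channel_id": trace.channel_id,
        "t0_s": trace.t0,
        "n_samples": trace.n,
        "byte_order": "little-endian",
    }
    if format == "csv":
        times = trace.times
        with open(path, "w") as fh:
            fh.write("time_s,value\n")
            for t, v in zip(times, trace.samples):
                fh.write(f"{float(t)!r},{float(v)!r}\n")
    elif format == "rawbin":
        trace.samples.astype("<f8").tofile(path)
    else:
        raise ParameterError(f"unknown format {format!r}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


# ---------------------------------------------------------------------------
# Filtering and segmentation


def apply_filter(trace: TimeSeries, spec: FilterSpec) -> TimeSeries:
    """Apply an IIR Butterworth filter; zero-phase (forward-backward) by default.

    Zero-phase application squares the magnitude response and cancels group
    delay, which the spike-triggered-average latency analysis relies on.
    """
    sos = spec.sos(trace.sampling_rate)
    if spec.zero_phase:
        out = _sig.sosfiltfilt(sos, trace.samples)
    else:
        out = _sig.sosfilt(sos, trace.samples)
    return trace.with_samples(out)


def bandpass_filter(trace: TimeSeries, spec: FilterSpec) -> TimeSeries:
    """Alias of :func:`apply_filter` kept for the band-pass reading of the API."""
    return apply_filter(trace, spec)


def segment(trace: TimeSeries, t_start: float, t_end: float) -> TimeSeries:
    """Extract the half-open window ``[t_start, t_end)`` as a new trace.

    Times are absolute (relative to ``trace.t0``). The returned trace restarts
    its clock at ``t0 = 0`` so that segmentation composes:
    ``segment(segment(x, a, c), 0, b - a) == segment(x, a, b)``.
    """
    eps = 1e-9
    if not (trace.t0 - eps <= t_start < t_end <= trace.t_end + eps):
        raise BoundsError(
            f"window [{t_start}, {t_end}) outside trace [{trace.t0}, {trace.t_end})"
        )
    i0 = int(np.floor((t_start - trace.t0) * trace.sampling_rate + 0.5))
    count = int(np.floor((t_end - t_start) * trace.sampling_rate + eps))
    if i0 + count > trace.n:
        count = trace.n - i0
    if count < 2:
        raise BoundsError("window too short: fewer than 2 samples")
    return replace(trace, samples=trace.samples[i0 : i0 + count], t0=0.0)
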