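"""Whole-cell synaptic current analysis.

Spontaneous events are found with the classic optimally-scaled sliding
template detector: at every sample the template is least-squares fitted
(scale + offset) to the data window, and the detection criterion is the
scale divided by the standard error of the fit. Evoked responses are
characterised by 20-80 % rise time and a monoexponential decay fit
``y(t) = A * exp(-t / tau)``; pharmacological component splits (e.g. the
N-type-channel-dependent fraction blocked by omega-conotoxin GVIA) are the
percentage of the control amplitude removed by the drug; five-pulse 20-Hz
train responses are summarised by the last/first amplitude ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve, find_peaks

from .core import TimeSeries
from .exceptions import DataError, FitError, ParameterError, ShapeError

__all__ = [
    "SynapticEvent",
    "EvokedKinetics",
    "ComponentSplit",
    "TrainResponse",
    "biexp_template",
    "template_detect",
    "sliding_template_criterion",
    "event_statistics",
    "rise_time_20_80",
    "fit_decay_monoexp",
    "toxin_component",
    "train_ratio",
]


@dataclass(frozen=True)
class SynapticEvent:
    onset_s: float
    peak_amplitude_pA: float  # signed per configured polarity
    detection_score: float


@dataclass
class EvokedKinetics:
    peak_pA: float
    rise_20_80_ms: float
    decay_tau_ms: float
    decay_A_pA: float
    fit_residual_pA: float  # rms of the decay fit residual


@dataclass
class ComponentSplit:
    control_amp_pA: float
    post_drug_amp_pA: float
    sensitive_percent: float  # 100 * (1 - post/control); < 0 flags facilitation
    negative_flag: bool = False


@dataclass
class TrainResponse:
    amplitudes_pA: np.ndarray  # exactly five values
    ratio_last_first: float
    stim_rate_hz: float = 20.0


def biexp_template(
    rise_ms: float = 0.5,
    decay_ms: float = 8.0,
    sampling_rate: float = 10_000.0,
    length_ms: float | None = None,
    polarity: str = "negative",
) -> np.ndarray:
    """Unit-peak biexponential event template ``exp(-t/td) - exp(-t/tr)``.

    ``polarity="negative"`` (inward current) flips the sign. Default length is
    rise + 4 decay time constants.
    """
    if rise_ms <= 0 or decay_ms <= rise_ms:
        raise ParameterError("need 0 < rise_ms < decay_ms")
    if length_ms is None:
        length_ms = rise_ms + 4.0 * decay_ms
    t = np.arange(0.0, length_ms * 1e-3, 1.0 / sampling_rate)
    w = np.exp(-t / (decay_ms * 1e-3)) - np.exp(-t / (rise_ms * 1e-3))
    w /= w.max()
    return -w if polarity == "negative" else w


def sliding_template_criterion(
    data: np.ndarray, template: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset optimal scale and detection criterion (scale / fit SE).

    At each offset ``i`` the window ``data[i:i+m]`` is fitted as
    ``scale * template + offset`` by least squares; the criterion is
    ``scale / sqrt(SSE / (m - 1))``. With a unit-peak template the criterion
    is, for an isolated event, approximately its peak signal-to-noise ratio,
    so thresholds of 3-4 behave like the classic detector's.
    """
    d = np.asarray(data, dtype=np.float64)
    p = np.asarray(template, dtype=np.float64)
    m = p.size
    if m >= d.size:
        raise ParameterError("template must be shorter than the trace")
    if np.ptp(p) == 0:
        raise ParameterError("flat template")
    n_off = d.size - m + 1
    sum_p = p.sum()
    sum_pp = float(np.dot(p, p))
    ones = np.ones(m)
    sum_d = fftconvolve(d, ones[::-1], mode="valid")
    sum_dd = fftconvolve(d * d, ones[::-1], mode="valid")
    sum_pd = fftconvolve(d, p[::-1], mode="valid")
    denom = sum_pp - sum_p * sum_p / m
    scale = (sum_pd - sum_p * sum_d / m) / denom
    offset = (sum_d - scale * sum_p) / m
    sse = (
        sum_dd
        + scale**2 * sum_pp
        + m * offset**2
        - 2.0 * (scale * sum_pd + offset * sum_d - scale * offset * sum_p)
    )
    sse = np.maximum(sse, 0.0)
    se = np.sqrt(sse / (m - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = np.where(se > 0, scale / se, 0.0)
    assert crit.size == n_off
    return scale, crit


def template_detect(
    trace: TimeSeries,
    template: np.ndarray,
    criterion_threshold: float = 3.0,
    polarity: str = "negative",
    min_separation_s: float | None = None,
) -> list[SynapticEvent]:
    """Detect spontaneous synaptic events by optimally-scaled sliding template.

    Local maxima of the detection criterion above ``criterion_threshold``
    become events; maxima closer than ``min_separation_s`` (default: one
    template length) keep the higher score. At event rates approaching the
    reciprocal of the template length the default merges genuinely distinct
    events — pass a shorter separation there. The template is moved one point
    at a time, so event timing is sample-accurate. The template must already
    carry the event polarity; only positive scales (template-shaped
    deflections) are eligible.
    """
    p = np.asarray(template, dtype=np.float64)
    expected_sign = -1.0 if polarity == "negative" else 1.0
    if np.sign(p[np.argmax(np.abs(p))]) != expected_sign:
        raise ParameterError(f"template polarity does not match {polarity!r}")
    scale, crit = sliding_template_criterion(trace.samples, p)
    crit = np.where(scale > 0, crit, 0.0)
    min_sep = (
        p.size
        if min_separation_s is None
        else max(1, int(round(min_separation_s * trace.sampling_rate)))
    )
    peaks, _ = find_peaks(crit, height=criterion_threshold, distance=min_sep)
    tpl_peak = p[np.argmax(np.abs(p))]
    events = [
        SynapticEvent(
            onset_s=trace.t0 + i / trace.sampling_rate,
            peak_amplitude_pA=float(scale[i] * tpl_peak),
            detection_score=float(crit[i]),
        )
        for i in peaks
    ]
    return events


def event_statistics(
    events: list[SynapticEvent], duration_s: float
) -> dict[str, float]:
    """Event frequency (Hz) and mean absolute amplitude (pA).

    An empty event list gives frequency 0 and NaN amplitude.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    freq = len(events) / duration_s
    amp = (
        float(np.mean([abs(e.peak_amplitude_pA) for e in events]))
        if events
        else float("nan")
    )
    return {"frequency_hz": freq, "mean_amplitude_pA": amp}


def _oriented(x: np.ndarray, polarity: str) -> np.ndarray:
    return -x if polarity == "negative" else x


def rise_time_20_80(
    evoked: TimeSeries, baseline_window_s: float = 0.001, polarity: str = "negative"
) -> float:
    """20-80 % rise time (ms) of a stimulus-aligned sweep.

    Baseline is the mean over the initial ``baseline_window_s``; crossing
    times of 20 % and 80 % of the baseline-to-peak amplitude are found by
    walking back from the peak with linear interpolation.
    """
    y = _oriented(evoked.samples, polarity)
    rate = evoked.sampling_rate
    n_base = max(1, int(round(baseline_window_s * rate)))
    baseline = float(y[:n_base].mean())
    dev = y - baseline
    peak_idx = int(np.argmax(dev))
    amp = dev[peak_idx]
    noise = float(dev[:n_base].std())
    if amp <= 0 or (noise > 0 and amp < 5 * noise):
        raise ShapeError("peak indistinguishable from baseline")
    t20 = _crossing_before(dev, peak_idx, 0.2 * amp)
    t80 = _crossing_before(dev, peak_idx, 0.8 * amp)
    return float((t80 - t20) / rate * 1e3)


def _crossing_before(dev: np.ndarray, peak_idx: int, level: float) -> float:
    """Interpolated index of the last upward crossing of ``level`` before peak."""
    i = peak_idx
    while i > 0 and dev[i] > level:
        i -= 1
    if dev[i] > level:
        raise ShapeError("rising phase never crosses the requested level")
    return i + (level - dev[i]) / (dev[i + 1] - dev[i])


def fit_decay_monoexp(
    evoked: TimeSeries,
    fit_end_s: float | None = None,
    baseline_window_s: float = 0.005,
    polarity: str = "negative",
) -> EvokedKinetics:
    """Fit ``A * exp(-t/tau)`` to the decay from the peak of an evoked sweep.

    Returns kinetics including the 20-80 % rise time of the same sweep.
    ``fit_end_s`` is measured from sweep start (default: to the end). The
    baseline window should cover as much pre-stimulus trace as available —
    a noisy baseline estimate biases the decay constant. The peak is located
    on a lightly smoothed (0.5 ms boxcar) copy so single noise samples do not
    shift the start of the fitted segment.
    """
    y = _oriented(evoked.samples, polarity)
    rate = evoked.sampling_rate
    n_base = max(1, int(round(baseline_window_s * rate)))
    baseline = float(y[:n_base].mean())
    dev = y - baseline
    k = max(1, int(round(0.0005 * rate)))
    smooth = np.convolve(dev, np.ones(k) / k, mode="same")
    peak_idx = int(np.argmax(smooth))
    amp = smooth[peak_idx]
    if amp <= 0:
        raise ShapeError("no peak above baseline")
    end_idx = dev.size if fit_end_s is None else int(round(fit_end_s * rate))
    seg = dev[peak_idx:end_idx]
    if seg.size < 5:
        raise ParameterError("decay segment must span at least 5 samples")
    t = np.arange(seg.size) / rate
    if seg[-1] >= seg[0]:
        raise FitError(
            f"segment does not decay (start {seg[0]:.3g}, end {seg[-1]:.3g})"
        )
    # log-linear initial guess on the positive part
    pos = seg > 0.05 * amp
    tau0 = max(np.trapezoid(seg, t) / amp, 2.0 / rate) if pos.sum() < 3 else -1.0 / np.polyfit(t[pos], np.log(seg[pos]), 1)[0]
    tau0 = float(np.clip(tau0, 1e-5, t[-1] * 10 if t[-1] > 0 else 1.0))
    try:
        popt, _ = curve_fit(
            lambda tt, A, tau: A * np.exp(-tt / tau),
            t,
            seg,
            p0=(amp, tau0),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        raise FitError(f"decay fit did not converge: {exc}") from exc
    A, tau = popt
    if tau <= 0 or A <= 0:
        raise FitError(f"non-physical fit: A={A:.3g}, tau={tau:.3g}")
    resid = seg - A * np.exp(-t / tau)
    try:
        rise = rise_time_20_80(evoked, baseline_window_s, polarity)
    except ShapeError:
        rise = float("nan")
    sign = -1.0 if polarity == "negative" else 1.0
    return EvokedKinetics(
        peak_pA=float(sign * amp),
        rise_20_80_ms=rise,
        decay_tau_ms=float(tau * 1e3),
        decay_A_pA=float(sign * A),
        fit_residual_pA=float(np.sqrt(np.mean(resid**2))),
    )


def toxin_component(
    control_amps: np.ndarray, post_drug_amps: np.ndarray
) -> ComponentSplit:
    """Percentage of the evoked current sensitive to a channel toxin.

    ``sensitive_percent = 100 * (1 - mean(post) / mean(control))`` on stable
    response windows; a negative value (facilitation by the drug) is returned
    but flagged.
    """
    control = float(np.mean(np.abs(control_amps)))
    post = float(np.mean(np.abs(post_drug_amps)))
    if control <= 0:
        raise DataError("mean control amplitude must be positive")
    pct = 100.0 * (1.0 - post / control)
    return ComponentSplit(
        control_amp_pA=control,
        post_drug_amp_pA=post,
        sensitive_percent=pct,
        negative_flag=pct < 0,
    )


def train_ratio(amplitudes: np.ndarray, stim_rate_hz: float = 20.0) -> TrainResponse:
    """Last/first amplitude ratio of a five-pulse stimulus train."""
    amps = np.asarray(amplitudes, dtype=np.float64)
    if amps.size != 5:
        raise ParameterError(f"expected exactly 5 amplitudes, got {amps.size}")
    if amps[0] == 0:
        raise ParameterError("first response must be non-zero")
    return TrainResponse(
        amplitudes_pA=amps,
        ratio_last_first=float(amps[4] / amps[0]),
        stim_rate_hz=stim_rate_hz,
    )
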