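"""Seeded generators for every input class the pipeline consumes.

Each generator returns the synthetic data plus a :class:`SyntheticGroundTruth`
record (true component variances, spike/burst/event times, component
fractions, realized path lengths...) sufficient to score every downstream
estimator without re-deriving anything from the generator internals.

Defaults emulate anesthetised hippocampal recordings: ~1 Hz slow waves of a
few tenths of a mV riding on theta (8 Hz) and gamma oscillations an order of
magnitude smaller, extracellular spikes of ~0.3 ms half-width, principal-cell
bursts of 2-5 spikes at >= 20 Hz intra-burst rate, inward synaptic currents
of tens of pA with millisecond rise and ~8 ms decay, and 10-min behavioural
sessions. All randomness flows from a single integer seed; per-component
sub-streams are spawned deterministically so editing one recipe component
does not reshuffle the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .behavior import ARENA_CM, SESSION_LENGTH_S, ChamberSession, OpenFieldTrack
from .core import FilterSpec, TimeSeries, apply_filter
from .exceptions import ParameterError
from .spikefield import SpikeTrain

__all__ = [
    "LFPComponent",
    "LFPRecipe",
    "SpikeRecipe",
    "CurrentRecipe",
    "BehaviorEffect",
    "SyntheticGroundTruth",
    "gen_lfp",
    "gen_spikes",
    "spike_waveform",
    "gen_current_trace",
    "gen_behavior",
]


@dataclass
class SyntheticGroundTruth:
    """The generator's record of what it actually produced."""

    component_variance: dict = field(default_factory=dict)
    band_variance: dict = field(default_factory=dict)
    component_phase: dict = field(default_factory=dict)
    spike_times: np.ndarray | None = None
    burst_windows: list = field(default_factory=list)
    burst_cycle_windows: list = field(default_factory=list)
    event_onsets: np.ndarray | None = None
    event_amplitudes: np.ndarray | None = None
    fractions: dict = field(default_factory=dict)
    pulse_amplitudes: np.ndarray | None = None
    occupancy: dict = field(default_factory=dict)
    path_length_cm: float | None = None
    extras: dict = field(default_factory=dict)


def _streams(seed: int | None, n: int) -> list[np.random.Generator]:
    """Deterministic per-component sub-streams from one seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# LFP


@dataclass(frozen=True)
class LFPComponent:
    """One additive LFP ingredient.

    kind:
        ``tone`` / ``slow_wave``  — sinusoid at ``freq`` Hz, peak ``amplitude``
        mV (slow_wave is a semantic label for the ~1 Hz anesthesia rhythm);
        ``band_limited_noise``    — white noise band-passed to ``band`` and
        scaled to sd ``amplitude``;
        ``amplitude_burst``       — carrier tone at ``freq`` whose amplitude is
        multiplied by ``burst_factor`` for ``n_bursts`` epochs of
        ``burst_cycles`` cycles each (evenly spaced unless ``burst_starts_s``).
    """

    kind: str
    amplitude: float  # mV (peak for tones, sd for noise)
    freq: float | None = None
    band: tuple[float, float] | None = None
    phase: float = 0.0  # radians; component is amplitude * sin(2*pi*f*t + phase)
    n_bursts: int = 0
    burst_cycles: int = 5
    burst_factor: float = 4.0
    burst_starts_s: tuple[float, ...] | None = None


@dataclass(frozen=True)
class LFPRecipe:
    duration_s: float = 10.0
    rate_hz: float = 10_000.0
    components: tuple[LFPComponent, ...] = ()
    noise_sd: float = 0.0  # mV white background
    pink_sd: float = 0.0  # mV 1/f background
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        for c in self.components:
            f_top = c.freq if c.freq is not None else (c.band[1] if c.band else 0.0)
            if f_top and f_top >= self.rate_hz / 2:
                raise ParameterError(f"component at {f_top} Hz exceeds Nyquist")


def anesthesia_lfp_recipe(
    duration_s: float = 10.0,
    rate_hz: float = 1000.0,
    seed: int | None = None,
    slow_amp: float = 0.2,
    theta_amp: float = 0.042,
    low_gamma_amp: float = 0.057,
    high_gamma_amp: float = 0.014,
    noise_sd: float = 0.005,
) -> LFPRecipe:
    """Default anesthetised-like LFP: 1 Hz slow wave + theta + two gamma tones.

    The 0.2 mV slow wave dominates the raw variance, and the tone amplitudes
    put the relative power of theta / low gamma / high gamma near 0.045 /
    0.08 / 0.005 of the raw variance — the magnitudes typical of control
    anesthetised CA2 recordings.
    """
    return LFPRecipe(
        duration_s=duration_s,
        rate_hz=rate_hz,
        components=(
            LFPComponent("slow_wave", slow_amp, freq=1.0),
            LFPComponent("tone", theta_amp, freq=8.0),
            LFPComponent("tone", low_gamma_amp, freq=40.0),
            LFPComponent("tone", high_gamma_amp, freq=80.0),
        ),
        noise_sd=noise_sd,
        seed=seed,
    )


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping, unit sd."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    return out / out.std()


def gen_lfp(recipe: LFPRecipe) -> tuple[TimeSeries, SyntheticGroundTruth]:
    """Render an LFP recipe into a trace plus ground truth."""
    n = int(round(recipe.duration_s * recipe.rate_hz))
    t = np.arange(n) / recipe.rate_hz
    rngs = _streams(recipe.seed, len(recipe.components) + 2)
    x = np.zeros(n)
    truth = SyntheticGroundTruth()
    for i, comp in enumerate(recipe.components):
        rng = rngs[i]
        if comp.kind in ("tone", "slow_wave"):
            y = comp.amplitude * np.sin(2 * np.pi * comp.freq * t + comp.phase)
            truth.component_phase[i] = {"freq": comp.freq, "phase": comp.phase}
        elif comp.kind == "band_limited_noise":
            y = rng.standard_normal(n)
            y = apply_filter(
                TimeSeries(y, recipe.rate_hz), FilterSpec("bandpass", comp.band)
            ).samples
            y *= comp.amplitude / y.std()
        elif comp.kind == "amplitude_burst":
            env = np.ones(n)
            cycle = 1.0 / comp.freq
            if comp.burst_starts_s is not None:
                starts = np.asarray(comp.burst_starts_s)
            else:
                gap = recipe.duration_s / (comp.n_bursts + 1)
                starts = gap * (1 + np.arange(comp.n_bursts))
                # align burst onsets to carrier cycle boundaries so each burst
                # spans a whole number of cycles
                starts = np.round(starts / cycle) * cycle
            width = comp.burst_cycles * cycle
            for s in starts:
                env[(t >= s) & (t < s + width)] = comp.burst_factor
                truth.burst_cycle_windows.append((float(s), float(s + width)))
            y = comp.amplitude * env * np.sin(2 * np.pi * comp.freq * t + comp.phase)
            truth.extras.setdefault("burst_cycles_per_burst", comp.burst_cycles)
        else:
            raise ParameterError(f"unknown component kind {comp.kind!r}")
        truth.component_variance[i] = float(y.var())
        _accumulate_band_variance(truth, comp, float(y.var()))
        x += y
    if recipe.noise_sd > 0:
        x += recipe.noise_sd * rngs[-2].standard_normal(n)
    if recipe.pink_sd > 0:
        x += recipe.pink_sd * _pink_noise(rngs[-1], n)
    truth.extras["noise_variance"] = recipe.noise_sd**2 + recipe.pink_sd**2
    trace = TimeSeries(x, recipe.rate_hz, units="mV", channel_id="synthetic-lfp")
    return trace, truth


def _accumulate_band_variance(
    truth: SyntheticGroundTruth, comp: LFPComponent, var: float
) -> None:
    from .core import CANONICAL_BANDS

    f = comp.freq if comp.freq is not None else (
        0.5 * (comp.band[0] + comp.band[1]) if comp.band else None
    )
    if f is None:
        return
    for name, band in CANONICAL_BANDS.items():
        if band.contains(f):
            truth.band_variance[name] = truth.band_variance.get(name, 0.0) + var


# ---------------------------------------------------------------------------
# Spikes


@dataclass(frozen=True)
class SpikeRecipe:
    """Spike-train recipe: Poisson, bursting, or phase-locked placement.

    ``embed`` adds biphasic waveforms (peak ``waveform_amplitude`` mV,
    ``waveform_halfwidth_ms`` FWHM) to a Gaussian noise carrier sampled at
    ``rate_hz``, producing an extracellular-like trace.
    """

    mode: str = "poisson"  # poisson | bursting | phase_locked
    duration_s: float = 60.0
    rate_hz: float = 1.0  # single-spike rate (poisson / bursting extras)
    burst_rate_hz: float = 1.0
    spikes_per_burst: int = 3
    intraburst_hz: float = 80.0
    lock_freq: float | None = None
    lock_phase: float = -np.pi / 2  # trough of a sin-phase component
    lock_jitter_s: float = 0.0
    lock_prob: float = 1.0
    embed: bool = False
    carrier_rate_hz: float = 10_000.0
    carrier_noise_sd: float = 0.01  # mV
    waveform_amplitude: float = 0.08  # mV
    waveform_halfwidth_ms: float = 0.3
    refractory_s: float = 0.002
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode == "bursting" and self.intraburst_hz < 20.0:
            raise ParameterError("intraburst rate must be >= 20 Hz for bursts")
        if self.mode == "phase_locked" and self.lock_freq is None:
            raise ParameterError("phase locking requires lock_freq")


def spike_waveform(
    rate_hz: float, amplitude: float = 0.08, halfwidth_ms: float = 0.3
) -> np.ndarray:
    """Biphasic extracellular spike: sharp negative peak, shallow rebound."""
    sigma = halfwidth_ms * 1e-3 / 2.355  # FWHM -> sd of the main lobe
    t = np.arange(-4 * sigma, 10 * sigma, 1.0 / rate_hz)
    main = -np.exp(-0.5 * (t / sigma) ** 2)
    rebound = 0.35 * np.exp(-0.5 * ((t - 3 * sigma) / (2 * sigma)) ** 2)
    w = main + rebound
    return amplitude * w / np.abs(w).max()


def _poisson_times(
    rng: np.random.Generator, rate: float, duration: float, refractory: float
) -> np.ndarray:
    if rate <= 0:
        return np.empty(0)
    n_expect = int(rate * duration * 3 + 20)
    gaps = rng.exponential(1.0 / rate, n_expect) + refractory
    times = np.cumsum(gaps)
    return times[times < duration]


def gen_spikes(
    recipe: SpikeRecipe, lfp_truth: SyntheticGroundTruth | None = None
) -> tuple[SpikeTrain | tuple[TimeSeries, SpikeTrain], SyntheticGroundTruth]:
    """Generate a spike train, optionally embedded as waveforms in a trace.

    Phase-locked mode places (with probability ``lock_prob``, jitter sd
    ``lock_jitter_s``) one spike per cycle of the target component at
    ``lock_phase`` radians of its ``sin(2 pi f t + phase0)`` cycle; the
    component's true phase comes from ``lfp_truth`` when given.
    """
    rng_main, rng_embed = _streams(recipe.seed, 2)
    d = recipe.duration_s
    truth = SyntheticGroundTruth()
    if recipe.mode == "poisson":
        times = _poisson_times(rng_main, recipe.rate_hz, d, recipe.refractory_s)
    elif recipe.mode == "bursting":
        isi = 1.0 / recipe.intraburst_hz
        burst_len = (recipe.spikes_per_burst - 1) * isi
        # keep bursts separated by more than the 50 ms burst-joining threshold
        # so downstream detection sees exactly the designed bursts
        min_gap = max(2.5 * isi, 0.075)
        # dead-time-compensated intensity so the realized burst rate matches
        dead = burst_len + min_gap
        lam = recipe.burst_rate_hz
        lam_eff = lam / max(1.0 - lam * dead, 0.1)
        burst_starts = _poisson_times(rng_main, lam_eff, d, 0.0)
        keep = []
        last_end = -np.inf
        for s in burst_starts:
            if s > last_end + min_gap and s + burst_len < d:
                keep.append(s)
                last_end = s + burst_len
        times_list = []
        for s in keep:
            times_list.extend(s + isi * np.arange(recipe.spikes_per_burst))
            truth.burst_windows.append((float(s), float(s + burst_len)))
        singles_raw = _poisson_times(rng_main, recipe.rate_hz, d, recipe.refractory_s)
        singles = []
        for t in singles_raw:
            if not all(t < a - 0.2 or t > b + 0.2 for a, b in truth.burst_windows):
                continue
            if singles and t - singles[-1] <= 0.06:  # would read as a spurious burst
                continue
            singles.append(t)
        times = np.sort(np.concatenate([times_list, singles]))
        truth.extras["n_singles"] = len(singles)
    elif recipe.mode == "phase_locked":
        if recipe.lock_freq is None:
            raise ParameterError("phase locking requires lock_freq")
        phase0 = 0.0
        if lfp_truth is not None:
            for meta in lfp_truth.component_phase.values():
                if meta["freq"] == recipe.lock_freq:
                    phase0 = meta["phase"]
                    break
        f = recipe.lock_freq
        # sin(2 pi f t + phase0) attains phase `lock_phase` at these times
        k = np.arange(int(np.floor(d * f)) + 2)
        times = ((recipe.lock_phase - phase0) / (2 * np.pi) + k) / f
        times = times[(times >= 0) & (times < d)]
        if recipe.lock_prob < 1.0:
            times = times[rng_main.random(times.size) < recipe.lock_prob]
        if recipe.lock_jitter_s > 0:
            times = np.sort(times + rng_main.normal(0, recipe.lock_jitter_s, times.size))
            times = times[(times >= 0) & (times < d)]
    else:
        raise ParameterError(f"unknown spike mode {recipe.mode!r}")

    times = np.unique(times)
    truth.spike_times = times
    train = SpikeTrain(times, source_id="synthetic-spikes", detection={"mode": recipe.mode})
    if not recipe.embed:
        return train, truth
    n = int(round(d * recipe.carrier_rate_hz))
    carrier = recipe.carrier_noise_sd * rng_embed.standard_normal(n)
    w = spike_waveform(
        recipe.carrier_rate_hz, recipe.waveform_amplitude, recipe.waveform_halfwidth_ms
    )
    peak_off = int(np.argmax(np.abs(w)))
    for t_spk in times:
        i0 = int(round(t_spk * recipe.carrier_rate_hz)) - peak_off
        a, b = max(i0, 0), min(i0 + w.size, n)
        if b > a:
            carrier[a:b] += w[a - i0 : b - i0]
    trace = TimeSeries(
        carrier, recipe.carrier_rate_hz, units="mV", channel_id="synthetic-mua"
    )
    return (trace, train), truth


# ---------------------------------------------------------------------------
# Synaptic currents


@dataclass(frozen=True)
class CurrentRecipe:
    """Whole-cell current recipe.

    ``mode="spontaneous"``: biexponential inward events at Poisson onsets.
    ``mode="evoked"``: stimulus-aligned sweeps; total amplitude splits into
    named ``fractions`` (summing to 1), a drug zeroes one component, and a
    five-pulse 20-Hz ``depression_profile`` scales successive responses.
    """

    mode: str = "spontaneous"
    duration_s: float = 120.0
    rate_hz: float = 10_000.0
    event_rate_hz: float = 0.5
    amplitude_mean_pA: float = 30.0
    amplitude_cv: float = 0.3
    rise_ms: float = 1.0
    decay_ms: float = 8.0
    noise_sd_pA: float = 3.0
    # evoked parameters
    evoked_peak_pA: float = 100.0
    fractions: tuple[tuple[str, float], ...] = (("cck", 0.582), ("other", 0.418))
    drug_blocks: str | None = None  # component zeroed by the "drug"
    n_pulses: int = 1
    stim_rate_hz: float = 20.0
    depression_profile: tuple[float, ...] = (1.0, 0.8, 0.65, 0.55, 0.48)
    sweep_duration_s: float = 0.25
    stim_time_s: float = 0.02
    response_cv: float = 0.0
    n_sweeps: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        tot = sum(f for _, f in self.fractions)
        if abs(tot - 1.0) > 1e-9:
            raise ParameterError(f"fractions must sum to 1 (got {tot})")
        if self.rise_ms <= 0 or self.decay_ms <= 0:
            raise ParameterError("time constants must be positive")


def _biexp_kernel(rate: float, rise_ms: float, decay_ms: float) -> np.ndarray:
    t = np.arange(0.0, (rise_ms + 6 * decay_ms) * 1e-3, 1.0 / rate)
    w = np.exp(-t / (decay_ms * 1e-3)) - np.exp(-t / (rise_ms * 1e-3))
    return w / w.max()


def gen_current_trace(
    recipe: CurrentRecipe,
) -> tuple[TimeSeries | list[TimeSeries], SyntheticGroundTruth]:
    """Spontaneous mode returns one trace; evoked mode a list of sweeps."""
    if recipe.mode == "spontaneous":
        return _gen_spontaneous(recipe)
    if recipe.mode == "evoked":
        return _gen_evoked(recipe)
    raise ParameterError(f"unknown current mode {recipe.mode!r}")


def _gen_spontaneous(recipe: CurrentRecipe) -> tuple[TimeSeries, SyntheticGroundTruth]:
    rng_onsets, rng_amps, rng_noise = _streams(recipe.seed, 3)
    n = int(round(recipe.duration_s * recipe.rate_hz))
    onsets = _poisson_times(rng_onsets, recipe.event_rate_hz, recipe.duration_s, 0.0)
    amps = recipe.amplitude_mean_pA * (
        1.0 + recipe.amplitude_cv * rng_amps.standard_normal(onsets.size)
    )
    amps = np.clip(amps, 0.2 * recipe.amplitude_mean_pA, None)
    kernel = _biexp_kernel(recipe.rate_hz, recipe.rise_ms, recipe.decay_ms)
    x = np.zeros(n)
    for t_on, a in zip(onsets, amps):
        i0 = int(round(t_on * recipe.rate_hz))
        b = min(i0 + kernel.size, n)
        if b > i0:
            x[i0:b] += -a * kernel[: b - i0]  # inward (negative) current
    if recipe.noise_sd_pA > 0:
        x += recipe.noise_sd_pA * rng_noise.standard_normal(n)
    truth = SyntheticGroundTruth(event_onsets=onsets, event_amplitudes=amps)
    trace = TimeSeries(x, recipe.rate_hz, units="pA", channel_id="synthetic-current")
    return trace, truth


def _gen_evoked(recipe: CurrentRecipe) -> tuple[list[TimeSeries], SyntheticGroundTruth]:
    (rng,) = _streams(recipe.seed, 1)
    rate = recipe.rate_hz
    kernel = _biexp_kernel(rate, recipe.rise_ms, recipe.decay_ms)
    n = int(round(recipe.sweep_duration_s * rate))
    frac = dict(recipe.fractions)
    active = sum(
        f for name, f in frac.items() if name != recipe.drug_blocks
    )
    profile = recipe.depression_profile[: recipe.n_pulses]
    sweeps: list[TimeSeries] = []
    pulse_amps = np.zeros((recipe.n_sweeps, recipe.n_pulses))
    for s in range(recipe.n_sweeps):
        x = np.zeros(n)
        for k, rel in enumerate(profile):
            amp = recipe.evoked_peak_pA * active * rel
            if recipe.response_cv > 0:
                amp *= max(0.0, 1.0 + recipe.response_cv * rng.standard_normal())
            i0 = int(round((recipe.stim_time_s + k / recipe.stim_rate_hz) * rate))
            b = min(i0 + kernel.size, n)
            x[i0:b] += -amp * kernel[: b - i0]
            pulse_amps[s, k] = amp
        if recipe.noise_sd_pA > 0:
            x += recipe.noise_sd_pA * rng.standard_normal(n)
        sweeps.append(TimeSeries(x, rate, units="pA", channel_id=f"sweep{s}"))
    truth = SyntheticGroundTruth(
        fractions=frac,
        pulse_amplitudes=pulse_amps,
        extras={
            "active_fraction": active,
            "drug_blocks": recipe.drug_blocks,
            "stim_time_s": recipe.stim_time_s,
            "decay_ms": recipe.decay_ms,
            "rise_ms": recipe.rise_ms,
        },
    )
    return sweeps, truth


# ---------------------------------------------------------------------------
# Behavior


@dataclass(frozen=True)
class BehaviorEffect:
    """Target group-level preferences and locomotion for a synthetic cohort."""

    sociability_preference_s: float = 30.0
    novelty_preference_s: float = 30.0
    base_time_s: float = 90.0
    between_animal_sd_s: float = 15.0
    n_animals: int = 9
    speed_mm_s: float = 65.8
    track_rate_hz: float = 10.0
    track_duration_s: float = SESSION_LENGTH_S


def gen_behavior(
    effect: BehaviorEffect, seed: int | None = None
) -> tuple[list[ChamberSession], OpenFieldTrack, SyntheticGroundTruth]:
    """Draw chamber sessions realising the stated preference on average, plus
    a reflecting random-walk open-field track with the stated mean speed."""
    rng_soc, rng_nov, rng_track = _streams(seed, 3)
    sessions: list[ChamberSession] = []
    for i in range(effect.n_animals):
        for phase, pref, rng in (
            ("sociability", effect.sociability_preference_s, rng_soc),
            ("novelty", effect.novelty_preference_s, rng_nov),
        ):
            a = effect.base_time_s + pref + rng.normal(0, effect.between_animal_sd_s)
            b = effect.base_time_s + rng.normal(0, effect.between_animal_sd_s)
            a, b = max(a, 0.0), max(b, 0.0)
            total = a + b
            if total > SESSION_LENGTH_S:  # cap occupancy at the session length
                a, b = a * SESSION_LENGTH_S / total, b * SESSION_LENGTH_S / total
            sessions.append(
                ChamberSession(phase, a, b, SESSION_LENGTH_S, animal_id=f"m{i}")
            )
    n = int(round(effect.track_duration_s * effect.track_rate_hz))
    step_cm = effect.speed_mm_s / 10.0 / effect.track_rate_hz  # mm/s -> cm/sample
    # persistent-heading random walk: smooth direction changes, constant speed
    headings = np.cumsum(rng_track.normal(0, 0.4, n - 1))
    headings += rng_track.uniform(0, 2 * np.pi)
    steps = step_cm * np.c_[np.cos(headings), np.sin(headings)]
    pos = np.empty((n, 2))
    pos[0] = (ARENA_CM / 2, ARENA_CM / 2)
    pos[1:] = pos[0] + np.cumsum(steps, axis=0)
    # fold back into the arena: reflection at the walls
    pos = ARENA_CM - np.abs(ARENA_CM - (pos % (2 * ARENA_CM)))
    path_cm = float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1)))
    track = OpenFieldTrack(pos, effect.track_rate_hz)
    truth = SyntheticGroundTruth(
        occupancy={
            "sociability_preference_s": effect.sociability_preference_s,
            "novelty_preference_s": effect.novelty_preference_s,
        },
        path_length_cm=path_cm,
    )
    return sessions, track, truth
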