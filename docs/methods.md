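# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `hippoephys`. Conventions throughout: time in seconds
(t = 0 at trace start), half-open windows `[start, end)`, voltages in mV,
currents in pA.

## Empirical mode decomposition

**Sifting (plain EMD).** Local extrema are found from sign changes of the
first difference (plateaus register at their last sample); upper and lower
envelopes are natural cubic splines through the maxima/minima, extended by
mirroring the two nearest extrema about each trace endpoint so spline
divergence at the borders decays within roughly one extremum spacing.
A candidate mode is repeatedly reduced by the envelope mean until the
Cauchy-type criterion Σm²/Σh² < 0.2 (m the envelope mean, h the current
candidate) or 50 sift iterations, whichever comes first. Extraction stops
when the running residual has fewer than three extrema; a monotone input
yields zero IMFs with itself as residual — a signalled outcome, not an
error. The 0.2 threshold trades IMF idealism against runtime: at 0.2 the
extrema/zero-crossing counts of noisy IMFs agree within ~10 %, at 0.01
within ~1 % (the test suite checks the latter at the stricter setting).
Because the residual is maintained by subtraction, IMFs + residual
reconstruct the input to floating-point round-off by construction.

**CEEMDAN.** Stage 1 averages, over `n_realizations` white-noise draws
`w_i`, the first sifted mode of `x + ε₀·w_i` with ε₀ = `noise_sd`·sd(x).
Stage k ≥ 2 perturbs the running residual with the k-th EMD mode of the
pre-decomposed noise, scaled by `noise_sd`·sd(residual), and again averages
first modes. Each stage's IMF is subtracted from the residual, so the
decomposition is complete *exactly* (unlike plain ensemble EMD, whose
averaged IMFs need not sum to the input; `eemd` is kept for comparison and
its approximation documented by its own reconstruction error). Defaults
`n_realizations = 100`, `noise_sd = 0.2` are the values conventional for
this algorithm family; all are exposed. The generator stream is seeded, so
results are bit-reproducible; across seeds, band variances on a two-tone
fixture vary well below 5 %.

**Band assembly.** Each IMF gets an amplitude-weighted mean instantaneous
frequency: the derivative of the unwrapped analytic (Hilbert) phase,
averaged with the analytic envelope as weights, which discounts
low-amplitude stretches where the phase is noise-dominated. A band signal
(theta 5–14, low gamma 25–55, high gamma 56–120 Hz) is the sum of IMFs whose
mean frequency falls inside the band. IMFs in the gaps (14–25 Hz, >120 Hz)
stay unassigned rather than being forced into a neighbour; an empty band is
returned as zeros and flagged. Noise-dominated recordings can push an IMF's
mean frequency just outside a band edge (e.g. 120→125 Hz), which
under-counts high-gamma power at low SNR — the ensemble decomposition
mitigates but does not remove this.

## Band statistics

**Average relative power** z-scores the band against the *raw* LFP sd
(centring on the band's own mean, which is ≈0) and averages z². Dividing by
the raw sd rather than the band's own normalises out across-animal gain
differences; the statistic is dimensionless and exactly invariant under
joint rescaling of band and raw trace. (Reports of this quantity in mV² in
the literature conflict with its definition; the dimensionless form is
implemented.) On a tone of amplitude a in white noise of sd σ it estimates
the variance fraction (a²/2)/(a²/2 + σ²), with a positive bias from
broadband noise captured by the band's member IMFs — about +7 % at
SNR 2 with CEEMDAN, larger with plain EMD.

**Band occurrence frequency** z-scores the band against its *own* sd (the
two statistics deliberately use different normalisations: occurrence
counting is threshold-relative per band), delimits cycles at consecutive
upward zero crossings, counts cycles whose peak |z| exceeds the threshold
(default 2, chosen because a pure sinusoid peaks at √2 and band amplitudes
are near-normal, so 2 sd ≈ the 95th percentile), and divides by duration.
An envelope-based cycle amplitude was considered and rejected as the default
for being less transparent; the upward-crossing definition is the simplest
consistent one.

**Welch PSD** uses Hann windows of 2048 samples with 50 % overlap and
constant detrending (≈4.9 Hz bins at 10 kHz); total power matches the
time-domain variance within 5 % on stationary noise. The spectrogram helper
is display-only.

## Spike–field analysis

Spike detection filters the trace (300–4500 Hz band-pass for spike-time
extraction; >500 Hz high-pass for MUA–STA alignment), thresholds at
5 × robust sd (median absolute deviation / 0.6745 — the raw sd is inflated
by the spikes themselves), takes the absolute extremum of each
supra-threshold excursion as the spike time (sub-millisecond stability,
unlike first-crossing times), and merges detections within a 1 ms
refractory interval keeping the larger. The STA band-passes the LFP to
0.2–50 Hz (zero-phase, so summary-window latencies are meaningful), averages
±1 s segments, skips spikes within one window of the trace edges, and flags
(but still reports) recordings whose spike rate is below 1 Hz. Peri-spike
power uses twenty 100 ms bins per spike, each bin z-scored against the raw
sd; windows of nearby spikes may overlap and each spike contributes
independently.

## Unit firing

Bursts are maximal runs of consecutive inter-spike intervals ≤ `max_isi_s`,
default 0.05 s (the reciprocal of the 20 Hz instantaneous-rate criterion;
per-cell values of 20–50 ms are accepted, values outside warn). Burst
boundaries are the first/last spike times, no padding. Rates: total = n/T,
burst = bursts/T, single = (n − spikes-in-bursts)/T, intra-burst = mean of
(n_b − 1)/(duration of burst). Spike half-width is the full width at half
the baseline-to-peak amplitude, baseline = median of the first 20 % of the
window, polarity auto-detected, crossings linearly interpolated.

## Synaptic currents

**Sliding template.** At every sample the template (default biexponential,
rise 0.5 ms / decay 8 ms for IPSC-like, 0.3/4 ms for EPSC-like, unit peak,
carrying the event polarity) is least-squares fitted with free scale and
offset; the detection criterion is scale / √(SSE/(m−1)), which for an
isolated event approximates its peak SNR, so thresholds of 3–4 behave as in
the classic detector. Criterion local maxima above threshold become events;
maxima closer than one template length keep the higher score. That default
merge distance systematically under-counts when the true event rate
approaches the reciprocal of the template length (~30 Hz for the IPSC
default), so `min_separation_s` is exposed for high-rate regimes. The
vectorised criterion equals a per-position least-squares oracle to 1e−6.

**Kinetics.** 20–80 % rise times interpolate the crossings walking back from
the peak; for a saturating exponential of constant τ_r the value is
τ_r·ln 4. The decay fit is unweighted least squares of A·e^(−t/τ) from the
peak; the peak is located on a 0.5 ms boxcar-smoothed copy (single noise
samples otherwise shift the segment start) and the baseline should use as
much pre-stimulus window as available — a baseline estimated from ~1 ms of
noisy trace biases τ several-fold above the Cramér–Rao bound, while a 15 ms
window brings the Monte-Carlo dispersion to ~2 % at 5 % noise. Both
estimators are exactly invariant to amplitude scaling and baseline offset.

**Component splits.** The toxin-sensitive percentage is
100·(1 − mean(post)/mean(control)) on stable response windows (means, not
sweep-paired differences, matching the subtraction definition; the last
pre-manipulation sweeps serve as the steady-state window). Negative values
(facilitation) are returned but flagged. Train responses are summarised by
the fifth/first amplitude ratio at 20 Hz.

## Behaviour

Chamber scores are plain differences of tracker-reported investigation
times; the package does not recompute them from positions. The open field
is tiled by 12 cm blocks; a 60 cm side forces a 5×5 grid with 16 perimeter
blocks (assay descriptions sometimes quote 12, which cannot tile this
arena — the inner/outer classification, central 3×3 versus the rest, is
unaffected). Distance is the path integral in metres, velocity its time
average in mm/s, zone occupancy per-sample membership times the sampling
interval.

## Synthetic data and what passing tests show

Generators are statistical, not biophysical: sinusoidal slow-wave/theta/
gamma components (optionally amplitude-burst-modulated or band-limited
noise), Gaussian white plus optional 1/f background, biphasic spike
waveforms of 0.3 ms half-width, Poisson or dead-time-compensated bursting
spike trains, biexponential synaptic events, and persistent-heading random
walks with reflecting walls. Default LFP amplitudes put theta / low gamma /
high gamma near 0.045 / 0.08 / 0.005 of the raw variance — magnitudes
typical of control anesthetised CA2 recordings — over a 0.2 mV 1 Hz slow
wave. One seed drives everything; per-component sub-streams are spawned
deterministically so editing one recipe component does not reshuffle others.
The bursting generator enforces >75 ms inter-burst gaps (beyond the 50 ms
joining threshold) and compensates Poisson dead time so realized burst rates
match the design.

Passing tests therefore demonstrate estimator correctness under the assumed
signal structure (stationary tones, white-ish noise, exact event kinetics).
They do not establish robustness to non-stationary anesthesia depth,
electrode drift, 1/f-dominated backgrounds, overlapping units, or
template/event kinetics mismatch — all of which degrade real recordings.

## Problem sizes

Routine analyses run on desk-scale fixtures: 10 s LFPs at 1 kHz for
ensemble decompositions (≈5–10 s per CEEMDAN at 100 realizations), 60 s
traces at 10 kHz for detection tasks, 100-seed Monte-Carlo loops for
estimator dispersion, and 100-replicate two-cohort (n = 10/10) studies at
2 s per trace for the group-level power contrast. The in-vivo sampling rate
of 10 kHz is kept where the content requires it (spike waveforms); band
analyses use 500–1000 Hz, comfortably above twice the highest band edge.
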