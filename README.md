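# hippoephys

Analysis pipeline for hippocampal network electrophysiology, built for
studies of CA2/CA3 circuit dynamics (e.g. in mouse models of synaptic
autism): local field potentials recorded under anesthesia, juxtacellular
single-unit firing, whole-cell synaptic currents from slices, and the
behavioural assays that accompany them. All stages are exercised end-to-end
against seeded synthetic data with known ground truth, so every estimator in
the chain is testable without access to raw recordings.

## What it computes

**LFP band decomposition.** Raw LFPs (mV, typically 10 kHz) are decomposed
into intrinsic mode functions with empirical mode decomposition — plain EMD,
ensemble EMD, or CEEMDAN (complete ensemble EMD with adaptive noise), the
variant whose IMFs plus residual reconstruct the input exactly. Oscillation
bands are assembled by summing IMFs whose amplitude-weighted mean
instantaneous frequency (from the analytic-signal phase) falls in
theta (5–14 Hz), low gamma (25–55 Hz), or high gamma (56–120 Hz).

**Band statistics.** For a band signal *b(t)* extracted from a raw LFP with
standard deviation σ_raw:

* *average relative power* = ⟨z²⟩ with z = (b − b̄)/σ_raw — dimensionless,
  invariant to overall recording gain;
* *band occurrence frequency* = (cycles whose peak |z| exceeds 2, z-scored
  against the band's own sd) / duration. A constant-amplitude sinusoid peaks
  at z = √2 < 2, so only amplitude excursions are counted;
* Welch PSD with the Hann(2048), 50 %-overlap convention (≈ 4.9 Hz bins at
  10 kHz).

**Spike–field coupling.** Multi-unit spike times from a 5-robust-sd threshold
on the 300–4500 Hz (or >500 Hz) filtered trace; spike-triggered average of
the 0.2–50 Hz LFP over ±1 s with pre/post 250 ms summary means (recordings
below 1 Hz spike rate are flagged excluded); peri-spike band power in twenty
100 ms bins.

**Unit firing.** Bursts = runs of ≥2 spikes with inter-spike intervals
≤ 20–50 ms (the ≥20 Hz criterion); rates decomposed into total / single /
burst / intra-burst; spike half-width (FWHM).

**Synaptic currents.** Optimally-scaled sliding-template detection of
spontaneous events (criterion = scale / SE of the fit); 20–80 % rise times;
monoexponential decay fits y(t) = A·e^(−t/τ); toxin-subtraction component
fractions, 100·(1 − post/control), for dissecting e.g. the
ω-conotoxin-GVIA-sensitive (CCK-interneuron) share of evoked IPSCs;
last/first ratios of five-pulse 20 Hz trains.

**Behaviour.** Three-chamber sociability and social-novelty scores
(investigation-time differences) and open-field metrics (path-integral
distance, velocity, central 3×3-block inner-zone occupancy of the 60×60 cm
arena).

**Synthetic data.** `hippoephys.synthetic` generates every input class with
ground truth: slow-wave/theta/gamma LFP mixtures, amplitude bursts,
phase-locked or bursting spike trains with embedded biphasic waveforms,
Poisson synaptic events with biexponential kinetics, evoked sweeps with named
component fractions, and chamber/open-field sessions.

## Worked example

```python
from hippoephys import (CANONICAL_BANDS, assemble_band,
                        average_relative_power, band_occurrence_frequency)
from hippoephys.emd import ceemdan
from hippoephys.synthetic import anesthesia_lfp_recipe, gen_lfp

trace, truth = gen_lfp(anesthesia_lfp_recipe(duration_s=10.0, rate_hz=1000.0, seed=7))
imfset = ceemdan(trace, n_realizations=100, noise_sd=0.2, seed=7)
print(f"{imfset.n_imfs} IMFs, reconstruction error "
      f"{imfset.reconstruction_error(trace.samples):.2e} mV")
for label in ("theta", "low_gamma", "high_gamma"):
    band = assemble_band(imfset, CANONICAL_BANDS[label], trace)
    arp = average_relative_power(band)
    occ = band_occurrence_frequency(band, threshold_sd=2.0)
    print(f"{label:10s} relative power {arp:.4f}  occurrence {occ.occurrence_frequency:.2f} Hz")
```

prints

```
9 IMFs, reconstruction error 4.34e-19 mV
theta      relative power 0.0385  occurrence 0.00 Hz
low_gamma  relative power 0.0656  occurrence 0.00 Hz
high_gamma relative power 0.0017  occurrence 21.60 Hz
```

The reconstruction error shows CEEMDAN's completeness (IMFs + residual equal
the input to round-off). Relative powers recover the generator's design —
the synthetic theta/low-gamma/high-gamma tones carry about 0.039 / 0.072 /
0.004 of the raw variance, the slow 1 Hz anesthesia wave the rest. The
constant-amplitude theta and low-gamma tones produce no supra-threshold
cycles (occurrence 0), while the noise-dominated high-gamma band crosses the
2 sd threshold at the rate typical of Gaussian amplitude fluctuations.

A command-line interface mirrors the library:
`hippoephys decompose|band-metrics|sta|bursts|events|evoked|behavior|simulate`
(see `hippoephys --help`).

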