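import numpy as np
import pytest

from hippoephys import TimeSeries
from hippoephys.exceptions import DataError, FitError, ParameterError
from hippoephys.synaptic import (
    biexp_template,
    event_statistics,
    fit_decay_monoexp,
    rise_time_20_80,
    sliding_template_criterion,
    template_detect,
    toxin_component,
    train_ratio,
)
from hippoephys.synthetic import CurrentRecipe, gen_current_trace

RATE = 10_000.0


def brute_force_criterion(data, template):
    """Per-position least-squares template fit, the slow way."""
    m = template.size
    scales, crits = [], []
    for i in range(data.size - m + 1):
        d = data[i : i + m]
        A = np.c_[template, np.ones(m)]
        (scale, offset), res, *_ = np.linalg.lstsq(A, d, rcond=None)
        sse = float(res[0]) if res.size else float(np.sum((d - A @ [scale, offset]) ** 2))
        se = np.sqrt(sse / (m - 1))
        scales.append(scale)
        crits.append(scale / se if se > 0 else 0.0)
    return np.array(scales), np.array(crits)


class TestTemplateDetect:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal(2000)
        tpl = biexp_template(0.5, 3.0, RATE)
        scale, crit = sliding_template_criterion(data, tpl)
        bf_scale, bf_crit = brute_force_criterion(data, tpl)
        np.testing.assert_allclose(scale, bf_scale, atol=1e-7)
        np.testing.assert_allclose(crit, bf_crit, atol=1e-6)

    def test_exact_template_copy_detected_at_onset(self):
        tpl = biexp_template(1.0, 8.0, RATE)
        x = np.zeros(5000)
        onset = 1234
        x[onset : onset + tpl.size] = 30.0 * tpl
        trace = TimeSeries(x, RATE, units="pA")
        events = template_detect(trace, tpl, criterion_threshold=3.0)
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(onset / RATE, abs=2e-4)
        assert events[0].peak_amplitude_pA == pytest.approx(-30.0, rel=0.01)

    def test_recall_precision_on_noisy_fixture(self):
        recipe = CurrentRecipe(
            mode="spontaneous", duration_s=60.0, event_rate_hz=0.5,
            amplitude_mean_pA=30.0, amplitude_cv=0.0, rise_ms=1.0,
            decay_ms=8.0, noise_sd_pA=3.0, seed=7,
        )
        trace, truth = gen_current_trace(recipe)
        tpl = biexp_template(1.0, 8.0, RATE)
        events = template_detect(trace, tpl, criterion_threshold=3.0)
        det = np.array([e.onset_s for e in events])
        matched = 0
        for t_true in truth.event_onsets:
            if det.size and np.min(np.abs(det - t_true)) <= 0.002:
                matched += 1
        recall = matched / truth.event_onsets.size
        precision = matched / det.size
        assert recall >= 0.9
        assert precision >= 0.9

    def test_noise_only_few_false_events(self):
        rng = np.random.default_rng(12)
        trace = TimeSeries(3.0 * rng.standard_normal(600_000), RATE, units="pA")
        tpl = biexp_template(1.0, 8.0, RATE)
        events = template_detect(trace, tpl, criterion_threshold=4.0)
        assert len(events) <= 1

    def test_flat_template_rejected(self):
        trace = TimeSeries(np.random.default_rng(0).standard_normal(1000), RATE)
        with pytest.raises(ParameterError):
            sliding_template_criterion(trace.samples, np.ones(50))

    def test_wrong_polarity_template_rejected(self):
        trace = TimeSeries(np.zeros(1000) + np.arange(1000) * 0.0 + 1.0, RATE)
        tpl = biexp_template(1.0, 8.0, RATE, polarity="positive")
        with pytest.raises(ParameterError):
            template_detect(trace, tpl, polarity="negative")


class TestEventStatistics:
    def test_frequency_arithmetic(self):
        from hippoephys.synaptic import SynapticEvent

        events = [SynapticEvent(i * 2.0, -20.0, 5.0) for i in range(30)]
        stats = event_statistics(events, 60.0)
        assert stats["frequency_hz"] == pytest.approx(0.5)
        assert stats["mean_amplitude_pA"] == pytest.approx(20.0)

    def test_empty_flagged(self):
        stats = event_statistics([], 60.0)
        assert stats["frequency_hz"] == 0.0
        assert np.isnan(stats["mean_amplitude_pA"])

    def test_poisson_rate_recovered(self):
        """Count/duration recovers a 10 Hz Poisson event rate within 1 Hz."""
        from hippoephys.synaptic import SynapticEvent

        recipe = CurrentRecipe(
            mode="spontaneous", duration_s=120.0, event_rate_hz=10.0,
            noise_sd_pA=2.0, seed=20,
        )
        _, truth = gen_current_trace(recipe)
        events = [
            SynapticEvent(t, -a, 10.0)
            for t, a in zip(truth.event_onsets, truth.event_amplitudes)
        ]
        stats = event_statistics(events, 120.0)
        assert stats["frequency_hz"] == pytest.approx(10.0, abs=1.0)


class TestKinetics:
    @staticmethod
    def make_evoked(tau_ms=30.0, rise_ms=1.5, amp=100.0, noise_sd=0.0, seed=0):
        t = np.arange(0, 0.25, 1 / RATE)
        t_stim = 0.02
        y = np.zeros_like(t)
        after = t >= t_stim
        ta = t[after] - t_stim
        y[after] = -(np.exp(-ta / (tau_ms * 1e-3)) - np.exp(-ta / (rise_ms * 1e-3)))
        y *= amp / np.abs(y).max()
        if noise_sd:
            y = y + noise_sd * np.random.default_rng(seed).standard_normal(t.size)
        return TimeSeries(y, RATE, units="pA")

    def test_exponential_rise_closed_form(self):
        # saturating exponential rise tau_r: 20-80% time = tau_r * ln 4
        t = np.arange(0, 0.1, 1 / RATE)
        tau_r = 2e-3
        y = np.zeros_like(t)
        after = t >= 0.01
        y[after] = -(1 - np.exp(-(t[after] - 0.01) / tau_r))
        rise = rise_time_20_80(TimeSeries(y, RATE, units="pA"))
        assert rise == pytest.approx(2.0 * np.log(4), rel=0.02)

    def test_linear_ramp_rise(self):
        t = np.arange(0, 0.05, 1 / RATE)
        y = -np.clip((t - 0.01) / 0.01, 0, 1)
        rise = rise_time_20_80(TimeSeries(y, RATE, units="pA"))
        assert rise == pytest.approx(6.0, rel=0.02)

    @pytest.mark.parametrize("scale", [0.5, 2.0])
    def test_rise_scale_invariance(self, scale):
        sweep = self.make_evoked()
        a = rise_time_20_80(sweep)
        b = rise_time_20_80(sweep.with_samples(scale * sweep.samples))
        assert a == pytest.approx(b, rel=1e-9)

    def test_noiseless_tau_recovery(self):
        kin = fit_decay_monoexp(self.make_evoked(tau_ms=30.0), fit_end_s=0.25)
        assert kin.decay_tau_ms == pytest.approx(30.0, abs=0.5)
        assert kin.peak_pA == pytest.approx(-100.0, rel=0.01)
        assert kin.rise_20_80_ms > 0

    def test_noisy_tau_within_5pct_over_seeds(self):
        taus = [
            fit_decay_monoexp(
                self.make_evoked(tau_ms=30.0, noise_sd=5.0, seed=s),
                fit_end_s=0.25,
                baseline_window_s=0.015,
            ).decay_tau_ms
            for s in range(100)
        ]
        taus = np.array(taus)
        # Monte-Carlo mean and dispersion of the estimator both within 5%
        assert np.abs(taus.mean() - 30.0) / 30.0 < 0.05
        assert taus.std() / 30.0 < 0.05

    def test_genotype_tau_difference_distinguishable(self):
        """Decay constants 31.1 vs 26.2 ms separate at n=10 sweeps (95% CIs)."""
        from scipy import stats as sps

        def cohort(tau, seed0):
            return np.array(
                [
                    fit_decay_monoexp(
                        self.make_evoked(tau_ms=tau, noise_sd=5.0, seed=1000 + seed0 + s),
                        fit_end_s=0.25,
                    ).decay_tau_ms
                    for s in range(10)
                ]
            )

        ctrl, ko = cohort(31.1, 0), cohort(26.2, 50)
        tcrit = sps.t.ppf(0.975, 9)
        ci_ctrl = (ctrl.mean() - tcrit * sps.sem(ctrl), ctrl.mean() + tcrit * sps.sem(ctrl))
        ci_ko = (ko.mean() - tcrit * sps.sem(ko), ko.mean() + tcrit * sps.sem(ko))
        assert ci_ko[1] < ci_ctrl[0]

    def test_non_decaying_segment_rejected(self):
        t = np.arange(0, 0.1, 1 / RATE)
        y = -np.clip(t * 10, 0, 1)  # monotone growth of inward current
        with pytest.raises((FitError, ParameterError)):
            fit_decay_monoexp(TimeSeries(y, RATE, units="pA"), fit_end_s=0.1)


class TestToxinSplit:
    def test_arithmetic(self):
        split = toxin_component(np.full(5, 100.0), np.full(5, 40.0))
        assert split.sensitive_percent == pytest.approx(60.0)

    def test_no_drug_effect(self):
        split = toxin_component(np.full(5, 80.0), np.full(5, 80.0))
        assert split.sensitive_percent == pytest.approx(0.0)

    @pytest.mark.parametrize("f", [0.0, 0.1, 0.582, 0.9, 1.0])
    def test_exact_identity(self, f):
        x = np.array([120.0, 115.0, 118.0, 122.0, 119.0])
        split = toxin_component(x, x * (1 - f))
        assert split.sensitive_percent == pytest.approx(100.0 * f, abs=1e-9)

    def test_facilitation_flagged(self):
        split = toxin_component(np.full(5, 50.0), np.full(5, 60.0))
        assert split.negative_flag
        assert split.sensitive_percent < 0

    def test_zero_control_rejected(self):
        with pytest.raises(DataError):
            toxin_component(np.zeros(5), np.full(5, 10.0))

    def test_stochastic_recovery_via_evoked_generator(self):
        """CCK-like fraction 0.582 at cv 0.15, n=10 sweeps: recovered within 5 points."""

        def peak_amps(drug):
            sweeps, _ = gen_current_trace(
                CurrentRecipe(
                    mode="evoked", drug_blocks=drug, response_cv=0.15,
                    noise_sd_pA=2.0, n_sweeps=10, seed=5 if drug else 6,
                )
            )
            return [np.abs(s.samples).max() for s in sweeps]

        split = toxin_component(peak_amps(None), peak_amps("cck"))
        assert split.sensitive_percent == pytest.approx(58.2, abs=5.0)


class TestTrainRatio:
    def test_depressing_train(self):
        resp = train_ratio(np.array([100.0, 80.0, 65.0, 55.0, 48.0]))
        assert resp.ratio_last_first == pytest.approx(0.48)

    def test_constant_train(self):
        assert train_ratio(np.full(5, 42.0)).ratio_last_first == pytest.approx(1.0)

    def test_strong_depression(self):
        resp = train_ratio(np.array([100.0, 70.0, 50.0, 35.0, 28.0]))
        assert resp.ratio_last_first == pytest.approx(0.28)

    def test_wrong_count_rejected(self):
        with pytest.raises(ParameterError):
            train_ratio(np.array([1.0, 2.0, 3.0]))
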