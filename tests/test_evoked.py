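"""Evoked metrics, charge kinetics, cooperativity, paired pulses, trains."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from quantal.datatypes import StimProtocol, Trace
from quantal.evoked import (analyze_train, cumulative_charge, decompose_charge,
                            evoked_metrics, fit_cooperativity, paired_pulse,
                            pool_estimates, quantal_content, time_to_fraction)
from quantal.minis import MiniSummary
from quantal.synth import quantal_kernel

FS = 10_000.0


def _mini_ref(amp=0.58, area=4.0):
    return MiniSummary(100, 2.7, amp, area, np.empty(0))


class TestEvokedMetrics:
    def test_rectangular_pulse_closed_form(self):
        cur = np.zeros(3000)
        cur[1000:1100] = -2.0  # 10 ms pulse of 2 nA
        m = evoked_metrics(Trace(cur, fs=FS), 0.1, window_ms=50, blank_ms=0)
        assert m.peak == pytest.approx(2.0)
        assert m.area == pytest.approx(20.0)
        assert m.t90 == pytest.approx(9.0, abs=0.05)

    def test_quantal_content_reproduces_ratio_of_means(self):
        # control and mutant group means: peak / mini peak
        assert quantal_content(51.78, 0.5898) == pytest.approx(87.79, abs=0.005)
        assert quantal_content(83.74, 0.5771) == pytest.approx(145.1, abs=0.05)

    def test_qc_of_n_simultaneous_quanta_is_exactly_n(self):
        q, n_quanta = 0.6, 7
        k = quantal_kernel(1.0, 6.0, FS)
        imp = np.zeros(4000)
        imp[1000] = q * n_quanta
        cur = -fftconvolve(imp, k)[:4000]
        kernel_area = k.sum() * 1000.0 / FS
        ref = _mini_ref(amp=q, area=q * kernel_area)
        m = evoked_metrics(Trace(cur, fs=FS), 0.1, window_ms=200, blank_ms=0)
        qc = quantal_content(m.peak, ref.mean_amplitude)
        assert qc == pytest.approx(n_quanta, rel=1e-9)

    def test_missing_mini_reference_rejected_for_qc(self):
        with pytest.raises(ValueError):
            quantal_content(10.0, None)

    def test_stim_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            evoked_metrics(Trace(np.zeros(1000), fs=FS), 5.0)


class TestCumulativeCharge:
    def test_rectangular_pulse_fraction_times(self):
        cur = np.zeros(3000)
        cur[1000:1100] = -1.0
        curve = cumulative_charge(Trace(cur, fs=FS), 0.1, window_ms=10, blank_ms=0)
        assert time_to_fraction(curve, 0.9) == pytest.approx(9.0, abs=0.05)
        assert time_to_fraction(curve, 0.5) == pytest.approx(5.0, abs=0.05)

    def test_exponential_decay_t90_analytic(self):
        t = np.arange(0, 0.3, 1 / FS)
        cur = np.concatenate([np.zeros(100), -np.exp(-t / 0.005)])
        curve = cumulative_charge(Trace(cur, fs=FS), 0.01, window_ms=250, blank_ms=0)
        assert time_to_fraction(curve, 0.9) == pytest.approx(-5 * np.log(0.1), abs=0.02)

    def test_curve_endpoints_normalized(self):
        cur = np.zeros(3000)
        cur[1000:1200] = -1.0
        t_ms, c = cumulative_charge(Trace(cur, fs=FS), 0.1, window_ms=50, blank_ms=0)
        assert c[0] == 0.0 and c[-1] == pytest.approx(1.0)
        assert np.all(np.diff(c) >= -1e-12)

    def test_zero_trace_total_charge_undefined(self):
        with pytest.raises(ValueError, match="charge"):
            cumulative_charge(Trace(np.zeros(3000), fs=FS), 0.1, blank_ms=0)


class TestDecomposeCharge:
    T = 200.0

    def _curve(self, w, tf, ts, noise=0.0, seed=0):
        t = np.linspace(0, self.T, 2001)
        L = lambda tau: np.log1p(t / tau) / np.log1p(self.T / tau)
        c = w * L(tf) + (1 - w) * L(ts)
        if noise:
            c = c + noise * np.random.default_rng(seed).standard_normal(t.size)
        return t, c

    def test_noiseless_recovery(self):
        dec = decompose_charge(self._curve(0.55, 2.0, 40.0))
        assert dec.converged
        assert dec.w_fast == pytest.approx(0.55, abs=0.02)
        assert dec.tau_slow > dec.tau_fast

    def test_single_component_degenerates_to_small_slow_percent(self):
        t = np.linspace(0, self.T, 2001)
        c = np.log1p(t / 3.0) / np.log1p(self.T / 3.0)
        dec = decompose_charge((t, c))
        # either the slow weight or the tau separation collapses
        assert dec.slow_percent <= 2.0 or abs(dec.tau_slow - dec.tau_fast) < 1e-3 \
            or dec.residual < 1e-4

    def test_biexp_form_also_recovers(self):
        t = np.linspace(0, self.T, 2001)
        E = lambda tau: (1 - np.exp(-t / tau)) / (1 - np.exp(-self.T / tau))
        c = 0.7 * E(3.0) + 0.3 * E(60.0)
        dec = decompose_charge((t, c), form="biexp")
        assert dec.w_fast == pytest.approx(0.7, abs=0.02)

    def test_curve_too_short_rejected(self):
        with pytest.raises(ValueError):
            decompose_charge((np.arange(4.0), np.arange(4.0) / 3))


class TestCooperativity:
    CA = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.75])

    def _responses(self, hill=3.2, ec50=0.5, top=100.0, bottom=2.0):
        return bottom + (top - bottom) / (1 + (ec50 / self.CA) ** hill)

    def test_noiseless_exact_recovery(self):
        fit = fit_cooperativity(self.CA, self._responses())
        assert fit.hill == pytest.approx(3.2, abs=1e-5)
        assert fit.ec50 == pytest.approx(0.5, abs=1e-5)

    def test_recovery_under_noise_across_replicates(self):
        rng = np.random.default_rng(17)
        hills = []
        for _ in range(50):
            y = self._responses() * (1 + 0.05 * rng.standard_normal(self.CA.size))
            hills.append(fit_cooperativity(self.CA, y).hill)
        assert np.mean(hills) == pytest.approx(3.2, abs=0.15)

    def test_equal_hill_with_different_top_amplitudes(self):
        # scaling the response amplitude must not change the cooperativity
        fit_a = fit_cooperativity(self.CA, self._responses(top=100))
        fit_b = fit_cooperativity(self.CA, self._responses(top=180))
        assert fit_a.hill == pytest.approx(fit_b.hill, abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_cooperativity([0.1, 0.2, 0.3], [1, 2, 3])


class TestPairedPulse:
    def _trace_with_pair(self, ratio, isi_ms=25.0, q=20.0):
        k = quantal_kernel(1.0, 6.0, FS)
        n = 8000
        imp = np.zeros(n)
        imp[2000] = q
        imp[2000 + int(isi_ms * 10)] = q * ratio
        cur = -fftconvolve(imp, k)[:n]
        return Trace(cur, fs=FS)

    def test_identical_nonoverlapping_responses(self):
        tr = self._trace_with_pair(1.0, isi_ms=75.0)
        ppr, reliable = paired_pulse(tr, 0.2, 0.275, blank_ms=0)
        assert reliable
        assert ppr == pytest.approx(1.0, abs=0.02)

    def test_overlap_corrected_ratio(self):
        tr = self._trace_with_pair(1.5, isi_ms=25.0)
        ppr, _ = paired_pulse(tr, 0.2, 0.225, blank_ms=0)
        assert ppr == pytest.approx(1.5, abs=0.02)

    def test_zero_second_response(self):
        tr = self._trace_with_pair(0.0, isi_ms=50.0)
        ppr, _ = paired_pulse(tr, 0.2, 0.25, blank_ms=0)
        assert ppr == pytest.approx(0.0, abs=0.02)

    def test_small_first_response_flagged_unreliable(self):
        rng = np.random.default_rng(3)
        tr = self._trace_with_pair(1.0, isi_ms=50.0, q=0.1)
        tr = Trace(tr.current + 0.05 * rng.standard_normal(tr.n_samples), fs=FS)
        _, reliable = paired_pulse(tr, 0.2, 0.25, blank_ms=0)
        assert not reliable


class TestTrains:
    def test_constant_qc_sequence_has_no_depletion_signature(self):
        ta = pool_estimates(np.full(1500, 50.0), 10.0)
        assert ta.depression_index(30) == pytest.approx(1.0)
        assert ta.irp == pytest.approx(30 * 50.0)
        assert ta.rrp == pytest.approx(0.0, abs=1e-6)
        assert ta.recycling_rate == pytest.approx(500.0)

    def test_geometric_depression_closed_form(self):
        qc = 100.0 * 0.8 ** np.arange(40)
        ta = pool_estimates(qc, 10.0)
        assert ta.depression_index(5) == pytest.approx(0.8**3)
        assert ta.depression_index(2) == 1.0

    def test_train_from_rendered_trace_recovers_counts(self):
        from quantal.synth import (ReleaseModelParams, kernel_charge,
                                   simulate_release, synthesize_trace)

        p = ReleaseModelParams(n_az=100, slots_per_az=5, p_v=0.3, rho=0.3,
                               mini_rate=0.0, seed=5)
        prot = StimProtocol.periodic(40, 10.0)
        rec = simulate_release(p, prot)
        tr = synthesize_trace(rec)
        ref = MiniSummary(1, 1.0, p.q_mean, p.q_mean * kernel_charge(p), np.empty(0))
        ta = analyze_train(tr, prot, mini_ref=ref)
        true_counts = rec.releases_per_stimulus
        # asynchronous tails shuffle ~10% of charge between adjacent windows
        assert ta.qc_per_stimulus == pytest.approx(true_counts, rel=0.10)
        assert ta.irp == pytest.approx(true_counts[:30].sum(), rel=0.02)
        assert ta.qc_per_stimulus.sum() == pytest.approx(true_counts.sum(), rel=0.02)

    def test_irregular_protocol_rejected(self):
        tr = Trace(np.zeros(40_000), fs=FS)
        prot = StimProtocol(np.array([0.5, 0.6, 0.75]), frequency=10.0)
        with pytest.raises(ValueError, match="irregular|missing"):
            analyze_train(tr, prot)
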