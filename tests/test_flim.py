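import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trifret import (
    DecayHistogram,
    average_lifetime,
    efficiency_from_lifetimes,
    fit_decay,
    load_decay,
    save_decay,
    simulate_decay,
    tail_lifetime,
    ternary_excess_quenching,
)
from trifret.flim import _periodic_exponentials, gaussian_irf


class TestSimulateDecay:
    def test_tail_slope_matches_lifetime(self):
        """Log-linear tail fit (independent of the reconvolution code) recovers tau."""
        hist = simulate_decay([3.99], n_photons=1_000_000, seed=5)
        assert tail_lifetime(hist) == pytest.approx(3.99, abs=0.01)

    def test_total_counts_exact_and_deterministic(self):
        h1 = simulate_decay([2.0], n_photons=123_457, seed=9)
        h2 = simulate_decay([2.0], n_photons=123_457, seed=9)
        assert h1.total_counts == 123_457
        np.testing.assert_array_equal(h1.counts, h2.counts)

    def test_degenerate_second_component_matches_mono(self):
        mono = simulate_decay([3.0], n_photons=200_000, seed=4)
        bi = simulate_decay([3.0, 1.0], [1.0, 0.0], n_photons=200_000, seed=4)
        np.testing.assert_array_equal(mono.counts, bi.counts)

    def test_unresolvable_lifetime_rejected(self):
        with pytest.raises(ValueError, match="period"):
            simulate_decay([400.0], n_photons=1000, seed=1)

    def test_wraparound_baseline_matches_periodic_steady_state(self):
        """Pre-pulse bins hold the analytic periodic residual of the incomplete decay."""
        tau, period, n_photons = 4.0, 25.0, 5_000_000
        hist = simulate_decay([tau], n_photons=n_photons, seed=8, irf_center=5.0)
        # well before the IRF (t < 2 ns) the signal is the wrapped tail of the
        # previous pulse: exp(-(t + period - t0)/tau) / (1 - exp(-period/tau))
        pre = hist.bin_times < 2.0
        wrapped = _periodic_exponentials(
            hist.bin_times - 5.0 + hist.period, hist.period, [tau]
        )[0]
        model = _periodic_exponentials(hist.bin_times, hist.period, [tau])[0]
        observed = hist.counts[pre].sum() / n_photons
        predicted = wrapped[pre].sum() / model.sum()
        assert observed == pytest.approx(predicted, rel=0.02)


class TestFitDecay:
    def test_noise_free_mono_recovery(self):
        """Fitting the exact forward curve recovers tau to 0.1%."""
        hist = simulate_decay([3.99], n_photons=50_000_000, seed=2)
        fit = fit_decay(hist)
        assert fit.lifetimes[0] == pytest.approx(3.99, rel=1e-3)
        assert fit.tau_avg == pytest.approx(3.99, rel=1e-3)

    def test_mono_recovery_across_lifetime_photon_grid(self):
        """Forward-inverse consistency over tau x photon-budget grid."""
        for tau in (0.5, 1.0, 2.0, 4.0):
            for n_photons, tol in ((10_000, 0.05), (100_000, 0.02), (1_000_000, 0.01)):
                hist = simulate_decay([tau], n_photons=n_photons,
                                      seed=hash((tau, n_photons)) % 2**31)
                fit = fit_decay(hist)
                assert fit.lifetimes[0] == pytest.approx(tau, rel=tol)

    def test_biexponential_recovery(self):
        """tau pair (3.99, 1.2), intensity fractions 0.6/0.4: 5%/2% recovery over seeds."""
        taus = np.array([3.99, 1.2])
        amps = np.array([0.6 / 3.99, 0.4 / 1.2])
        amps = amps / amps.sum()
        true_avg = float(amps @ taus**2 / (amps @ taus))
        worst_tau, worst_avg = 0.0, 0.0
        for seed in range(50):
            hist = simulate_decay(taus, amps, n_photons=1_000_000, seed=300 + seed)
            fit = fit_decay(hist, n_components=2)
            worst_tau = max(worst_tau, np.max(np.abs(fit.lifetimes - taus) / taus))
            worst_avg = max(worst_avg, abs(fit.tau_avg - true_avg) / true_avg)
        assert worst_tau < 0.05
        assert worst_avg < 0.02

    def test_overparameterized_fit_keeps_average_lifetime(self):
        hist = simulate_decay([3.5], n_photons=1_000_000, seed=77)
        mono = fit_decay(hist, 1)
        bi = fit_decay(hist, 2)
        assert bi.tau_avg == pytest.approx(mono.tau_avg, rel=0.01)

    def test_low_count_warning(self):
        hist = simulate_decay([3.0], n_photons=500, seed=1)
        with pytest.warns(UserWarning, match="photons"):
            fit_decay(hist)

    def test_fit_with_timing_shift(self):
        """A deliberately shifted IRF is absorbed by the shift parameter."""
        hist = simulate_decay([3.0], n_photons=2_000_000, seed=6, irf_center=2.0)
        shifted = DecayHistogram(
            bin_times=hist.bin_times,
            counts=hist.counts,
            irf=np.roll(hist.irf, -4),  # ~0.1 ns early
            period=hist.period,
        )
        fit = fit_decay(shifted, 1, fit_shift=True)
        dt = hist.period / len(hist.bin_times)
        assert fit.shift == pytest.approx(4 * dt, abs=dt)
        assert fit.lifetimes[0] == pytest.approx(3.0, rel=0.01)


class TestAverageLifetime:
    def test_single_component_identity(self):
        assert average_lifetime([1.0], [4.0]) == 4.0

    def test_hand_arithmetic(self):
        assert average_lifetime([1.0, 1.0], [4.0, 2.0]) == pytest.approx(10.0 / 3.0)

    def test_zero_amplitude_component_ignored(self):
        assert average_lifetime([1.0, 0.0], [4.0, 2.0]) == 4.0

    def test_all_zero_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            average_lifetime([0.0, 0.0], [4.0, 2.0])


class TestEfficiencyFromLifetimes:
    def test_equal_lifetimes_give_zero(self):
        assert efficiency_from_lifetimes(3.99, 3.99) == 0.0

    def test_ternary_and_binary_closed_forms(self):
        assert efficiency_from_lifetimes(3.40, 3.99) == pytest.approx(0.148, abs=0.0005)
        assert efficiency_from_lifetimes(3.54, 3.99) == pytest.approx(0.113, abs=0.0005)

    def test_negative_efficiency_passed_through(self):
        assert efficiency_from_lifetimes(4.2, 3.99) < 0.0

    @settings(deadline=None, max_examples=50)
    @given(tau_d=st.floats(0.5, 10.0), frac=st.floats(0.05, 1.5))
    def test_antitone_in_quenched_lifetime(self, tau_d, frac):
        tau_da = frac * tau_d
        e = efficiency_from_lifetimes(tau_da, tau_d)
        e_more = efficiency_from_lifetimes(tau_da * 0.9, tau_d)
        assert e_more > e
        assert e < 1.0


class TestTernaryExcessQuenching:
    def _sets(self, rng, ternary=3.40, b1=3.54, b2=3.54, donor=3.99, sd=0.05, n=20):
        return (
            rng.normal(ternary, sd, n),
            rng.normal(b1, sd, n),
            rng.normal(b2, sd, n),
            rng.normal(donor, sd, n),
        )

    def test_study_regime_supported(self):
        """The published lifetime pattern (3.40 vs 3.54/3.54, donor 3.99) is supported."""
        decision = ternary_excess_quenching(*self._sets(np.random.default_rng(12)))
        assert decision.supported
        assert decision.excess_quenching == pytest.approx(0.14, abs=0.05)
        assert decision.efficiency_ternary == pytest.approx(0.148, abs=0.02)

    def test_ternary_equal_to_binary_not_supported(self):
        rng = np.random.default_rng(3)
        t = rng.normal(3.54, 0.0, 5)
        decision = ternary_excess_quenching(t, t, t + 0.1, rng.normal(3.99, 0.0, 5))
        assert decision.excess_quenching == pytest.approx(0.0, abs=1e-12)
        assert not decision.supported

    def test_ternary_equal_to_donor_not_supported(self):
        decision = ternary_excess_quenching(
            *self._sets(np.random.default_rng(4), ternary=3.99)
        )
        assert decision.excess_quenching < 0
        assert not decision.supported

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            ternary_excess_quenching([3.4, 3.4], [3.5] * 5, [3.5] * 5, [4.0] * 5)


class TestDecayIO:
    def test_round_trip_single_file(self, tmp_path):
        hist = simulate_decay([2.5], n_photons=10_000, seed=11)
        path = tmp_path / "decay.csv"
        save_decay(hist, path)
        back = load_decay(path)
        np.testing.assert_array_equal(back.counts, hist.counts)
        np.testing.assert_allclose(back.irf, hist.irf, rtol=1e-12)
        assert back.period == pytest.approx(hist.period)

    def test_round_trip_companion_irf(self, tmp_path):
        hist = simulate_decay([2.5], n_photons=10_000, seed=11)
        d, i = tmp_path / "decay.csv", tmp_path / "irf.csv"
        save_decay(hist, d, i)
        back = load_decay(d, i)
        np.testing.assert_array_equal(back.counts, hist.counts)
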