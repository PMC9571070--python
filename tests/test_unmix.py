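import math

import numpy as np
import pytest

from trifret import (
    LEICA,
    RatioTaggedSample,
    SpectralScene,
    bin_spectrum,
    donor_acceptor_ratio,
    ratio_matched_compare,
    reference_stacks,
    response_matrix,
    sensitized_emission_flag,
    simulate_emission,
    unmix,
)
from trifret.spectra_sim import channel_intensities


@pytest.fixture(scope="module")
def refs(fluorophores, leica):
    records = [fluorophores[n] for n in ("mTRQ2", "mVEN", "mRFP")]
    return reference_stacks(records, leica), tuple(r.name for r in records)


class TestUnmix:
    def test_pure_component_recovered_exactly(self, refs):
        basis, names = refs
        res = unmix(37.0 * basis[1], basis, fit_background=False, reference_names=names)
        assert res.coefficients[1] == pytest.approx(37.0, rel=1e-9)
        assert res.coefficients[0] == pytest.approx(0.0, abs=1e-9)
        assert res.coefficients[2] == pytest.approx(0.0, abs=1e-9)
        assert res.residual_rms == pytest.approx(0.0, abs=1e-9)
        assert res.proportions[1] == pytest.approx(1.0)

    def test_round_trip_recovers_component_integrals(self, ternary_scene, refs, leica):
        """Noise-free unmixing recovers each member's emitted quanta from the stack."""
        basis, names = refs
        spec = simulate_emission(ternary_scene)
        stack = bin_spectrum(spec, leica)
        res = unmix(stack, basis, fit_background=False)
        np.testing.assert_allclose(res.coefficients, spec.emitted, rtol=1e-6)

    def test_noisy_proportions_recovered(self, ternary_scene, refs, leica):
        """2% peak noise keeps proportion errors within 0.02 absolute (Monte-Carlo)."""
        basis, names = refs
        spec = simulate_emission(ternary_scene)
        stack = bin_spectrum(spec, leica)
        truth = spec.emitted / spec.emitted.sum()
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            noisy = stack + rng.normal(0.0, 0.02 * stack.max(), size=stack.shape)
            res = unmix(noisy, basis, fit_background=False)
            errors.append(np.max(np.abs(res.proportions - truth)))
        errors = np.array(errors)
        assert np.mean(errors) < 0.02
        assert np.mean(errors <= 0.02) >= 0.95

    def test_proportions_invariant_to_global_scale(self, ternary_scene, refs, leica):
        basis, _ = refs
        stack = bin_spectrum(simulate_emission(ternary_scene), leica)
        p1 = unmix(stack, basis).proportions
        p2 = unmix(1234.5 * stack, basis).proportions
        np.testing.assert_allclose(p1, p2, rtol=1e-9)

    def test_collinear_references_rejected(self, refs):
        basis, names = refs
        doubled = np.vstack([basis, 2.0 * basis[0]])
        with pytest.raises(ValueError, match="collinear"):
            unmix(basis[0], doubled, reference_names=names + ("copy",))

    def test_background_absorbed_by_offset_term(self, refs):
        basis, _ = refs
        stack = 10.0 * basis[0] + 5.0
        res = unmix(stack, basis, fit_background=True)
        assert res.background == pytest.approx(5.0, rel=1e-6)
        assert res.coefficients[0] == pytest.approx(10.0, rel=1e-6)


class TestDonorAcceptorRatio:
    def test_identity_response_one_to_four(self):
        ratio = donor_acceptor_ratio([120.0, 480.0, 0.0], np.eye(3))
        assert ratio == pytest.approx(0.25)

    def test_zero_acceptor_gives_inf_sentinel(self):
        assert math.isinf(donor_acceptor_ratio([120.0, 0.0, 0.0], np.eye(3)))

    def test_bleedthrough_inversion_self_consistent(self, fluorophores, leica):
        """Response matrix from pure members recovers a mixed scene's true ratio."""
        records = [fluorophores[n] for n in ("mTRQ2", "mVEN", "mRFP")]
        m = response_matrix(records, leica)
        scene = SpectralScene(
            tuple(zip(records, (1.0, 4.0, 2.0))), np.zeros((3, 3)), 458.0
        )
        channels = channel_intensities(scene, leica)
        assert donor_acceptor_ratio(channels, m) == pytest.approx(0.25, rel=1e-9)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="invertible"):
            donor_acceptor_ratio([1.0, 1.0], np.ones((2, 2)))

    def test_negative_abundance_clamped_with_warning(self):
        m = np.array([[1.0, 0.9], [0.0, 1.0]])
        with pytest.warns(UserWarning, match="clamped"):
            donor_acceptor_ratio([0.5, 1.0], m)


def _simulated_sample(records, basis, e_da1, label, seed, leica):
    """One synthetic ROI: jittered expression, optional FRET, 2% stack noise."""
    rng = np.random.default_rng(seed)
    amounts = (1.0, 4.0 * rng.lognormal(0.0, 0.15))
    transfer = np.array([[0.0, e_da1], [0.0, 0.0]])
    scene = SpectralScene(tuple(zip(records, amounts)), transfer, 458.0)
    stack = bin_spectrum(simulate_emission(scene), leica)
    stack = stack + rng.normal(0.0, 0.02 * stack.max(), size=stack.shape)
    res = unmix(stack, basis)
    return RatioTaggedSample(unmix=res, da_ratio=amounts[0] / amounts[1], label=label)


@pytest.fixture(scope="module")
def pair_setup(fluorophores, leica):
    records = [fluorophores["mTRQ2"], fluorophores["mVEN"]]
    return records, reference_stacks(records, leica)


class TestRatioMatchedCompare:
    def test_identical_groups_give_zero_difference(self, pair_setup, leica):
        records, basis = pair_setup
        samples = [
            _simulated_sample(records, basis, 0.0, label, seed, leica)
            for label in ("a", "b")
            for seed in range(5)
        ]
        out = ratio_matched_compare(samples, "a", "b")
        assert out.difference == pytest.approx(0.0, abs=1e-12)
        assert out.n_a == out.n_b == 5

    def test_fret_detected_at_matched_ratios(self, pair_setup, leica):
        """A 15% donor->acceptor pathway raises the acceptor proportion in >=95% of trials."""
        records, basis = pair_setup
        detected = 0
        n_trials = 200
        for trial in range(n_trials):
            samples = [
                _simulated_sample(records, basis, 0.15, "fret", 10_000 + trial * 20 + k, leica)
                for k in range(6)
            ] + [
                _simulated_sample(records, basis, 0.0, "ctrl", 50_000 + trial * 20 + k, leica)
                for k in range(6)
            ]
            out = ratio_matched_compare(samples, "fret", "ctrl")
            detected += out.difference > 0
        assert detected / n_trials >= 0.95

    def test_disjoint_ratio_ranges_rejected(self, pair_setup, leica):
        records, basis = pair_setup
        samples = [
            _simulated_sample(records, basis, 0.0, "a", s, leica) for s in range(4)
        ]
        far = [
            RatioTaggedSample(unmix=s.unmix, da_ratio=s.da_ratio * 100.0, label="b")
            for s in samples
        ]
        with pytest.raises(ValueError, match="ratio band"):
            ratio_matched_compare(samples + far, "a", "b", ratio_tolerance=0.25)


@pytest.fixture(scope="module")
def condition_stacks(fluorophores, ternary_scene, leica):
    from trifret import fret_efficiency

    d, a1, a2 = (fluorophores[n] for n in ("mTRQ2", "mVEN", "mRFP"))
    e = fret_efficiency(7.0, 5.7)
    donor_only = SpectralScene(((d, 1.0),), np.zeros((1, 1)), 458.0)
    binary = SpectralScene(
        ((d, 1.0), (a1, 1.0)), np.array([[0.0, e], [0.0, 0.0]]), 458.0
    )
    uncoupled = SpectralScene(
        ((d, 1.0), (a1, 1.0), (a2, 1.0)),
        np.array([[0.0, e, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]),
        458.0,
    )
    return {
        "donor": bin_spectrum(simulate_emission(donor_only), leica),
        "binary": bin_spectrum(simulate_emission(binary), leica),
        "uncoupled": bin_spectrum(simulate_emission(uncoupled), leica),
        "ternary": bin_spectrum(simulate_emission(ternary_scene), leica),
    }


class TestSensitizedEmissionFlag:
    def test_cascade_signature_raised_only_for_ternary(self, condition_stacks, leica):
        report = sensitized_emission_flag(
            condition_stacks, leica, baseline_label="donor",
            intermediate_reference_label="binary",
        )
        assert report["ternary"].terminal_sensitized
        assert report["ternary"].cascade_signature
        assert not report["uncoupled"].terminal_sensitized
        assert not report["uncoupled"].cascade_signature
        assert not report["binary"].cascade_signature
        assert not report["donor"].cascade_signature

    def test_baseline_against_itself_not_flagged(self, condition_stacks, leica):
        report = sensitized_emission_flag(
            {"donor": condition_stacks["donor"]}, leica, baseline_label="donor"
        )
        assert not report["donor"].terminal_sensitized

    def test_missing_baseline_rejected(self, condition_stacks, leica):
        with pytest.raises(ValueError, match="baseline"):
            sensitized_emission_flag(condition_stacks, leica, baseline_label="absent")
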