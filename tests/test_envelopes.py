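"""Isotope envelopes, Poisson-binomial convolution, EX1 bimodality detection."""

import itertools
import math

import numpy as np
import pytest

from hdxdiff.corrections import LabellingCondition
from hdxdiff.envelopes import (
    IsotopeEnvelope,
    deuterated_envelope,
    detect_bimodality,
    mix_envelopes,
    natural_isotope_distribution,
    recover_k_open,
    simulate_pulse_label,
)
from hdxdiff.io import PeptideRecord
from hdxdiff.simulate import (
    ConformationalState,
    Unfolding,
    random_exchange_model,
    random_protein_sequence,
)


def poisson_binomial_exhaustive(ps):
    """Oracle: exact Poisson-binomial pmf by enumerating all 2^N outcomes."""
    n = len(ps)
    pmf = np.zeros(n + 1)
    for outcome in itertools.product([0, 1], repeat=n):
        prob = 1.0
        for p, o in zip(ps, outcome):
            prob *= p if o else 1 - p
        pmf[sum(outcome)] += prob
    return pmf


class TestNaturalEnvelope:
    def test_glycine_monoisotopic_dominant(self):
        env = natural_isotope_distribution("G")
        assert env.intensities[0] > 0.9
        assert env.intensities.argmax() == 0

    def test_normalized(self, myoglobin_peptide):
        env = natural_isotope_distribution(myoglobin_peptide.sequence)
        assert env.intensities.sum() == pytest.approx(1.0, abs=1e-9)
        assert (env.intensities >= 0).all()

    def test_longer_sequence_shifts_centroid(self):
        short = natural_isotope_distribution("GLSDGEWQLV")
        long = natural_isotope_distribution("GLSDGEWQLV" * 2)
        assert long.centroid > short.centroid


class TestDeuteratedEnvelope:
    def test_zero_probabilities_identity(self, myoglobin_peptide):
        nat = natural_isotope_distribution(myoglobin_peptide.sequence)
        out = deuterated_envelope(nat, [0.0] * 8)
        np.testing.assert_allclose(out.intensities[: len(nat.intensities)], nat.intensities)

    def test_saturation_shifts_by_n(self, myoglobin_peptide):
        nat = natural_isotope_distribution(myoglobin_peptide.sequence)
        out = deuterated_envelope(nat, [1.0] * 7)
        assert out.centroid == pytest.approx(nat.centroid + 7, abs=1e-9)
        np.testing.assert_allclose(out.intensities[7:], nat.intensities, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_poisson_binomial(self, seed):
        rng = np.random.default_rng(seed)
        ps = rng.uniform(0, 1, size=8)
        nat = IsotopeEnvelope(np.array([1.0]))  # delta at 0 isolates the PB part
        out = deuterated_envelope(nat, ps)
        oracle = poisson_binomial_exhaustive(ps)
        np.testing.assert_allclose(out.intensities, oracle, atol=1e-12)
        assert out.centroid == pytest.approx(ps.sum(), abs=1e-9)

    def test_centroid_additivity_on_real_envelope(self, myoglobin_peptide):
        rng = np.random.default_rng(3)
        ps = rng.uniform(0, 1, size=10)
        nat = natural_isotope_distribution(myoglobin_peptide.sequence)
        out = deuterated_envelope(nat, ps)
        assert out.centroid == pytest.approx(nat.centroid + ps.sum(), abs=1e-6)

    def test_invalid_probability_rejected(self, myoglobin_peptide):
        nat = natural_isotope_distribution(myoglobin_peptide.sequence)
        with pytest.raises(ValueError):
            deuterated_envelope(nat, [0.5, 1.2])


class TestMixing:
    @pytest.fixture
    def pair(self, myoglobin_peptide):
        nat = natural_isotope_distribution(myoglobin_peptide.sequence)
        n = myoglobin_peptide.n_exchangeable
        lo = deuterated_envelope(nat, [0.12] * n)
        hi = deuterated_envelope(nat, [0.47] * n)
        return lo, hi

    def test_pure_weights_are_identities(self, pair):
        lo, hi = pair
        np.testing.assert_allclose(mix_envelopes(lo, hi, 1.0).intensities[: len(lo.intensities)],
                                   lo.intensities)

    def test_even_mixture_has_two_maxima(self, pair):
        lo, hi = pair
        mixed = mix_envelopes(lo, hi, 0.5).intensities
        local_maxima = sum(
            1
            for i in range(1, len(mixed) - 1)
            if mixed[i] > mixed[i - 1] and mixed[i] >= mixed[i + 1] and mixed[i] > 0.01
        )
        assert local_maxima == 2

    def test_centroid_linear_in_weight(self, pair):
        lo, hi = pair
        for w in (0.0, 0.25, 0.5, 0.75, 1.0):
            mixed = mix_envelopes(lo, hi, w)
            assert mixed.centroid == pytest.approx(
                w * lo.centroid + (1 - w) * hi.centroid, abs=1e-9
            )

    def test_normalization_preserved(self, pair):
        lo, hi = pair
        assert mix_envelopes(lo, hi, 0.3).intensities.sum() == pytest.approx(1.0, abs=1e-9)


class TestBimodalityDetection:
    @pytest.fixture
    def pair(self, myoglobin_peptide):
        nat = natural_isotope_distribution(myoglobin_peptide.sequence)
        n = myoglobin_peptide.n_exchangeable
        lo = deuterated_envelope(nat, [0.12] * n)
        hi = deuterated_envelope(nat, [0.47] * n)  # ~6.5 Da separation
        return lo, hi

    def test_pure_ex2_envelope_unimodal(self, pair):
        lo, hi = pair
        assert not detect_bimodality(lo).is_bimodal
        assert not detect_bimodality(hi).is_bimodal

    def test_even_mixture_detected_with_weights(self, pair):
        lo, hi = pair
        fit = detect_bimodality(mix_envelopes(hi, lo, 0.5))
        assert fit.is_bimodal
        assert fit.weights[0] == pytest.approx(0.5, abs=0.1)
        assert fit.centroids[0] < fit.centroids[1]

    @pytest.mark.parametrize("w", [0.2, 0.5, 0.8])
    def test_weight_recovery_sweep(self, pair, w):
        lo, hi = pair
        fit = detect_bimodality(mix_envelopes(hi, lo, w))
        assert fit.is_bimodal
        assert fit.open_weight == pytest.approx(w, abs=0.1)

    def test_degenerate_envelope_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fit = detect_bimodality(IsotopeEnvelope(np.array([0.5, 0.5])))
        assert not fit.is_bimodal

    def test_roc_at_6da_separation_and_1pct_noise(self, pair):
        # 500 simulated envelopes: >=95% true-positive, <=5% false-positive
        lo, hi = pair
        nat = natural_isotope_distribution("GLSDGEWQLVLNVWGKVEAD")
        rng = np.random.default_rng(17)
        tp = fp = 0
        n_each = 250
        for _ in range(n_each):
            w = rng.uniform(0.2, 0.8)
            env = mix_envelopes(hi, lo, w).with_noise(0.01, rng)
            tp += detect_bimodality(env).is_bimodal
            uni = deuterated_envelope(nat, [rng.uniform(0.1, 0.8)] * 19).with_noise(0.01, rng)
            fp += detect_bimodality(uni).is_bimodal
        assert tp / n_each >= 0.95
        assert fp / n_each <= 0.05


class TestPulseLabelling:
    @pytest.fixture
    def pulse_setup(self):
        seq = random_protein_sequence(60, 3)
        model = random_exchange_model(seq, 3)
        pep = PeptideRecord("p", seq[19:35], 20, 35)
        k_open = math.log(2) / 120.0
        state = ConformationalState(
            "acid", np.full(60, 3.5), Unfolding(k_open, np.full(60, 0.3))
        )
        cond = LabellingCondition(7.4, 0.95)
        return pep, model, state, cond, k_open

    def test_limits_unimodal(self, pulse_setup):
        pep, model, state, cond, k_open = pulse_setup
        pts = simulate_pulse_label(pep, model, state, [0.0, 1e7], 10.0, cond)
        assert not pts[0].fit.is_bimodal
        assert pts[0].w_open_detected == pytest.approx(0.0, abs=1e-9)
        assert not pts[1].fit.is_bimodal
        assert pts[1].w_open_detected == pytest.approx(1.0, abs=1e-9)

    def test_detected_weight_tracks_two_state_kinetics(self, pulse_setup):
        pep, model, state, cond, k_open = pulse_setup
        times = [0, 30, 60, 120, 240, 480, 960]
        pts = simulate_pulse_label(pep, model, state, times, 10.0, cond, noise_sd=0.01, seed=5)
        for p in pts:
            assert p.w_open_detected == pytest.approx(p.w_open_true, abs=0.12)

    def test_k_open_recovered_within_20pct(self, pulse_setup):
        pep, model, state, cond, k_open = pulse_setup
        times = [0, 30, 60, 120, 240, 480, 960]
        pts = simulate_pulse_label(pep, model, state, times, 10.0, cond, noise_sd=0.01, seed=5)
        k_fit = recover_k_open(pts)
        assert abs(k_fit - k_open) / k_open < 0.2

    def test_missing_unfolding_rejected(self, pulse_setup):
        pep, model, state, cond, _ = pulse_setup
        stable = ConformationalState("stable", state.log10_pf)
        with pytest.raises(ValueError, match="unfolding"):
            simulate_pulse_label(pep, model, stable, [0.0], 10.0, cond)
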