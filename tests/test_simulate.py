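"""Synthetic EX2/EX1 dataset generator: kinetics, noise, determinism."""

import math

import numpy as np
import pytest

from hdxdiff.corrections import LabellingCondition, ph_correction_factor
from hdxdiff.io import PeptideRecord
from hdxdiff.simulate import (
    ConformationalState,
    ExperimentDesign,
    ResidueExchangeModel,
    Unfolding,
    ex2_uptake,
    generate_peptide_map,
    random_exchange_model,
    random_protein_sequence,
    simulate_dataset,
    simulate_two_state,
    uniform_state,
)


def brute_force_coverage(peptides, length):
    covered = [False] * (length + 1)
    for pep in peptides:
        for i in range(pep.start, pep.end + 1):
            covered[i] = True
    return sum(covered[1:]) / length


class TestPeptideMap:
    def test_degenerate_full_length(self):
        seq = random_protein_sequence(20, 0)
        peps = generate_peptide_map(seq, mean_length=20, overlap=5, coverage_target=1.0, seed=1)
        assert len(peps) == 1
        assert (peps[0].start, peps[0].end) == (1, 20)

    def test_coverage_meets_target(self):
        seq = random_protein_sequence(100, 3)
        peps = generate_peptide_map(seq, mean_length=12, overlap=5, coverage_target=0.9, seed=3)
        assert brute_force_coverage(peps, 100) >= 0.9
        for pep in peps:
            assert 1 <= pep.start <= pep.end <= 100
            assert seq[pep.start - 1 : pep.end] == pep.sequence

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            generate_peptide_map("", mean_length=10)

    def test_deterministic_for_seed(self):
        seq = random_protein_sequence(100, 5)
        a = generate_peptide_map(seq, seed=11)
        b = generate_peptide_map(seq, seed=11)
        assert [(p.start, p.end) for p in a] == [(p.start, p.end) for p in b]


class TestModelInvariants:
    def test_proline_and_first_residue_rates_zero(self):
        with pytest.raises(ValueError, match="rate 0"):
            ResidueExchangeModel("MAP", np.array([0.0, 1.0, 1.0]), 7.4)
        model = random_exchange_model("MAPAG", 1)
        assert model.k_int_ref[0] == 0.0 and model.k_int_ref[2] == 0.0

    def test_base_catalysed_scaling(self):
        model = random_exchange_model("MAGAG", 1, reference_pH=7.4)
        np.testing.assert_allclose(model.rates_at(8.4), 10 * model.k_int_ref)

    def test_negative_pf_rejected(self):
        with pytest.raises(ValueError):
            uniform_state("bad", 5, -0.1)


class TestEX2:
    def test_zero_time_gives_zero(self, model, sequence, flat_state):
        pep = PeptideRecord("x", sequence[:12], 1, 12)
        assert ex2_uptake(pep, model, flat_state, 0.0, 0.89) == 0.0

    def test_saturation_limit(self):
        seq = "M" + "A" * 10  # 10 exchangeable amides beyond the N-terminus
        model = ResidueExchangeModel(seq, np.array([0.0] + [1.0] * 10), 7.4)
        state = uniform_state("s", 11, 0.0)
        pep = PeptideRecord("x", seq, 1, 11)
        assert ex2_uptake(pep, model, state, 1e9, 0.89) == pytest.approx(8.9)

    def test_single_residue_closed_form(self):
        seq = "MA"
        model = ResidueExchangeModel(seq, np.array([0.0, 0.1]), 7.4)
        state = uniform_state("s", 2, 1.0)  # PF = 10
        pep = PeptideRecord("x", seq, 1, 2)
        got = ex2_uptake(pep, model, state, 100.0, 1.0)
        assert got == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_multi_residue_sum_of_exponentials(self, sequence, model, flat_state):
        # oracle: sum independently computed single-site exponentials
        pep = PeptideRecord("x", sequence[9:21], 10, 21)
        t, d = 37.0, 0.78
        expected = d * sum(
            1 - math.exp(-model.k_int_ref[i] / 10 ** flat_state.log10_pf[i] * t)
            for i in range(10, 21)  # 0-based: residues start+1..end
        )
        assert ex2_uptake(pep, model, flat_state, t, d) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_time_and_protection(self, sequence, model):
        pep = PeptideRecord("x", sequence[:15], 1, 15)
        times = np.logspace(-1, 5, 12)
        for lo, hi in [(0.0, 0.0), (1.0, 2.0)]:
            uptakes = [
                ex2_uptake(pep, model, uniform_state("s", len(sequence), hi), t, 0.89)
                for t in times
            ]
            assert all(b >= a - 1e-12 for a, b in zip(uptakes, uptakes[1:]))
        weak = [ex2_uptake(pep, model, uniform_state("s", len(sequence), 1.0), t, 0.89) for t in times]
        strong = [ex2_uptake(pep, model, uniform_state("s", len(sequence), 2.0), t, 0.89) for t in times]
        assert all(w >= s - 1e-12 for w, s in zip(weak, strong))

    def test_negative_time_rejected(self, sequence, model, flat_state):
        pep = PeptideRecord("x", sequence[:10], 1, 10)
        with pytest.raises(ValueError):
            ex2_uptake(pep, model, flat_state, -1.0, 0.89)

    def test_cross_ph_time_equivalence(self, sequence, model, flat_state):
        # labelling for t at pH 5.38 equals labelling for t/factor at pH 7.36
        pep = PeptideRecord("x", sequence[19:31], 20, 31)
        factor = ph_correction_factor(7.36, 5.38).factor
        t = 240.0
        low = ex2_uptake(pep, model, flat_state, t * factor, 0.78, pH=5.38)
        high = ex2_uptake(pep, model, flat_state, t, 0.78, pH=7.36)
        assert low == pytest.approx(high, rel=1e-9)


class TestDataset:
    def test_noiseless_matches_expected_uptake(self, sequence, model, peptides, condition, flat_state):
        design = ExperimentDesign(
            states=("a",),
            conditions={"a": condition},
            timepoints=(60.0, 600.0),
            noise_sd=0.0,
            seed=1,
        )
        uptake, controls = simulate_dataset(design, model, peptides, {"a": flat_state})
        for row in uptake.itertuples(index=False):
            pep = next(p for p in peptides if (p.start, p.end) == (row.start, row.end))
            expected = ex2_uptake(pep, model, flat_state, row.exposure_s, condition.d_frac,
                                  pH=condition.pH_read)
            assert row.uptake_Da == pytest.approx(expected, rel=1e-12)
        for row in controls.itertuples(index=False):
            pep = next(p for p in peptides if (p.start, p.end) == (row.start, row.end))
            assert row.uptake_Da == pytest.approx(condition.d_frac * pep.n_exchangeable)

    def test_back_exchange_scales_controls(self, model, condition):
        seq = "M" + "A" * 10
        pep = PeptideRecord("x", seq, 1, 11)  # N = 10
        cond = LabellingCondition(7.4, 1.0)
        design = ExperimentDesign(
            states=("a",), conditions={"a": cond}, timepoints=(60.0,),
            noise_sd=0.0, back_exchange_frac=0.3, seed=1,
        )
        m = ResidueExchangeModel(seq, np.array([0.0] + [1.0] * 10), 7.4)
        _, controls = simulate_dataset(design, m, [pep], {"a": uniform_state("a", 11, 0.0)})
        assert controls["uptake_Da"].iloc[0] == pytest.approx(7.0)

    def test_seeded_determinism(self, sequence, model, peptides, small_design, flat_state):
        states = {"a": flat_state, "b": flat_state}
        u1, c1 = simulate_dataset(small_design, model, peptides, states)
        u2, c2 = simulate_dataset(small_design, model, peptides, states)
        assert u1.equals(u2) and c1.equals(c2)

    def test_replicate_schedule_respected(self, sequence, model, peptides, small_design, flat_state):
        uptake, _ = simulate_dataset(small_design, model, peptides, {"a": flat_state, "b": flat_state})
        counts = uptake.groupby(["state", "start", "end", "exposure_s"]).size()
        for (_, _, _, t), n in counts.items():
            assert n == (3 if t in (60.0, 600.0) else 1)

    def test_saturation_bound_with_noise(self, sequence, model, peptides, small_design, flat_state):
        uptake, _ = simulate_dataset(small_design, model, peptides, {"a": flat_state, "b": flat_state})
        n_ex = {(p.start, p.end): p.n_exchangeable for p in peptides}
        bound = uptake.apply(
            lambda r: 0.78 * n_ex[(r.start, r.end)] + 5 * small_design.noise_sd, axis=1
        )
        assert (uptake["uptake_Da"] <= bound).all()


class TestTwoState:
    def test_no_preincubation(self):
        state = ConformationalState("s", np.zeros(5), Unfolding(0.1, np.zeros(5)))
        assert simulate_two_state(state, 0.0) == (1.0, 0.0)

    def test_half_life_identity(self):
        k = math.log(2) / 60.0
        state = ConformationalState("s", np.zeros(5), Unfolding(k, np.zeros(5)))
        w_f, w_o = simulate_two_state(state, 60.0)
        assert w_o == pytest.approx(0.5)
        assert w_f + w_o == pytest.approx(1.0)

    def test_stable_protein_never_opens(self):
        state = ConformationalState("s", np.zeros(5), Unfolding(0.0, np.zeros(5)))
        for t in (0.0, 1e3, 1e9):
            assert simulate_two_state(state, t) == (1.0, 0.0)

    def test_missing_unfolding_rejected(self):
        with pytest.raises(ValueError, match="unfolding"):
            simulate_two_state(ConformationalState("s", np.zeros(5)), 10.0)
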