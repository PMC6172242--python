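"""Folding engine versus the exhaustive enumeration oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from accessprobe import thermo
from accessprobe.thermo import (
    EnergyModel,
    IntervalError,
    NucleotideSequence,
    SequenceError,
    enumerate_structures,
    opening_energy,
    pair_probabilities,
    probe_folding_energy,
    unpaired_profile,
)

rna = st.text(alphabet="ACGU", min_size=4, max_size=12)


def test_sequence_normalization():
    s = NucleotideSequence("acgt")
    assert s.residues == "ACGU"
    with pytest.raises(SequenceError):
        NucleotideSequence("ACGX")
    with pytest.raises(SequenceError):
        NucleotideSequence("")


def test_model_validation():
    with pytest.raises(ValueError):
        EnergyModel(min_hairpin_loop=2)
    with pytest.raises(ValueError):
        EnergyModel(pair_energy={("G", "C"): 1.0})
    with pytest.raises(ValueError):
        EnergyModel(RT=0.0)


@pytest.mark.parametrize("seq", ["AAAAAAA", "ACGU"])
def test_unpairable_sequences_have_trivial_ensemble(seq):
    ens = pair_probabilities(seq)
    assert ens.Z == pytest.approx(1.0)
    assert ens.ensemble_dG == pytest.approx(0.0)
    assert np.allclose(ens.unpaired_prob, 1.0)
    assert not ens.pair_prob.any()


def test_ensemble_matches_enumeration_oracle():
    for seq in ["GGGAAACCC", "GCGCAAAGCGC", "GGAAACC", "GAAAC", "AUGGCAAAGCC"]:
        ens = pair_probabilities(seq)
        _, Z, P, up, _ = enumerate_structures(seq)
        assert ens.Z == pytest.approx(Z, rel=1e-9)
        assert np.allclose(ens.pair_prob, P, rtol=1e-9, atol=1e-12)
        assert np.allclose(ens.unpaired_prob, up, rtol=1e-9, atol=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seq=rna)
def test_ensemble_oracle_property(seq):
    ens = pair_probabilities(seq)
    _, Z, P, up, mfe = enumerate_structures(seq)
    assert ens.Z == pytest.approx(Z, rel=1e-9)
    assert np.allclose(ens.pair_prob, P, rtol=1e-9, atol=1e-12)
    # invariants
    assert ens.Z >= 1.0
    assert ens.ensemble_dG <= 1e-12
    assert np.all(ens.unpaired_prob >= -1e-12) and np.all(ens.unpaired_prob <= 1 + 1e-12)
    assert np.allclose(ens.pair_prob, ens.pair_prob.T)


def test_unpaired_profile_restriction():
    ens = pair_probabilities("AAAAAA")
    assert np.allclose(unpaired_profile(ens, 2, 4), [1, 1, 1])
    assert np.allclose(unpaired_profile(ens, 1, 6), ens.unpaired_prob)
    with pytest.raises(IntervalError):
        unpaired_profile(ens, 0, 3)
    with pytest.raises(IntervalError):
        unpaired_profile(ens, 5, 7)


def test_unpaired_profile_matches_oracle():
    ens = pair_probabilities("GGGAAACCC")
    _, _, _, up, _ = enumerate_structures("GGGAAACCC")
    assert np.allclose(unpaired_profile(ens, 4, 6), up[3:6], rtol=1e-9)


class TestDuplexEnergy:
    def test_forced_values(self, model):
        assert thermo.duplex_energy("CCC", "GGG", model) == pytest.approx(-9.0)
        assert thermo.duplex_energy("UUU", "AAA", model) == pytest.approx(-6.0)

    def test_mixed_region_equals_per_pair_sum(self, model):
        region = "GAUCGAUCGGAUCCAU"
        probe = thermo.reverse_complement(region)
        expected = sum(model.energy(b, thermo._COMPLEMENT[b]) for b in region)
        assert thermo.duplex_energy(probe, region, model) == pytest.approx(expected)

    def test_non_complementary_rejected(self, model):
        with pytest.raises(SequenceError):
            thermo.duplex_energy("AAA", "AAA", model)

    def test_strictly_decreases_with_added_pairs(self, model):
        region = "GAUCGAUC"
        energies = [
            thermo.duplex_energy(thermo.reverse_complement(region[:k]), region[:k], model)
            for k in range(1, len(region) + 1)
        ]
        assert all(b < a for a, b in zip(energies, energies[1:]))


class TestOpeningEnergy:
    def test_unstructured_is_free(self):
        assert opening_energy("AAAAAAAAA", 2, 5) == pytest.approx(0.0)

    def test_matches_constrained_oracle(self, model):
        seq = "GGGAAACCC"
        structures, Z, _, _, _ = enumerate_structures(seq, model)
        for (a, b) in [(7, 9), (1, 3), (4, 6), (2, 8)]:
            blocked = set(range(a, b + 1))
            Zc = sum(
                math.exp(-e / model.RT)
                for pairs, e in structures
                if not any(i in blocked or j in blocked for i, j in pairs)
            )
            expected = -model.RT * math.log(Zc / Z)
            assert opening_energy(seq, a, b, model) == pytest.approx(expected, abs=1e-9)
        assert opening_energy(seq, 7, 9, model) > 0

    def test_unreachable_interval_costs_nothing(self):
        # Gs at the 5' end cannot reach anything pairable
        assert opening_energy("AAAAAAAGGG", 1, 4) == pytest.approx(0.0)

    def test_monotone_in_interval_growth(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=14))
        costs = [opening_energy(seq, 5, end) for end in range(5, 12)]
        assert all(b >= a - 1e-12 for a, b in zip(costs, costs[1:]))


class TestProbeFolding:
    def test_unpairable_probe(self):
        assert probe_folding_energy("UUUUUUUUUUUU") == pytest.approx(0.0)

    def test_mfe_matches_enumeration(self):
        for probe in ["GGGGAAAACCCC", "GCAUGCAAAGCAUGC"]:
            _, _, _, _, mfe = enumerate_structures(probe)
            assert probe_folding_energy(probe) == pytest.approx(mfe)

    def test_single_gc_hairpin(self):
        # exactly one pair possible: the terminal G:C around an AAA loop
        assert probe_folding_energy("AAAAGAAACAAA") == pytest.approx(-3.0)

    def test_off_design_length_warns(self):
        with pytest.warns(UserWarning):
            probe_folding_energy("GAAAC")


class TestEnumerationOracle:
    def test_structure_counts(self):
        assert len(enumerate_structures("AAAA")[0]) == 1
        assert len(enumerate_structures("GAAAC")[0]) == 2

    def test_count_matches_independent_recursion(self, model):
        # independent count of nested pairings via a plain interval recursion
        def count(s, i, j):
            if j - i + 1 <= model.min_hairpin_loop:
                return 1
            total = count(s, i, j - 1)
            for k in range(i, j - model.min_hairpin_loop):
                if model.energy(s[k], s[j]) is not None:
                    left = count(s, i, k - 1) if k > i else 1
                    total += left * count(s, k + 1, j - 1)
            return total

        for seq in ["GGAAACC", "GCGCAAAGCGC", "GGGAAACCC"]:
            assert len(enumerate_structures(seq)[0]) == count(seq, 0, len(seq) - 1)

    def test_refuses_large_input(self):
        with pytest.raises(ValueError):
            enumerate_structures("A" * 19)


def test_large_sequence_scaled_recursion_consistent():
    # n > 200 triggers the rescaled recursion; spot-check against the
    # unscaled path on a sequence whose prefix dominates the folding.
    seq = "GGGAAACCC" + "A" * 200
    ens = thermo.pair_probabilities(seq)
    small = thermo.pair_probabilities("GGGAAACCC")
    assert ens.ensemble_dG == pytest.approx(small.ensemble_dG, rel=1e-6)
    assert np.allclose(ens.pair_prob[:9, :9], small.pair_prob, atol=1e-6)


def test_backend_registry():
    assert thermo.get_backend("builtin") is thermo.pair_probabilities
    with pytest.raises(KeyError):
        thermo.get_backend("nope")
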