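"""Library mutagenesis, selection dynamics, and read simulation."""

import numpy as np
import pytest
from scipy import stats as sps

from ubisel.core_model import Clone, NucSubstitution, ValidationError
from ubisel.synthetic_data import (
    EffectTable,
    MutagenesisParams,
    Population,
    ReadSimParams,
    SelectionParams,
    advance_round,
    binding_activity,
    default_effect_table,
    default_spectrum,
    mutagenize,
    population_aa_frequencies,
    sample_count_matrix,
    simulate_reads,
    simulate_selection,
    ura3_activity,
    write_fastq,
)


def _sub_at(ref, residue, codon_pos, alt):
    nt = 3 * (residue - ref.first_residue) + codon_pos
    return NucSubstitution(nt, ref.nt_sequence[nt - 1], alt)


class TestMutagenesis:
    def test_zero_rate_yields_wild_type_library(self, ref):
        pop = mutagenize(ref, MutagenesisParams(per_base_rate=0.0, seed=1), 50)
        assert all(len(c.substitutions) == 0 for c in pop.clones.values())
        assert all(n == 1 for n in pop.abundances.values())

    def test_default_rate_is_five_per_kb(self, ref):
        pop = mutagenize(ref, MutagenesisParams(seed=11), 1000)
        mean = np.mean([len(c.substitutions) for c in pop.clones.values()])
        assert mean / ref.length * 1000 == pytest.approx(5.0, rel=0.1)

    def test_transition_only_spectrum_emits_no_transversions(self, ref):
        pop = mutagenize(ref, MutagenesisParams(spectrum=default_spectrum(1.0), seed=3), 200)
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for clone in pop.clones.values():
            for s in clone.substitutions:
                assert (s.ref_base, s.alt_base) in transitions

    def test_substitution_counts_match_binomial(self, ref):
        pop = mutagenize(ref, MutagenesisParams(seed=5), 10_000)
        counts = np.array([len(c.substitutions) for c in pop.clones.values()])
        # KS against the binomial CDF (discrete, so compare via sampled reference)
        reference = sps.binom.rvs(
            ref.length, 0.005, size=10_000, random_state=np.random.RandomState(0)
        )
        assert sps.ks_2samp(counts, reference).pvalue > 0.01

    def test_spectrum_rows_validated(self):
        bad = np.ones((4, 4)) / 3
        with pytest.raises(ValidationError):
            MutagenesisParams(spectrum=bad)


class TestActivities:
    def test_wild_type_binds_fully(self, ref):
        effects = default_effect_table()
        assert binding_activity(Clone("wt"), effects, ref) == 1.0

    def test_single_effect(self, ref):
        effects = EffectTable(position_effects={833: 0.9})
        clone = Clone("m", (_sub_at(ref, 833, 2, "G"),))
        assert binding_activity(clone, effects, ref) == pytest.approx(0.1)

    def test_two_effects_multiply(self, ref):
        effects = EffectTable(position_effects={833: 0.5, 818: 0.5})
        clone = Clone("mm", (_sub_at(ref, 833, 2, "G"), _sub_at(ref, 818, 1, "C")))
        assert binding_activity(clone, effects, ref) == pytest.approx(0.25)

    def test_substitution_override_beats_position_effect(self, ref):
        effects = EffectTable(
            position_effects={833: 0.9}, substitution_overrides={(833, "G"): 0.2}
        )
        clone = Clone("m", (_sub_at(ref, 833, 2, "G"),))
        assert binding_activity(clone, effects, ref) == pytest.approx(0.8)

    def test_ura3_is_complement_of_binding(self, ref):
        params = SelectionParams()
        effects = EffectTable(position_effects={833: 1.0})
        broken = Clone("b", (_sub_at(ref, 833, 2, "G"),))
        assert ura3_activity(Clone("wt"), effects, params, ref) == 0.0
        assert ura3_activity(broken, effects, params, ref) == 1.0

    def test_nonsense_clone_gets_truncation_activity(self, ref):
        nonsense = Clone("stop", (_sub_at(ref, 818, 3, "A"),))  # TAT -> TAA
        assert ura3_activity(nonsense, EffectTable(), SelectionParams(), ref) == 0.2

    def test_rearranged_clone_gets_full_activity(self, ref):
        assert ura3_activity(None, EffectTable(), SelectionParams(), ref) == 1.0


class TestSelectionRounds:
    def test_bottleneck_conserves_total(self, ref):
        pop = mutagenize(ref, MutagenesisParams(seed=2), 500)
        nxt = advance_round(pop, default_effect_table(), SelectionParams(seed=9), ref)
        assert nxt.total == SelectionParams().bottleneck_size
        assert nxt.round_index == 1

    def test_strong_selection_matches_closed_form(self, ref):
        # two clones, equal counts, u=1 vs u=0, G=10: expected winner
        # frequency is 2^10/(2^10+1) ~ 0.999
        broken = Clone("b", (_sub_at(ref, 833, 2, "G"),))
        pop = Population(0, {"b": broken, "wt": Clone("wt")}, {"b": 1000, "wt": 1000})
        effects = EffectTable(position_effects={833: 1.0})
        params = SelectionParams(seed=4, rearrangement_rate=0.0, bottleneck_size=200_000)
        freqs = [
            advance_round(pop, effects, params, ref).frequency_of("b")
            for params in [SelectionParams(seed=s, rearrangement_rate=0.0) for s in range(5)]
        ]
        assert np.mean(freqs) == pytest.approx(2**10 / (2**10 + 1), abs=5e-3)

    def test_bottleneck_of_one_leaves_single_clone(self, ref):
        pop = mutagenize(ref, MutagenesisParams(seed=2), 100)
        nxt = advance_round(
            pop, EffectTable(), SelectionParams(seed=3, bottleneck_size=1, rearrangement_rate=0.0), ref
        )
        assert nxt.total == 1 and len(nxt.clones) == 1

    def test_neutral_round_preserves_expected_frequencies(self, ref):
        pop = mutagenize(ref, MutagenesisParams(seed=6), 200)
        params = SelectionParams(
            rearrangement_rate=0.0, truncation_activity=0.0, bottleneck_size=500_000
        )
        nxt = advance_round(pop, EffectTable(), params, ref)
        before = np.array([pop.abundances[c] / pop.total for c in sorted(pop.abundances)])
        after = np.array(
            [nxt.abundances.get(c, 0) / nxt.total for c in sorted(pop.abundances)]
        )
        assert np.abs(before - after).max() < 0.002

    def test_zero_rounds_returns_library_only(self, ref):
        pops = simulate_selection(
            ref, MutagenesisParams(seed=1), EffectTable(), SelectionParams(n_rounds=0), 50
        )
        assert len(pops) == 1 and pops[0].round_index == 0

    def test_planted_carrier_frequency_increases_monotonically(self, ref):
        effects = default_effect_table()
        pops = simulate_selection(
            ref, MutagenesisParams(seed=1), effects, SelectionParams(seed=2), 5000
        )
        planted = set(effects.position_effects)

        def carrier_freq(pop):
            hit = 0
            for cid, clone in pop.clones.items():
                if clone is not None and any(
                    m.residue in planted for m in clone.aa_mutations(ref)
                ):
                    hit += pop.abundances[cid]
            return hit / pop.total

        freqs = [carrier_freq(p) for p in pops]
        # strictly increasing until the carriers saturate the population
        for a, b in zip(freqs, freqs[1:], strict=False):
            if a < 0.99:
                assert b > a
        assert freqs[-1] > 0.99

    def test_nonsense_outcompeted_by_clean_breakers(self, ref):
        # truncation activity 0.2 < planted 0.95: stop-carrying clones lose
        broken = Clone("b", (_sub_at(ref, 833, 2, "G"),))
        nonsense = Clone("s", (_sub_at(ref, 818, 3, "A"),))
        pop = Population(0, {"b": broken, "s": nonsense}, {"b": 100, "s": 100})
        effects = EffectTable(position_effects={833: 0.95})
        cur = pop
        for _ in range(3):
            cur = advance_round(cur, effects, SelectionParams(seed=8, rearrangement_rate=0.0), ref)
        assert cur.abundances.get("b", 0) > 100 * cur.abundances.get("s", 0)

    def test_rearranged_lineages_appear_late(self, ref):
        pops = simulate_selection(
            ref,
            MutagenesisParams(seed=3),
            default_effect_table(),
            SelectionParams(seed=4, rearrangement_rate=0.01),
            2000,
        )
        assert all(c is not None for c in pops[0].clones.values())
        rearranged_final = [c for c in pops[-1].clones.values() if c is None]
        assert len(rearranged_final) > 0


class TestReadSimulation:
    def test_error_free_wild_type_reads_are_exact_substrings(self, ref):
        pop = Population(0, {"wt": Clone("wt")}, {"wt": 10})
        params = ReadSimParams(n_reads_per_round=200, error_rate=0.0, seed=1)
        from Bio.Seq import reverse_complement

        for _, seq, qual in simulate_reads(pop, ref, params):
            assert seq in ref.nt_sequence or reverse_complement(seq) in ref.nt_sequence
            assert qual == chr(30 + 33) * params.read_length

    def test_forward_only_when_strand_prob_zero(self, ref):
        pop = Population(0, {"wt": Clone("wt")}, {"wt": 10})
        params = ReadSimParams(n_reads_per_round=100, error_rate=0.0, strand_prob=0.0, seed=2)
        for _, seq, _ in simulate_reads(pop, ref, params):
            assert seq in ref.nt_sequence

    def test_read_names_carry_no_genotype(self, ref):
        pop = mutagenize(ref, MutagenesisParams(seed=9), 20)
        names = [n for n, _, _ in simulate_reads(pop, ref, ReadSimParams(n_reads_per_round=50, seed=3))]
        assert names == [f"r0_{i}" for i in range(50)]

    def test_rearranged_clones_not_sequenced(self, ref):
        pop = Population(
            0, {"wt": Clone("wt"), "rearr": None}, {"wt": 1, "rearr": 1_000_000}
        )
        params = ReadSimParams(n_reads_per_round=50, error_rate=0.0, seed=4)
        from Bio.Seq import reverse_complement

        for _, seq, _ in simulate_reads(pop, ref, params):
            assert seq in ref.nt_sequence or reverse_complement(seq) in ref.nt_sequence

    def test_read_longer_than_insert_rejected(self, ref):
        pop = Population(0, {"wt": Clone("wt")}, {"wt": 1})
        with pytest.raises(ValidationError):
            next(simulate_reads(pop, ref, ReadSimParams(read_length=ref.length + 3)))

    def test_fastq_round_trip(self, ref, tmp_path):
        pop = Population(0, {"wt": Clone("wt")}, {"wt": 5})
        records = list(simulate_reads(pop, ref, ReadSimParams(n_reads_per_round=20, seed=5)))
        path = tmp_path / "r0.fastq"
        assert write_fastq(records, path) == 20
        from Bio.SeqIO.QualityIO import FastqGeneralIterator

        with open(path) as fh:
            back = [(n, s, q) for n, s, q in FastqGeneralIterator(fh)]
        assert back == records


class TestCountChannel:
    def test_population_frequencies_sum_to_one(self, ref):
        pop = mutagenize(ref, MutagenesisParams(seed=7), 300)
        freqs = population_aa_frequencies(pop, ref)
        assert freqs.shape == (427, 21)
        assert np.allclose(freqs.sum(axis=1), 1.0)

    def test_wild_type_population_is_pure(self, ref):
        pop = Population(0, {"wt": Clone("wt")}, {"wt": 3})
        freqs = population_aa_frequencies(pop, ref)
        assert np.allclose(freqs.max(axis=1), 1.0)

    def test_sampled_counts_have_requested_depth(self, ref):
        pops = simulate_selection(
            ref, MutagenesisParams(seed=1), EffectTable(), SelectionParams(n_rounds=2), 200
        )
        cm = sample_count_matrix(pops, ref, depth=500, seed=1)
        assert cm.counts.shape == (3, 427, 21)
        assert (cm.depth == 500).all()
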