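"""Alignment, codon calling, and count tabulation, checked against a naive oracle."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from ubisel.core_model import AA_ALPHABET, AA_INDEX, translate_codon
from ubisel.variant_counts import (
    CountMatrix,
    EmptyRoundError,
    align_read,
    codon_calls,
    tabulate,
)

# ---------------------------------------------------------------------------
# Independent naive oracle: per-offset scan with Python string comparison,
# then a per-read, per-codon double loop.  Shares no code with the library.
# ---------------------------------------------------------------------------


def naive_align(seq, ref, max_mismatch_frac=0.1):
    best = None  # (mismatches, strand_order, offset, oriented_seq)
    for strand_order, oriented in ((0, seq.upper()), (1, reverse_complement(seq.upper()))):
        for offset in range(ref.length - len(seq) + 1):
            window = ref.nt_sequence[offset : offset + len(seq)]
            mism = sum(a != b for a, b in zip(window, oriented, strict=True))
            cand = (mism, strand_order, offset, oriented)
            if best is None or cand < best:
                best = cand
    if best[0] > max_mismatch_frac * len(seq):
        return None
    return best  # mismatches, strand(0=+), offset, forward-oriented sequence


def naive_tabulate(reads_by_round, ref, max_mismatch_frac=0.1, min_quality=20):
    rounds = sorted(reads_by_round)
    counts = np.zeros((len(rounds), ref.n_codons, len(AA_ALPHABET)), dtype=np.int64)
    for r, rnd in enumerate(rounds):
        for _, seq, qual in reads_by_round[rnd]:
            hit = naive_align(seq, ref, max_mismatch_frac)
            if hit is None:
                continue
            _, strand, offset, oriented = hit
            quals = [ord(c) - 33 for c in qual]
            if strand == 1:
                quals = quals[::-1]
            for codon_idx in range(ref.n_codons):
                start = 3 * codon_idx
                if start < offset or start + 3 > offset + len(seq):
                    continue
                triple = oriented[start - offset : start - offset + 3]
                q3 = quals[start - offset : start - offset + 3]
                if any(q < min_quality for q in q3) or any(b not in "ACGT" for b in triple):
                    continue
                counts[r, codon_idx, AA_INDEX[translate_codon(triple)]] += 1
    return counts


def _random_reads(ref, rng, n=20, read_len=60, planted=True, junk_frac=0.2):
    """Reads sampled from the reference with planted codon changes and junk."""
    reads = []
    for i in range(n):
        if rng.random() < junk_frac:
            seq = "".join(rng.choice(list("ACGT"), size=read_len))
        else:
            start = int(rng.integers(0, ref.length - read_len + 1))
            seq = list(ref.nt_sequence[start : start + read_len])
            for _ in range(int(rng.integers(0, 4))):  # a few substitutions
                j = int(rng.integers(0, read_len))
                seq[j] = "ACGT"[(("ACGT".index(seq[j])) + 1 + int(rng.integers(0, 3))) % 4]
            seq = "".join(seq)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
        qual = "".join(chr(int(q) + 33) for q in rng.integers(15, 40, size=read_len))
        reads.append((f"read{i}", seq, qual))
    return reads


class TestAlignRead:
    def test_exact_substring_found_at_offset(self, ref):
        ar = align_read(ref.nt_sequence[30:180], ref)
        assert (ar.offset, ar.strand, ar.n_mismatches) == (30, "+", 0)

    def test_reverse_complement_recognized(self, ref):
        ar = align_read(reverse_complement(ref.nt_sequence[60:210]), ref)
        assert (ar.offset, ar.strand, ar.n_mismatches) == (60, "-", 0)
        assert ar.aligned_sequence == ref.nt_sequence[60:210]

    def test_random_sequence_rejected(self, ref, rng):
        junk = "".join(rng.choice(list("ACGT"), size=150))
        assert align_read(junk, ref) is None

    def test_mismatch_budget_respected(self, ref):
        seq = list(ref.nt_sequence[100:200])
        for j in range(0, 30, 3):  # 10 mismatches in a 100-mer: exactly at the 0.1 limit
            seq[j] = "ACGT"[("ACGT".index(seq[j]) + 1) % 4]
        ar = align_read("".join(seq), ref)
        assert ar is not None and ar.n_mismatches == 10
        seq[40] = "ACGT"[("ACGT".index(seq[40]) + 1) % 4]  # 11th pushes over
        assert align_read("".join(seq), ref) is None

    def test_agrees_with_naive_oracle(self, small_ref, rng):
        for _ in range(50):
            _, seq, _ = _random_reads(small_ref, rng, n=1, read_len=33)[0]
            ours = align_read(seq, small_ref)
            naive = naive_align(seq, small_ref)
            if naive is None:
                assert ours is None
            else:
                assert (ours.n_mismatches, ours.offset) == (naive[0], naive[2])


class TestCodonCalls:
    def test_full_coverage_counts_all_codons(self, ref):
        # read covering codons 2-50 completely: offset 3, length 147
        ar = align_read(ref.nt_sequence[3:150], ref)
        calls = codon_calls(ar, ref)
        assert len(calls) == 49
        assert calls[0][0] == ref.first_residue + 1

    def test_partial_codons_at_ends_dropped(self, ref):
        ar = align_read(ref.nt_sequence[4:150], ref)  # starts mid-codon
        calls = codon_calls(ar, ref)
        assert calls[0][0] == ref.first_residue + 2

    def test_low_quality_base_vetoes_codon(self, ref):
        ar = align_read(ref.nt_sequence[3:150], ref)
        ar.qualities = ar.qualities.copy()
        ar.qualities[1] = 10  # second base of the first covered codon
        calls = codon_calls(ar, ref, min_quality=20)
        assert calls[0][0] == ref.first_residue + 2  # first codon vetoed

    def test_wild_type_read_calls_wild_type(self, ref):
        ar = align_read(ref.nt_sequence[0:90], ref)
        translation = ref.translate()
        for residue, aa in codon_calls(ar, ref):
            assert aa == translation[residue - ref.first_residue]


class TestTabulate:
    def test_wild_type_reads_give_pure_depth(self, ref):
        reads = [("r%d" % i, ref.nt_sequence[0:150], "I" * 150) for i in range(100)]
        cm, stats = tabulate({0: reads}, ref)
        assert stats["rounds"][0] == {"reads": 100, "accepted": 100, "rejected": 0}
        wt = cm.wildtype_counts(ref)[0]
        assert (wt[:50] == 100).all() and (cm.depth[0, :50] == 100).all()
        assert cm.depth[0, 50:].sum() == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_naive_oracle_exactly(self, small_ref, seed):
        rng = np.random.default_rng(seed)
        reads = {0: _random_reads(small_ref, rng, n=40, read_len=33)}
        cm, _ = tabulate(reads, small_ref)
        assert (cm.counts == naive_tabulate(reads, small_ref)).all()

    def test_read_order_permutation_invariant(self, small_ref, rng):
        reads = _random_reads(small_ref, rng, n=30, read_len=30)
        cm1, _ = tabulate({0: reads}, small_ref)
        cm2, _ = tabulate({0: reads[::-1]}, small_ref)
        assert (cm1.counts == cm2.counts).all()

    def test_depth_bounded_by_accepted_reads(self, small_ref, rng):
        reads = _random_reads(small_ref, rng, n=50, read_len=30)
        cm, stats = tabulate({0: reads}, small_ref)
        assert cm.depth.max() <= stats["rounds"][0]["accepted"]

    def test_all_rejected_round_raises(self, ref, rng):
        junk = [("j%d" % i, "".join(rng.choice(list("ACGT"), 150)), "I" * 150) for i in range(5)]
        with pytest.raises(EmptyRoundError):
            tabulate({0: junk}, ref)

    def test_reads_from_fastq_file(self, ref, tmp_path):
        from ubisel.synthetic_data import write_fastq

        reads = [("r%d" % i, ref.nt_sequence[9:159], "I" * 150) for i in range(10)]
        path = tmp_path / "round_0.fastq"
        write_fastq(reads, path)
        cm_file, _ = tabulate({0: path}, ref)
        cm_mem, _ = tabulate({0: reads}, ref)
        assert (cm_file.counts == cm_mem.counts).all()

    def test_strand_does_not_bias_counts(self, ref):
        from ubisel.core_model import Clone
        from ubisel.synthetic_data import Population, ReadSimParams, simulate_reads

        pop = Population(0, {"wt": Clone("wt")}, {"wt": 5})
        cms = []
        for strand_prob in (0.0, 1.0):
            params = ReadSimParams(
                n_reads_per_round=2000, error_rate=0.0, strand_prob=strand_prob, seed=6
            )
            cm, _ = tabulate({0: list(simulate_reads(pop, ref, params))}, ref)
            cms.append(cm)
        # identical sampling seed, mirrored strands: same per-site coverage profile
        d0, d1 = cms[0].depth[0], cms[1].depth[0]
        assert abs(int(d0.sum()) - int(d1.sum())) < 0.01 * d0.sum()
        assert (cms[0].wildtype_counts(ref)[0] == cms[0].depth[0]).all()
        assert (cms[1].wildtype_counts(ref)[0] == cms[1].depth[0]).all()

    def test_count_matrix_tsv_round_trip(self, small_ref, rng, tmp_path):
        reads = _random_reads(small_ref, rng, n=30, read_len=30)
        cm, _ = tabulate({0: reads, 1: reads}, small_ref)
        cm.to_tsv(tmp_path / "counts.tsv")
        back = CountMatrix.from_tsv(tmp_path / "counts.tsv", cm.sites)
        assert back.rounds == cm.rounds
        assert (back.counts == cm.counts).all()
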