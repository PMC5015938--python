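"""Ungapped amplicon alignment and codon-level variant counting.

Reads are placed on the insert by a brute-force scan over every offset on
both strands (the amplicon is short, so exhaustive ungapped placement is
cheap and has no mapping heuristics to tune); a read is accepted when its
best placement has at most ``max_mismatch_frac`` mismatches per base.  A
codon is called only when all three of its bases lie inside the read, are
unambiguous, and meet the quality threshold; calls are tallied into a
rounds x sites x 21 count matrix (20 amino acids + stop).

The scan is vectorized: batches of equal-length reads are one-hot encoded
and matched against all reference windows with a single matrix product,
which is exactly the per-offset Hamming distance computed in bulk.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core_model import (
    AA_ALPHABET,
    AA_INDEX,
    CODON_CODE_TO_AA,
    ReferenceInsert,
    ValidationError,
    encode_sequence,
)

__all__ = [
    "AlignedRead",
    "CountMatrix",
    "EmptyRoundError",
    "align_read",
    "codon_calls",
    "tabulate",
]

_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)


class EmptyRoundError(ValueError):
    """A round contributed no accepted reads."""


@dataclass
class AlignedRead:
    """An accepted ungapped placement, stored in forward-strand orientation."""

    offset: int
    strand: str  # '+' or '-'
    aligned_sequence: str
    qualities: np.ndarray
    n_mismatches: int


@dataclass
class CountMatrix:
    """Per-round, per-site amino-acid call counts.

    ``counts`` has shape (n_rounds, n_sites, 21) over the fixed alphabet
    ``AA_ALPHABET``; ``depth`` is the per-site row sum.
    """

    rounds: list[int]
    sites: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites)
        self.counts = np.asarray(self.counts)
        expected = (len(self.rounds), len(self.sites), len(AA_ALPHABET))
        if self.counts.shape != expected:
            raise ValidationError(f"counts shape {self.counts.shape} != {expected}")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=2)

    def round_index(self, round_number: int) -> int:
        return self.rounds.index(round_number)

    def wildtype_counts(self, ref: ReferenceInsert) -> np.ndarray:
        """Per-round, per-site counts of the wild-type amino acid."""
        wt_idx = np.array([AA_INDEX[a] for a in ref.translate()])
        return self.counts[:, np.arange(len(self.sites)), wt_idx]

    def to_tsv(self, path: str | Path) -> None:
        """Write tidy counts (round, residue, aa, count); zero cells omitted."""
        with open(path, "w") as fh:
            fh.write("round\tresidue\taa\tcount\n")
            for r, rnd in enumerate(self.rounds):
                nz = np.argwhere(self.counts[r] > 0)
                for s, a in nz:
                    fh.write(
                        f"{rnd}\t{self.sites[s]}\t{AA_ALPHABET[a]}\t{self.counts[r, s, a]}\n"
                    )

    def depth_to_tsv(self, path: str | Path) -> None:
        depth = self.depth
        with open(path, "w") as fh:
            fh.write("round\tresidue\tdepth\n")
            for r, rnd in enumerate(self.rounds):
                for s, site in enumerate(self.sites):
                    fh.write(f"{rnd}\t{site}\t{depth[r, s]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, sites: np.ndarray) -> "CountMatrix":
        """Read tidy counts written by :meth:`to_tsv` (sites must be supplied)."""
        sites = np.asarray(sites)
        site_pos = {int(s): i for i, s in enumerate(sites)}
        data: dict[int, np.ndarray] = {}
        with open(path) as fh:
            fh.readline()
            for line in fh:
                rnd, residue, aa, count = line.rstrip("\n").split("\t")
                r = int(rnd)
                if r not in data:
                    data[r] = np.zeros((len(sites), len(AA_ALPHABET)), dtype=np.int64)
                data[r][site_pos[int(residue)], AA_INDEX[aa]] = int(count)
        rounds = sorted(data)
        return cls(rounds, sites, np.stack([data[r] for r in rounds]))


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

_window_cache: dict[tuple[int, int], np.ndarray] = {}


def _onehot_windows(ref: ReferenceInsert, read_len: int) -> np.ndarray:
    """One-hot (n_offsets x 4*read_len) float32 matrix of all reference windows."""
    key = (id(ref), read_len)
    if key not in _window_cache:
        windows = np.lib.stride_tricks.sliding_window_view(ref.encoded, read_len)
        onehot = (windows[:, :, None] == np.arange(4, dtype=np.uint8)).astype(np.float32)
        _window_cache[key] = np.ascontiguousarray(onehot.reshape(windows.shape[0], -1))
    return _window_cache[key]


def _onehot_reads(codes: np.ndarray) -> np.ndarray:
    onehot = (codes[:, :, None] == np.arange(4, dtype=np.uint8)).astype(np.float32)
    return onehot.reshape(codes.shape[0], -1)


def _align_batch(
    codes: np.ndarray, ref: ReferenceInsert, max_mismatch_frac: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Best ungapped placement for a batch of equal-length encoded reads.

    Returns (accepted mask, offsets, reverse-strand mask, mismatch counts).
    Ties prefer the forward strand, then the smallest offset.  Ambiguous
    bases (code > 3) never match, so they count as mismatches everywhere.
    """
    n, read_len = codes.shape
    windows = _onehot_windows(ref, read_len)
    mism_fwd = read_len - _onehot_reads(codes) @ windows.T
    rc = _COMPLEMENT[np.minimum(codes, 3)][:, ::-1]
    rc[codes[:, ::-1] > 3] = 255  # ambiguous stays ambiguous under revcomp
    mism_rev = read_len - _onehot_reads(rc) @ windows.T
    best_fwd = np.argmin(mism_fwd, axis=1)
    best_rev = np.argmin(mism_rev, axis=1)
    m_fwd = mism_fwd[np.arange(n), best_fwd]
    m_rev = mism_rev[np.arange(n), best_rev]
    use_rev = m_rev < m_fwd
    offsets = np.where(use_rev, best_rev, best_fwd)
    mismatches = np.rint(np.where(use_rev, m_rev, m_fwd)).astype(np.int64)
    accepted = mismatches <= max_mismatch_frac * read_len
    return accepted, offsets.astype(np.int64), use_rev, mismatches


def align_read(
    sequence: str,
    ref: ReferenceInsert,
    qualities: Sequence[int] | None = None,
    max_mismatch_frac: float = 0.1,
) -> AlignedRead | None:
    """Place one read on the insert; returns ``None`` if rejected.

    The scan covers every offset on both orientations; the minimum-mismatch
    placement wins, with ties broken toward the forward strand and then the
    smallest offset.  The returned read is re-oriented to the forward strand
    (sequence and qualities both reversed for '-' placements).
    """
    if len(sequence) > ref.length:
        return None
    codes = encode_sequence(sequence)[None, :]
    accepted, offsets, use_rev, mismatches = _align_batch(codes, ref, max_mismatch_frac)
    if not accepted[0]:
        return None
    qual = (
        np.full(len(sequence), 40, dtype=np.int64)
        if qualities is None
        else np.asarray(qualities, dtype=np.int64)
    )
    if use_rev[0]:
        rc = _COMPLEMENT[np.minimum(codes[0], 3)][::-1]
        seq_fwd = "".join("ACGT"[c] if c < 4 else "N" for c in rc)
        qual = qual[::-1].copy()
        strand = "-"
    else:
        seq_fwd = sequence.upper()
        strand = "+"
    return AlignedRead(int(offsets[0]), strand, seq_fwd, qual, int(mismatches[0]))


def codon_calls(
    ar: AlignedRead, ref: ReferenceInsert, min_quality: int = 20
) -> list[tuple[int, str]]:
    """Call (residue, amino acid) for every codon fully covered by the read.

    A codon is called only if all three bases lie inside the read, none is
    ambiguous, and all meet ``min_quality``.  Partial codons at read ends are
    dropped.
    """
    codes = encode_sequence(ar.aligned_sequence)
    o, l = ar.offset, len(codes)
    first = -(-o // 3)  # first codon (0-based) fully inside the read
    last = (o + l) // 3 - 1
    calls = []
    for c in range(first, last + 1):
        rel = 3 * c - o
        triple = codes[rel : rel + 3]
        if np.any(triple > 3):
            continue
        if np.any(ar.qualities[rel : rel + 3] < min_quality):
            continue
        aa = AA_ALPHABET[CODON_CODE_TO_AA[16 * triple[0] + 4 * triple[1] + triple[2]]]
        calls.append((ref.first_residue + c, aa))
    return calls


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------


def _iter_fastq(source) -> Iterable[tuple[str, str, str]]:
    if isinstance(source, (str, Path)):
        path = str(source)
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "rt") as fh:
            yield from FastqGeneralIterator(fh)
    else:
        yield from source


def _count_batch(
    codes: np.ndarray,
    phred: np.ndarray,
    ref: ReferenceInsert,
    counts: np.ndarray,
    max_mismatch_frac: float,
    min_quality: int,
) -> int:
    """Align one equal-length batch and accumulate codon calls into ``counts``."""
    accepted, offsets, use_rev, _ = _align_batch(codes, ref, max_mismatch_frac)
    if not accepted.any():
        return 0
    codes = codes[accepted]
    phred = phred[accepted]
    offsets = offsets[accepted]
    use_rev = use_rev[accepted]
    if use_rev.any():
        rc = _COMPLEMENT[np.minimum(codes[use_rev], 3)][:, ::-1]
        rc[codes[use_rev][:, ::-1] > 3] = 255
        codes[use_rev] = rc
        phred[use_rev] = phred[use_rev][:, ::-1]
    read_len = codes.shape[1]
    for o in np.unique(offsets):
        rows = offsets == o
        sub, q = codes[rows], phred[rows]
        first = -(-int(o) // 3)
        last = (int(o) + read_len) // 3 - 1
        if last < first:
            continue
        rel = 3 * np.arange(first, last + 1) - int(o)
        idx = rel[None, :, None] + np.arange(3)[None, None, :]
        triples = sub[np.arange(sub.shape[0])[:, None, None], idx]
        quals = q[np.arange(sub.shape[0])[:, None, None], idx]
        valid = (triples <= 3).all(axis=2) & (quals >= min_quality).all(axis=2)
        t = np.minimum(triples, 3).astype(np.int64)
        aa = CODON_CODE_TO_AA[16 * t[:, :, 0] + 4 * t[:, :, 1] + t[:, :, 2]]
        site_idx = np.broadcast_to(np.arange(first, last + 1), aa.shape)
        np.add.at(counts, (site_idx[valid], aa[valid]), 1)
    return int(accepted.sum())


def tabulate(
    reads_by_round: Mapping[int, object],
    ref: ReferenceInsert,
    max_mismatch_frac: float = 0.1,
    min_quality: int = 20,
    batch_size: int = 4096,
) -> tuple[CountMatrix, dict]:
    """Count codon-level amino-acid calls per round.

    Parameters
    ----------
    reads_by_round : mapping round -> FASTQ path or iterable of
        ``(name, sequence, quality-string)`` records.

    Returns the :class:`CountMatrix` and a per-round acceptance-statistics
    dict.  A round in which no read is accepted raises
    :class:`EmptyRoundError`.
    """
    rounds = sorted(reads_by_round)
    sites = np.arange(ref.first_residue, ref.last_residue + 1)
    counts = np.zeros((len(rounds), ref.n_codons, len(AA_ALPHABET)), dtype=np.int64)
    stats: dict = {"rounds": {}, "max_mismatch_frac": max_mismatch_frac, "min_quality": min_quality}
    for r, rnd in enumerate(rounds):
        n_reads = n_accepted = 0
        by_len: dict[int, tuple[list[str], list[str]]] = {}

        def flush(length: int) -> None:
            nonlocal n_accepted
            seqs, quals = by_len.pop(length)
            codes = encode_sequence("".join(seqs)).reshape(len(seqs), length)
            phred = (
                np.frombuffer("".join(quals).encode("ascii"), dtype=np.uint8).reshape(
                    len(quals), length
                ).astype(np.int64)
                - 33
            )
            n_accepted += _count_batch(
                codes, phred, ref, counts[r], max_mismatch_frac, min_quality
            )

        for name, seq, qual in _iter_fastq(reads_by_round[rnd]):
            n_reads += 1
            if len(seq) != len(qual):
                raise ValidationError(f"round {rnd}, read {name}: sequence/quality length mismatch")
            if len(seq) > ref.length or len(seq) < 3:
                continue  # unalignable: longer than the insert or sub-codon
            seqs, quals = by_len.setdefault(len(seq), ([], []))
            seqs.append(seq)
            quals.append(qual)
            if len(seqs) >= batch_size:
                flush(len(seq))
        for length in list(by_len):
            flush(length)
        if n_reads == 0 or n_accepted == 0:
            raise EmptyRoundError(f"round {rnd}: no accepted reads")
        stats["rounds"][rnd] = {
            "reads": n_reads,
            "accepted": n_accepted,
            "rejected": n_reads - n_accepted,
        }
    return CountMatrix(rounds, sites, counts), stats
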