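"""Reference insert, codon translation, and mutation coordinate model.

The analyses in this package all operate on a single protein-coding insert
(by default a 427-codon fragment corresponding to the C-terminal part of a
full-length protein, numbered in full-length protein coordinates starting at
residue 428).  This module owns the two coordinate systems -- 1-based
nucleotide positions within the insert and 1-based full-length residue
numbers -- and the derivation of amino-acid mutations from nucleotide
substitution genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqIO import parse as _fasta_parse
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

__all__ = [
    "AA_ALPHABET",
    "AA_INDEX",
    "STOP",
    "CoordinateError",
    "TranslationError",
    "ValidationError",
    "ReferenceInsert",
    "NucSubstitution",
    "AaMutation",
    "Clone",
    "translate_codon",
    "codon_index_to_residue",
    "residue_to_codon_index",
    "derive_aa_mutations",
    "has_premature_stop",
    "default_reference",
    "read_reference_fasta",
    "write_reference_fasta",
]

STOP = "*"
#: Fixed amino-acid alphabet used for all count matrices: 20 residues + stop.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY*"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

# 64-entry codon -> amino-acid lookup built from Biopython's standard table.
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_CODON_TO_AA = {c: str(Seq(c).translate(table=1)) for c in _CODONS}
#: Same lookup as a flat array indexed by 16*b0 + 4*b1 + b2 (base codes 0..3).
CODON_CODE_TO_AA = np.array([AA_INDEX[_CODON_TO_AA[c]] for c in _CODONS], dtype=np.uint8)

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


class CoordinateError(ValueError):
    """A nucleotide or residue coordinate falls outside the insert."""


class TranslationError(ValueError):
    """A codon contains a base outside {A, C, G, T}."""


class ValidationError(ValueError):
    """A genotype or parameter object violates its invariants."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes A=0, C=1, G=2, T=3 (255 = other)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def translate_codon(codon: str) -> str:
    """Translate a single codon with the standard genetic code; stops map to '*'.

    Raises
    ------
    TranslationError
        If the codon is not exactly three bases over {A, C, G, T}.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASE_INDEX for b in codon):
        raise TranslationError(f"cannot translate codon {codon!r}: ambiguous or invalid base")
    return _CODON_TO_AA[codon]


@dataclass(frozen=True)
class ReferenceInsert:
    """A protein-coding insert with full-length residue numbering.

    Parameters
    ----------
    name : str
        Identifier of the construct.
    nt_sequence : str
        Coding sequence over {A, C, G, T}; length must be divisible by 3.
    first_residue : int
        Full-length protein residue number of codon 1 (default 428, matching
        a C-terminal fragment whose first insert codon is residue 428).
    """

    name: str
    nt_sequence: str
    first_residue: int = 428

    def __post_init__(self) -> None:
        seq = self.nt_sequence.upper()
        object.__setattr__(self, "nt_sequence", seq)
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise ValidationError(f"insert length {len(seq)} is not a positive multiple of 3")
        if set(seq) - set(_BASES):
            raise ValidationError("insert sequence contains bases outside {A,C,G,T}")

    @property
    def length(self) -> int:
        return len(self.nt_sequence)

    @property
    def n_codons(self) -> int:
        return len(self.nt_sequence) // 3

    @property
    def last_residue(self) -> int:
        return self.first_residue + self.n_codons - 1

    @property
    def encoded(self) -> np.ndarray:
        """Sequence as uint8 base codes (cached)."""
        cached = getattr(self, "_encoded", None)
        if cached is None:
            cached = encode_sequence(self.nt_sequence)
            object.__setattr__(self, "_encoded", cached)
        return cached

    def codon(self, index: int) -> str:
        """Return the codon at 1-based codon ``index``."""
        if not 1 <= index <= self.n_codons:
            raise CoordinateError(f"codon index {index} outside 1..{self.n_codons}")
        return self.nt_sequence[3 * (index - 1) : 3 * index]

    def residue_wt_aa(self, residue: int) -> str:
        """Wild-type amino acid at a full-length residue number."""
        return translate_codon(self.codon(residue_to_codon_index(residue, self)))

    def translate(self) -> str:
        """Full translation of the insert."""
        return "".join(
            AA_ALPHABET[i]
            for i in CODON_CODE_TO_AA[
                self.encoded.reshape(-1, 3) @ np.array([16, 4, 1], dtype=np.int32)
            ]
        )


def codon_index_to_residue(index: int, ref: ReferenceInsert) -> int:
    """Map a 1-based codon index to its full-length residue number."""
    if not 1 <= index <= ref.n_codons:
        raise CoordinateError(f"codon index {index} outside 1..{ref.n_codons}")
    return ref.first_residue + index - 1


def residue_to_codon_index(residue: int, ref: ReferenceInsert) -> int:
    """Inverse of :func:`codon_index_to_residue`."""
    if not ref.first_residue <= residue <= ref.last_residue:
        raise CoordinateError(
            f"residue {residue} outside insert range {ref.first_residue}..{ref.last_residue}"
        )
    return residue - ref.first_residue + 1


@dataclass(frozen=True)
class NucSubstitution:
    """A single nucleotide substitution, 1-based within the insert."""

    nt_position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValidationError(f"substitution at {self.nt_position} has ref == alt")
        for b in (self.ref_base, self.alt_base):
            if b not in _BASE_INDEX:
                raise ValidationError(f"invalid base {b!r} in substitution")

    def __str__(self) -> str:
        return f"{self.nt_position}:{self.ref_base}>{self.alt_base}"

    @classmethod
    def from_string(cls, s: str) -> "NucSubstitution":
        pos, change = s.split(":")
        ref_base, alt_base = change.split(">")
        return cls(int(pos), ref_base, alt_base)


@dataclass(frozen=True, order=True)
class AaMutation:
    """An amino-acid mutation in full-length numbering, e.g. D833G."""

    residue: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValidationError(f"amino-acid mutation at {self.residue} has ref == alt")

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.residue}{self.alt_aa}"

    @property
    def is_nonsense(self) -> bool:
        return self.alt_aa == STOP


@dataclass
class Clone:
    """A library clone: an identifier plus its nucleotide substitutions.

    Substitutions are stored sorted by position with unique positions; the
    amino-acid consequences are derived lazily against a reference and cached.
    """

    clone_id: str
    substitutions: tuple[NucSubstitution, ...] = ()

    def __post_init__(self) -> None:
        subs = tuple(sorted(self.substitutions, key=lambda s: s.nt_position))
        positions = [s.nt_position for s in subs]
        if len(set(positions)) != len(positions):
            raise ValidationError(f"clone {self.clone_id}: duplicate substitution positions")
        self.substitutions = subs
        self._aa_cache: tuple[AaMutation, ...] | None = None

    def aa_mutations(self, ref: ReferenceInsert) -> tuple[AaMutation, ...]:
        if self._aa_cache is None:
            self._aa_cache = tuple(derive_aa_mutations(self, ref))
        return self._aa_cache


def _validate_substitutions(clone: Clone, ref: ReferenceInsert) -> None:
    for sub in clone.substitutions:
        if not 1 <= sub.nt_position <= ref.length:
            raise CoordinateError(
                f"clone {clone.clone_id}: position {sub.nt_position} outside insert"
            )
        actual = ref.nt_sequence[sub.nt_position - 1]
        if actual != sub.ref_base:
            raise ValidationError(
                f"clone {clone.clone_id}: ref base mismatch at {sub.nt_position} "
                f"(reference has {actual}, substitution claims {sub.ref_base})"
            )


def derive_aa_mutations(clone: Clone, ref: ReferenceInsert) -> list[AaMutation]:
    """Derive amino-acid mutations from a clone's nucleotide substitutions.

    All substitutions falling in one codon are applied jointly before
    translation, so two hits in the same codon yield at most one amino-acid
    record (and none if the joint change is silent).
    """
    _validate_substitutions(clone, ref)
    by_codon: dict[int, list[NucSubstitution]] = {}
    for sub in clone.substitutions:
        by_codon.setdefault((sub.nt_position - 1) // 3, []).append(sub)
    mutations = []
    for codon_idx0, subs in sorted(by_codon.items()):
        codon = list(ref.nt_sequence[3 * codon_idx0 : 3 * codon_idx0 + 3])
        for sub in subs:
            codon[(sub.nt_position - 1) % 3] = sub.alt_base
        wt_aa = translate_codon(ref.codon(codon_idx0 + 1))
        alt_aa = translate_codon("".join(codon))
        if alt_aa != wt_aa:
            mutations.append(
                AaMutation(codon_index_to_residue(codon_idx0 + 1, ref), wt_aa, alt_aa)
            )
    return mutations


def has_premature_stop(clone: Clone, ref: ReferenceInsert) -> bool:
    """True if any derived amino-acid mutation introduces a stop codon."""
    return any(m.is_nonsense for m in clone.aa_mutations(ref))


# ---------------------------------------------------------------------------
# Default reference fixture
# ---------------------------------------------------------------------------

# Wild-type residues that the default fixture must carry so that mutation
# names used throughout the clone tables (D833G, Y818D, ...) translate
# correctly against it.
FIXTURE_WT_RESIDUES: dict[int, str] = {
    701: "T", 705: "P", 730: "D", 735: "R", 742: "F", 744: "S", 747: "K",
    751: "E", 752: "N", 755: "N", 756: "S", 759: "E", 768: "Y", 780: "I",
    784: "L", 787: "K", 788: "V", 789: "W", 790: "N", 791: "F", 794: "L",
    795: "I", 796: "M", 803: "S", 804: "N", 809: "N", 816: "I", 818: "Y",
    819: "Q", 820: "D", 822: "D", 824: "D", 825: "F", 828: "L", 830: "S",
    833: "D", 834: "W", 835: "N", 836: "V", 838: "K", 839: "E", 840: "M",
    841: "L", 847: "K",
}

# One deterministic codon per amino acid for constrained positions
# (frequent yeast codons; D -> GAT so that a single A>G transition in codon
# position 2 yields the canonical D -> G exchange).
_PREFERRED_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTG", "M": "ATG", "N": "AAT",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

_NON_STOP_CODONS = [c for c in _CODONS if _CODON_TO_AA[c] != STOP]


def default_reference(
    n_codons: int = 427, first_residue: int = 428, seed: int = 20160705
) -> ReferenceInsert:
    """Build the deterministic default insert (427 codons, residues 428-854).

    Codons are drawn from the 61 non-stop codons with a fixed seed, then the
    residues named in the shipped clone tables are overwritten with fixed
    codons for their required wild-type amino acids.  The result has no
    internal stop codon and is identical across runs.
    """
    rng = np.random.default_rng(seed)
    codons = [_NON_STOP_CODONS[i] for i in rng.integers(0, len(_NON_STOP_CODONS), n_codons)]
    for residue, aa in FIXTURE_WT_RESIDUES.items():
        idx = residue - first_residue
        if 0 <= idx < n_codons:
            codons[idx] = _PREFERRED_CODON[aa]
    return ReferenceInsert(
        name=f"insert_{first_residue}-{first_residue + n_codons - 1}",
        nt_sequence="".join(codons),
        first_residue=first_residue,
    )


def read_reference_fasta(path: str | Path) -> ReferenceInsert:
    """Read a single-record FASTA; ``first_residue=<n>`` may appear in the description."""
    records = list(_fasta_parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValidationError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    first_residue = 428
    for token in rec.description.split():
        if token.startswith("first_residue="):
            first_residue = int(token.split("=", 1)[1])
    return ReferenceInsert(name=rec.id, nt_sequence=str(rec.seq), first_residue=first_residue)


def write_reference_fasta(ref: ReferenceInsert, path: str | Path) -> None:
    rec = SeqRecord(
        Seq(ref.nt_sequence), id=ref.name, description=f"first_residue={ref.first_residue}"
    )
    SeqIO.write([rec], str(path), "fasta")
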