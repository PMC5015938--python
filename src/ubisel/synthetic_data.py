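"""Simulation of a mutant-library selection experiment.

This module generates everything the downstream analyses consume:

* an error-prone-PCR mutant library (nucleotide substitutions at a target
  rate of ~5/kb with a transition-biased spectrum, emulating dPTP/8oxo-dGTP
  base-analog mutagenesis),
* serial uracil-dropout selection rounds in which loss of binding to the
  partner protein restores reporter (Ura3) activity and hence growth,
* rare late-arising rearranged/insert-less clones that escape selection
  entirely, and
* per-round amplicon FASTQ reads with substitution sequencing errors.

The growth model is deliberately minimal: during one 24-h round a clone with
Ura3 activity ``u`` grows by a factor ``2**(G*u)`` (``G`` effective
generations), after which a fixed-size bottleneck is sampled multinomially.
With all activities equal the expected frequencies are exactly preserved, so
the neutral case is an exact null.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .core_model import (
    AA_ALPHABET,
    AA_INDEX,
    Clone,
    NucSubstitution,
    ReferenceInsert,
    ValidationError,
    has_premature_stop,
)

__all__ = [
    "MutagenesisParams",
    "EffectTable",
    "SelectionParams",
    "ReadSimParams",
    "Population",
    "default_spectrum",
    "default_effect_table",
    "mutagenize",
    "binding_activity",
    "ura3_activity",
    "advance_round",
    "simulate_selection",
    "sample_population",
    "simulate_reads",
    "write_fastq",
    "population_aa_frequencies",
    "sample_count_matrix",
]

_BASES = "ACGT"
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G in code space
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_spectrum(transition_weight: float = 0.8) -> np.ndarray:
    """Row-normalized 4x4 substitution spectrum (rows/cols ordered A,C,G,T).

    Each base mutates to its transition partner with probability
    ``transition_weight`` and to either transversion with equal shares of the
    remainder.  The default 0.8 reflects the strongly transition-biased
    chemistry of dPTP-driven mutagenesis; 8oxo-dGTP transversions make up the
    rest.
    """
    if not 0 <= transition_weight <= 1:
        raise ValidationError("transition_weight must be in [0, 1]")
    tv = (1.0 - transition_weight) / 2.0
    # transition partners in code space: A(0)<->G(2), C(1)<->T(3)
    spectrum = np.zeros((4, 4))
    for b, partner in enumerate([2, 3, 0, 1]):
        spectrum[b, partner] = transition_weight
        for alt in range(4):
            if alt not in (b, partner):
                spectrum[b, alt] = tv
    return spectrum


@dataclass(frozen=True)
class MutagenesisParams:
    """Error-prone PCR parameters.

    ``per_base_rate`` is the substitution probability per nucleotide per
    clone; the default 0.005 reproduces the target of ~5 substitutions per
    kilobase.  ``spectrum`` is a row-normalized 4x4 matrix (zero diagonal)
    giving the distribution of the substituted base conditional on the
    reference base.
    """

    per_base_rate: float = 0.005
    spectrum: np.ndarray = field(default_factory=default_spectrum)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.per_base_rate <= 0.05:
            raise ValidationError("per_base_rate must be in [0, 0.05]")
        spectrum = np.asarray(self.spectrum, dtype=float)
        if spectrum.shape != (4, 4) or np.any(spectrum < 0) or np.any(np.diag(spectrum) != 0):
            raise ValidationError("spectrum must be 4x4, non-negative, zero diagonal")
        if not np.allclose(spectrum.sum(axis=1), 1.0):
            raise ValidationError("spectrum rows must sum to 1")
        object.__setattr__(self, "spectrum", spectrum)


@dataclass
class EffectTable:
    """Planted ground truth: binding-disruption effect per residue in [0, 1].

    ``position_effects[residue]`` applies to any amino-acid change at that
    residue; ``substitution_overrides[(residue, alt_aa)]`` refines single
    substitutions.  Unlisted mutations are neutral (effect 0).
    """

    position_effects: dict[int, float] = field(default_factory=dict)
    substitution_overrides: dict[tuple[int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in list(self.position_effects.values()) + list(
            self.substitution_overrides.values()
        ):
            if not 0.0 <= e <= 1.0:
                raise ValidationError(f"effect {e} outside [0, 1]")

    def effect(self, residue: int, alt_aa: str) -> float:
        override = self.substitution_overrides.get((residue, alt_aa))
        if override is not None:
            return override
        return self.position_effects.get(residue, 0.0)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("residue\talt_aa\teffect\n")
            for residue, e in sorted(self.position_effects.items()):
                fh.write(f"{residue}\t.\t{e}\n")
            for (residue, aa), e in sorted(self.substitution_overrides.items()):
                fh.write(f"{residue}\t{aa}\t{e}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EffectTable":
        positions: dict[int, float] = {}
        overrides: dict[tuple[int, str], float] = {}
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                residue, alt_aa, e = line.rstrip("\n").split("\t")
                if alt_aa == ".":
                    positions[int(residue)] = float(e)
                else:
                    overrides[(int(residue), alt_aa)] = float(e)
        return cls(positions, overrides)


def default_effect_table() -> EffectTable:
    """Default planted interface: seven strong binding-disruption sites.

    The residues are the canonical round-5 enriched set of the worked example
    (Y818, Q819, D820, D824, L828, D833, W834), with D833 strongest so that
    rank-order checks are well posed.
    """
    return EffectTable(
        position_effects={
            818: 0.90, 819: 0.85, 820: 0.85, 824: 0.85,
            828: 0.88, 833: 0.95, 834: 0.93,
        }
    )


@dataclass(frozen=True)
class SelectionParams:
    """Serial-selection parameters.

    ``generations_per_round`` (G) scales growth advantage per 24-h round;
    ``truncation_activity`` is the residual reporter activity of clones with
    premature stops (truncated fusions yield little Ura3 activity, so they
    compete poorly against clean interaction-breakers); rearranged /
    insert-less clones have full activity ``rearrangement_activity`` and
    arise at ``rearrangement_rate`` per surviving lineage per round.
    """

    n_rounds: int = 5
    generations_per_round: float = 10.0
    truncation_activity: float = 0.2
    rearrangement_activity: float = 1.0
    rearrangement_rate: float = 1e-4
    bottleneck_size: int = 100_000
    sequencing_sample: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 0:
            raise ValidationError("n_rounds must be >= 0")
        if self.bottleneck_size < 1 or self.sequencing_sample < 1:
            raise ValidationError("bottleneck_size and sequencing_sample must be >= 1")
        for u in (self.truncation_activity, self.rearrangement_activity):
            if not 0 <= u <= 1:
                raise ValidationError("activities must be in [0, 1]")


@dataclass(frozen=True)
class ReadSimParams:
    """Amplicon read-simulation parameters (single-end, substitution errors only)."""

    read_length: int = 150
    n_reads_per_round: int = 200_000
    error_rate: float = 0.001
    quality_score: int = 30
    strand_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.1:
            raise ValidationError("error_rate must be in [0, 0.1)")
        if not 0 <= self.strand_prob <= 1:
            raise ValidationError("strand_prob must be in [0, 1]")


@dataclass
class Population:
    """A selection-round population: clone genotypes plus abundances.

    ``clones[clone_id]`` is a :class:`~ubisel.core_model.Clone`, or ``None``
    for rearranged / insert-less clones (these carry no alignable insert and
    are excluded from read simulation).  Round 0 is the unselected library.
    """

    round_index: int
    clones: dict[str, Clone | None]
    abundances: dict[str, int]

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValidationError("population total must be > 0")
        if set(self.clones) != set(self.abundances):
            raise ValidationError("clones and abundances must share keys")

    @property
    def total(self) -> int:
        return sum(self.abundances.values())

    def frequency_of(self, clone_id: str) -> float:
        return self.abundances[clone_id] / self.total

    def insert_bearing(self) -> tuple[list[str], np.ndarray]:
        """Clone ids with an alignable insert and their counts."""
        ids = [cid for cid, c in self.clones.items() if c is not None]
        counts = np.array([self.abundances[cid] for cid in ids], dtype=np.int64)
        return ids, counts

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("clone_id\tcount\tsubstitutions\n")
            for cid in sorted(self.abundances):
                clone = self.clones[cid]
                geno = "REARRANGED" if clone is None else ";".join(
                    str(s) for s in clone.substitutions
                )
                fh.write(f"{cid}\t{self.abundances[cid]}\t{geno}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, round_index: int = 0) -> "Population":
        clones: dict[str, Clone | None] = {}
        abundances: dict[str, int] = {}
        with open(path) as fh:
            fh.readline()
            for line in fh:
                cid, count, geno = line.rstrip("\n").split("\t")
                abundances[cid] = int(count)
                if geno == "REARRANGED":
                    clones[cid] = None
                else:
                    subs = tuple(
                        NucSubstitution.from_string(s) for s in geno.split(";") if s
                    )
                    clones[cid] = Clone(cid, subs)
        return cls(round_index, clones, abundances)


# ---------------------------------------------------------------------------
# Mutagenesis
# ---------------------------------------------------------------------------


def mutagenize(
    ref: ReferenceInsert, params: MutagenesisParams, n_clones: int
) -> Population:
    """Generate the unselected (round-0) library.

    Each clone receives ``Binomial(L, per_base_rate)`` substitutions at
    distinct uniform positions; the substituted base is drawn from the
    spectrum row of the reference base.  All clones start at abundance 1.
    """
    if n_clones < 1:
        raise ValidationError("n_clones must be >= 1")
    rng = np.random.default_rng(params.seed)
    L = ref.length
    ref_codes = ref.encoded
    n_subs = rng.binomial(L, params.per_base_rate, size=n_clones)
    # cumulative spectrum rows for inverse-CDF sampling of the alt base
    cum = np.cumsum(params.spectrum, axis=1)
    clones: dict[str, Clone | None] = {}
    abundances: dict[str, int] = {}
    width = len(str(n_clones))
    for i in range(n_clones):
        k = int(n_subs[i])
        cid = f"c{i:0{width}d}"
        if k == 0:
            clones[cid] = Clone(cid)
        else:
            positions = np.sort(rng.choice(L, size=k, replace=False))
            refs = ref_codes[positions]
            alts = np.argmax(cum[refs] > rng.random((k, 1)), axis=1)
            subs = tuple(
                NucSubstitution(int(p) + 1, _BASES[r], _BASES[a])
                for p, r, a in zip(positions, refs, alts)
            )
            clones[cid] = Clone(cid, subs)
        abundances[cid] = 1
    return Population(0, clones, abundances)


# ---------------------------------------------------------------------------
# Selection model
# ---------------------------------------------------------------------------


def binding_activity(clone: Clone, effects: EffectTable, ref: ReferenceInsert) -> float:
    """Binding activity b in [0, 1]: product over missense mutations of (1 - effect).

    Wild type gives 1.  Nonsense records are ignored here; truncation is
    handled by :func:`ura3_activity`.
    """
    b = 1.0
    for m in clone.aa_mutations(ref):
        if not m.is_nonsense:
            b *= 1.0 - effects.effect(m.residue, m.alt_aa)
    return b


def ura3_activity(
    clone: Clone | None,
    effects: EffectTable,
    params: SelectionParams,
    ref: ReferenceInsert,
) -> float:
    """Reporter activity u in [0, 1] driving growth on uracil-dropout medium.

    Full-length in-frame clones: u = 1 - b (binding degrades the reporter).
    Clones with a premature stop: the fixed residual ``truncation_activity``.
    Rearranged / insert-less clones (``None``): ``rearrangement_activity``.
    """
    if clone is None:
        return params.rearrangement_activity
    if has_premature_stop(clone, ref):
        return params.truncation_activity
    return 1.0 - binding_activity(clone, effects, ref)


def advance_round(
    pop: Population,
    effects: EffectTable,
    params: SelectionParams,
    ref: ReferenceInsert,
) -> Population:
    """One selection round: deterministic growth, then a multinomial bottleneck.

    Clone ``c`` grows to weight ``count_c * 2**(G * u_c)``; the next round's
    counts are a multinomial draw of ``bottleneck_size`` with probabilities
    proportional to the weights.  Each surviving lineage then spawns a
    rearranged derivative with probability ``rearrangement_rate`` (one unit of
    abundance moves to a new insert-less clone).  Randomness is seeded from
    ``params.seed`` and the round index, so rounds are reproducible.
    """
    rng = np.random.default_rng([params.seed, pop.round_index + 1])
    ids = sorted(pop.abundances)
    counts = np.array([pop.abundances[cid] for cid in ids], dtype=np.float64)
    u = np.array(
        [ura3_activity(pop.clones[cid], effects, params, ref) for cid in ids]
    )
    weights = counts * np.exp2(params.generations_per_round * u)
    total_w = weights.sum()
    if not total_w > 0:
        raise ValidationError("degenerate population: all growth weights are zero")
    new_counts = rng.multinomial(params.bottleneck_size, weights / total_w)

    clones: dict[str, Clone | None] = {}
    abundances: dict[str, int] = {}
    next_round = pop.round_index + 1
    n_rearr = 0
    survivors = np.nonzero(new_counts)[0]
    rearr_flags = rng.random(len(survivors)) < params.rearrangement_rate
    for j, idx in enumerate(survivors):
        cid = ids[idx]
        count = int(new_counts[idx])
        if rearr_flags[j] and pop.clones[cid] is not None:
            rearr_id = f"rearr_r{next_round}_{n_rearr}"
            clones[rearr_id] = None
            abundances[rearr_id] = 1
            n_rearr += 1
            count -= 1
            if count == 0:
                continue
        clones[cid] = pop.clones[cid]
        abundances[cid] = count
    return Population(next_round, clones, abundances)


def simulate_selection(
    ref: ReferenceInsert,
    mut_params: MutagenesisParams,
    effects: EffectTable,
    sel_params: SelectionParams,
    n_clones: int,
) -> list[Population]:
    """Mutagenize, then run ``n_rounds`` selection rounds; returns rounds 0..n."""
    pops = [mutagenize(ref, mut_params, n_clones)]
    for _ in range(sel_params.n_rounds):
        pops.append(advance_round(pops[-1], effects, sel_params, ref))
    return pops


def sample_population(pop: Population, n: int, seed: int) -> Population:
    """Multinomial subsample of ``n`` cells, e.g. the aliquot taken for sequencing."""
    rng = np.random.default_rng(seed)
    ids = sorted(pop.abundances)
    counts = np.array([pop.abundances[cid] for cid in ids], dtype=np.float64)
    drawn = rng.multinomial(n, counts / counts.sum())
    keep = np.nonzero(drawn)[0]
    return Population(
        pop.round_index,
        {ids[i]: pop.clones[ids[i]] for i in keep},
        {ids[i]: int(drawn[i]) for i in keep},
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _mutant_sequences(
    ids: Sequence[str], pop: Population, ref: ReferenceInsert
) -> np.ndarray:
    """Encoded full-insert sequences (n_clones x L, uint8) for the given clone ids."""
    seqs = np.tile(ref.encoded, (len(ids), 1))
    for row, cid in enumerate(ids):
        clone = pop.clones[cid]
        for sub in clone.substitutions:
            seqs[row, sub.nt_position - 1] = _BASES.index(sub.alt_base)
    return seqs


def simulate_reads(
    pop: Population,
    ref: ReferenceInsert,
    params: ReadSimParams,
    chunk_size: int = 20_000,
) -> Iterator[tuple[str, str, str]]:
    """Yield ``(name, sequence, quality)`` FASTQ records for one round.

    Each read samples an insert-bearing clone proportional to abundance, a
    uniform fragment start, and a strand; the clone's substitutions are
    applied, then i.i.d. substitution errors at ``error_rate``.  Qualities
    are constant.  Read names encode only round and serial number, so no
    genotype information leaks to the counting stage.  Rearranged clones
    carry no amplifiable insert and are excluded.
    """
    rl = params.read_length
    L = ref.length
    if rl > L:
        raise ValidationError(f"read_length {rl} exceeds insert length {L}")
    ids, counts = pop.insert_bearing()
    if len(ids) == 0 or counts.sum() == 0:
        raise ValidationError("population has no insert-bearing clones to sequence")
    rng = np.random.default_rng([params.seed, pop.round_index])
    freqs = counts / counts.sum()
    seqs = _mutant_sequences(ids, pop, ref)
    qual = chr(params.quality_score + 33) * rl
    window = np.arange(rl)
    serial = 0
    n_left = params.n_reads_per_round
    while n_left > 0:
        n = min(chunk_size, n_left)
        n_left -= n
        clone_idx = rng.choice(len(ids), size=n, p=freqs)
        starts = rng.integers(0, L - rl + 1, size=n)
        fragments = seqs[clone_idx[:, None], starts[:, None] + window]
        err = rng.random((n, rl)) < params.error_rate
        n_err = int(err.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            fragments[err] = (fragments[err] + shift) % 4
        rev = rng.random(n) < params.strand_prob
        fragments[rev] = _COMPLEMENT[fragments[rev]][:, ::-1]
        ascii_frag = _DECODE[fragments]
        for i in range(n):
            yield (f"r{pop.round_index}_{serial}", ascii_frag[i].tobytes().decode(), qual)
            serial += 1


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    """Write ``(name, seq, qual)`` records as FASTQ (gzipped if path ends in .gz)."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    n = 0
    with opener(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Read-free counting channel
# ---------------------------------------------------------------------------


def population_aa_frequencies(pop: Population, ref: ReferenceInsert) -> np.ndarray:
    """Exact per-site amino-acid frequencies (n_codons x 21) of a population.

    Computed at the codon level from the clone genotypes of insert-bearing
    clones (silent changes remain wild type; nonsense codons fall in the stop
    column), i.e. what error-free, infinitely deep sequencing would observe.
    """
    ids, counts = pop.insert_bearing()
    if counts.sum() == 0:
        raise ValidationError("population has no insert-bearing clones")
    n_sites = ref.n_codons
    wt_aa_idx = np.array([AA_INDEX[a] for a in ref.translate()])
    freqs = np.zeros((n_sites, len(AA_ALPHABET)))
    total = counts.sum()
    freqs[np.arange(n_sites), wt_aa_idx] = total
    for cid, count in zip(ids, counts):
        for m in pop.clones[cid].aa_mutations(ref):
            site = m.residue - ref.first_residue
            freqs[site, AA_INDEX[m.ref_aa]] -= count
            freqs[site, AA_INDEX[m.alt_aa]] += count
    return freqs / total


def sample_count_matrix(pops: Sequence[Population], ref: ReferenceInsert, depth: int, seed: int):
    """Sample a CountMatrix directly from population genotypes (no reads).

    Per round and site, ``depth`` codon observations are drawn multinomially
    from the population's exact amino-acid frequencies.  This is the fast,
    sequencing-error-free channel used for calibration studies; the FASTQ
    channel (:func:`simulate_reads` + variant counting) is the full pipeline.
    """
    from .variant_counts import CountMatrix

    rng = np.random.default_rng(seed)
    rounds = [p.round_index for p in pops]
    sites = np.arange(ref.first_residue, ref.last_residue + 1)
    counts = np.zeros((len(pops), ref.n_codons, len(AA_ALPHABET)), dtype=np.int64)
    for r, pop in enumerate(pops):
        freqs = population_aa_frequencies(pop, ref)
        for s in range(ref.n_codons):
            counts[r, s] = rng.multinomial(depth, freqs[s])
    return CountMatrix(rounds=list(rounds), sites=sites, counts=counts)
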