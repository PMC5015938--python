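# Methods

## The selection model

`ubisel` models a split-ubiquitin interaction selection as a discrete-round
birth process.  Each clone is a set of nucleotide substitutions on a single
protein-coding insert (default: a 427-codon fragment numbered 428–854 in
full-length coordinates).  Its phenotype is derived in three steps:

1. **Genotype → protein.**  All substitutions within one codon are applied
   jointly and translated with the standard genetic code; silent changes are
   dropped, stops are flagged as truncations.
2. **Protein → binding.**  Binding activity is a product of independent
   per-mutation effects, `b = Π (1 − e(m))`, with `e(m) ∈ [0, 1]` taken from
   a substitution-specific override when present, else a per-residue effect,
   else 0.  Independence across sites is an assumption, not a claim: real
   interfaces show epistasis, and the product form merely makes multi-hit
   clones at least as disruptive as their worst single hit.
3. **Binding → growth.**  Reporter (Ura3) activity is `u = 1 − b` for
   full-length clones.  Truncated clones get a fixed residual
   `truncation_activity` (default 0.2): a truncated fusion yields little
   reporter activity, so nonsense mutations enjoy a weak advantage but are
   out-competed by clean interaction breakers — the bias the selection design
   relies on.  Rearranged / insert-less clones get
   `rearrangement_activity` (default 1.0) and arise spontaneously at
   `rearrangement_rate` (default 10⁻⁴ per surviving lineage per round),
   reproducing the late-appearing escape clones such selections show.
   One 24-h round multiplies clone abundance by `2^(G·u)` with
   `G = generations_per_round = 10`, then a multinomial bottleneck resamples
   `bottleneck_size` (default 100,000) cells.  The linear map `u = 1 − b`
   is a modeling choice; partial binders are known to grow at intermediate
   rates, but no quantitative growth-rate data exist to calibrate a more
   elaborate map.

Because growth weights multiply abundances and the bottleneck is
multinomial, equal activities leave expected frequencies exactly unchanged:
the all-neutral configuration is an exact null.  Note that "all planted
effects zero" alone is *not* neutral — truncated clones would still grow at
`2^(G·0.2)` per round and drag their passenger mutations up.  Neutral-null
analyses therefore also set `truncation_activity = 0` and
`rearrangement_rate = 0`.

## Mutagenesis

Error-prone PCR with base analogs is modeled as i.i.d. per-base
substitution: each clone receives `Binomial(L, per_base_rate)` substitutions
at distinct uniform positions.  The default rate 0.005/nt reproduces the
target of ~5 substitutions per kilobase (≈ 6.4 per 1,281-nt insert).  The
substituted base follows a row-normalized 4×4 spectrum; the default gives
each base its transition partner with probability 0.8 and either
transversion 0.1 each, reflecting strongly transition-biased dPTP chemistry
with 8oxo-dGTP transversions making up the remainder
(`default_spectrum(transition_weight)` to change).  PCR jackpot effects
(cycle-correlated mutations) and indel errors are not modeled.

## Read simulation and counting

Reads are single-end, fixed-length (default 150 nt at 200,000 reads/round),
drawn from insert-bearing clones proportional to abundance, with uniform
fragment start, Bernoulli(0.5) strand, i.i.d. substitution errors (default
10⁻³/base), and constant Phred quality.  Rearranged clones carry no
amplifiable insert and are excluded, mirroring amplicon protocols in which
deletion/rearrangement clones are not amplified.  An optional
`sequencing_sample` bottleneck (default 20,000 cells) models the aliquot
taken for plasmid isolation.

Counting is deliberately heuristic-free: every read is placed by an
exhaustive ungapped scan over all offsets on both orientations (vectorized
as a one-hot matrix product, which computes exactly the per-offset Hamming
distance), accepted if its best placement has ≤ `max_mismatch_frac`
(default 0.1) mismatches — permissive enough for clones carrying up to ~14
substitutions — and tallied codon-by-codon.  A codon is called only when all
three bases lie inside the read, are unambiguous, and meet `min_quality`
(default Q20); stop codons are counted in a dedicated `*` column rather than
discarded.  Ties in placement prefer the forward strand, then the smallest
offset.  Gapped placements are not attempted (the simulator emits no
indels); reads that would need them are rejected and logged.  Paired-read
reconciliation is out of scope.

Alongside the FASTQ channel there is a read-free channel
(`sample_count_matrix`) that draws codon observations directly from a
population's exact per-site amino-acid frequencies.  It is used for
calibration studies (e.g. the neutral null over many seeds) where sequencing
error and coverage geometry are not the question; the FASTQ channel is the
full pipeline.

## Enrichment values

Per site and round, the signal is the pseudocounted non-wild-type frequency
`f = (non_WT + α)/(depth + 2α)` with Jeffreys-style `α = 0.5`, and the
enrichment value is `E = log2(f_r / f_0)` against the unselected library.
Per-round log2 increments telescope, so combining scores across rounds and
taking the direct ratio to the library coincide under this definition — the
package tests this to machine precision.  Cells with depth below `min_depth`
(default 1,000, the lower end of realistic post-filter amplicon depth) in
either compared round are masked as data-deficient and exported as white/`NA`.
Site-level `E` (all non-WT amino acids pooled) is the primary display; a
per-substitution analog is produced for diagnostics.  No variance or
significance estimate is attached to `E`; with one sequencing library per
round there is no replicate structure to estimate it from.

## Clone tables and hotspots

Sanger clone tables are TSV rows of comma-separated mutation strings
(`D833G`, `I780` for positional/silent records, `in-frame deletion from K787
on`, rearrangement/empty-plasmid markers).  A *hotspot* is an identical
missense mutation recurring in ≥ `hotspot_min_count` (default 3) evaluated
clones, or in ≥ `hotspot_min_frac` (default 0.25) of them — singletons never
qualify.  Both prongs are needed: a thrice-recurring mutation in a round of
18 evaluated clones (16.7%) is a hotspot by recurrence even though it misses
the fractional cut, while a twice-recurring one in a round of 10 (20%) is
not.  Empty-plasmid and unalignable (rearranged) clones are excluded from
denominators.  Region classification (PB domain 781–854, second helix
831–841, acidic clusters {820, 822, 824} and {833}, interface = clusters +
{818, 825, 830}) lives in an editable annotation file because these regions
are defined by membership examples rather than sharp boundaries.

## Structure contacts

Distances are minimum heavy-atom distances; "side chain" means atoms beyond
the backbone (CB inclusive), with glycine falling back to CA.  Multi-model
NMR ensembles default to model 1, with min/median across models available —
when a printed contact distance is not reproduced by model 1, the cross-model
minimum is the natural fallback.  Chain and numbering offsets are explicit
config; the overlay refuses to silently produce an empty result when no
enriched site maps into the structure's residue range.  Accessions are never
fetched from the network implicitly; a local PDB/mmCIF file must be
supplied.  The shipped `synthetic_pb_complex.pdb` is a schematic,
artificially-placed two-chain fixture (labelled synthetic in the file) used
to exercise the geometry code, including a planted 3.69 Å side-chain
contact between an ASP 833 and an ARG 510; it is not a real structure and
supports no structural conclusions.

## Problem sizes and what the tests show

Simulation studies in the test suite and `scripts/acceptance.py` run at desk
scale: libraries of 10,000 clones (a real electroporation library is ~10⁷),
30,000 reads/round (vs ~200,000), bottlenecks of 10⁵ cells, 5 rounds.  These
sizes give per-site depths of ~3,500 — inside the realistic 10³–2×10⁴
band — and are chosen so the planted-recovery and neutral-null studies are
informative while each completing in well under a minute per replicate.
The planted-recovery configuration uses effects of 0.9 at seven interface
sites with the known strongest site at 0.95, so that "the strongest effect
ranks first" is a well-posed check.

Passing these studies shows that the pipeline is internally consistent
(counting matches a brute-force oracle exactly, the neutral null is
centered, planted signal is recovered in rank order) — not that the effect
model, error model, or depth geometry matches any particular real dataset.
Real amplicon data add PCR jackpots, position-dependent error rates,
paired-end structure, and epistasis, none of which the generator emulates.

## Numerical and degenerate-input choices

* Pseudocount `α = 0.5` keeps frequencies strictly inside (0, 1); depth-0
  cells evaluate to `f = 0.5` and are always masked.
* Enrichment of a site with identical counts at equal depth is exactly 0
  (same `f`), not merely close.
* `advance_round` totals are conserved exactly (`bottleneck_size`), and a
  population with no positive growth weight raises rather than returning an
  empty population.
* Ranking ties break by ascending residue number, making reports
  deterministic.
* All randomness flows from explicit integer seeds, one per stage
  (mutagenesis; each selection round via `(seed, round)`; sequencing
  subsample; reads), so every artifact is byte-reproducible and stages can
  be rerun in isolation.
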