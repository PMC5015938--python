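# ubisel

Simulation and analysis of **split-ubiquitin selections for
protein-complex-interfering mutations**.

## The problem

The split-ubiquitin assay turns a protein–protein interaction into a growth
phenotype: a bait fused to C-terminal ubiquitin plus an RUra3 reporter
(Cub-RUra3, "CRU") interacts with an Nub-tagged prey, ubiquitin refolds, and
the reporter is cleaved and degraded — so cells carrying an *interacting*
pair stop growing on uracil-dropout medium, while cells whose bait carries an
*interaction-breaking* mutation keep their Ura3 and keep dividing.  Growing a
randomly mutagenized bait library in liquid SD ura⁻ for several serial
rounds therefore enriches mutations that disrupt one specific interface —
e.g. the PB domain of the Cdc42 GEF Cdc24 (Cdc24_428-854) against the PB
domain of the scaffold Bem1, where the exchange D833G in the second acidic
cluster abolishes binding.

`ubisel` packages the computational side of that experiment for people who
want to design, simulate, or analyze such selections:

* **synthetic_data** — an error-prone-PCR library model (default 0.005
  substitutions/nt ≈ 5/kb, transition-biased base-analog spectrum), serial
  selection rounds under a binding → Ura3 → growth model, and per-round
  amplicon FASTQ reads (~depth 10³–10⁴ per site).
* **variant_counts** — exhaustive ungapped placement of amplicon reads on
  the insert and quality-filtered, codon-level amino-acid counting
  (rounds × sites × 21 matrix).
* **enrichment** — per-site enrichment values
  `E = log2(f_r / f_0)` with `f = (non-WT + α)/(depth + 2α)`, depth
  masking of data-deficient positions, site ranking, and heat-map export.
* **clone_table** — Sanger-era clone genotype tables: per-round summaries,
  hotspot detection, interface/helix region classification, multi-hit
  analysis, mutation-spectrum plots.
* **structure_map** — residue–residue contact geometry on a two-chain
  complex structure (PDB/mmCIF via gemmi), e.g. the D833–R510 salt-bridge
  distance, and overlays of enriched sites onto the contact map.
* **cli** — a `ubisel` command with `simulate`, `count`, `enrich`,
  `clones`, `structure`, and `all` subcommands driven by one YAML config.

The model at the core: a clone with missense mutations *m* has binding
activity `b = Π (1 − e(m))` with per-site effects `e ∈ [0,1]`; its reporter
activity is `u = 1 − b` (truncated clones get a small residual `u`, plasmid
rearrangements get full `u`); one selection round multiplies a clone's
abundance by `2^(G·u)` before a fixed-size multinomial bottleneck.  With all
activities equal, expected frequencies are preserved exactly, so the neutral
case is an exact null for the enrichment statistic.

## Worked example

Simulate a 10,000-clone library with seven planted interface sites (Y818,
Q819, D820, D824, L828, D833, W834; D833 strongest), five selection rounds,
30,000 reads per round, then count and score:

```python
from ubisel.core_model import default_reference
from ubisel import synthetic_data as sd, variant_counts as vc, enrichment as en

ref = default_reference()                 # 427 codons, residues 428-854
effects = sd.default_effect_table()       # the seven planted interface sites
pops = sd.simulate_selection(ref, sd.MutagenesisParams(seed=1), effects,
                             sd.SelectionParams(seed=2), n_clones=10_000)
reads = {p.round_index: sd.simulate_reads(p, ref,
                                          sd.ReadSimParams(n_reads_per_round=30_000, seed=7))
         for p in pops}
cm, stats = vc.tabulate(reads, ref)
em = en.build_enrichment(cm, ref, min_depth=1000)
for site, e in en.rank_enriched(em, 5, top_k=7):
    print(site, round(e, 2))
```

prints

```
833 4.99
828 4.49
818 3.95
834 3.36
824 3.3
820 2.72
819 2.35
```

— all seven planted sites lead the round-5 ranking, the strongest planted
effect (D833) first, with log2 enrichment values in the same 2–5 range a
real selection of this design produces.  Sites whose read depth falls below
`min_depth` in any compared round are masked and rendered white/`NA` in the
heat-map export.

The same run from the shell:

```bash
ubisel all --config run.yaml     # simulate + count + enrich, manifest.json with hashes
ubisel clones --table src/ubisel/data/example_clone_table.tsv --out clone_report/
```

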