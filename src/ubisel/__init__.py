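"""ubisel: simulate and analyze split-ubiquitin selections for
protein-complex-interfering mutations.

Subpackages
-----------
core_model
    Reference insert, codon translation, coordinate mapping.
synthetic_data
    Mutant-library mutagenesis, serial-selection dynamics, read simulation.
variant_counts
    Ungapped amplicon alignment and codon-level variant counting.
enrichment
    Per-site log2 enrichment values, depth masking, ranking, heat maps.
clone_table
    Sanger clone genotype tables: summaries, hotspots, region classification.
structure_map
    Residue-contact geometry on a two-chain complex structure.
cli
    ``ubisel`` command-line pipeline over the above.
"""

from importlib.resources import files as _files

from .core_model import (
    AA_ALPHABET,
    AaMutation,
    Clone,
    NucSubstitution,
    ReferenceInsert,
    default_reference,
)
from .synthetic_data import (
    EffectTable,
    MutagenesisParams,
    Population,
    ReadSimParams,
    SelectionParams,
    default_effect_table,
    mutagenize,
    simulate_reads,
    simulate_selection,
)
from .variant_counts import CountMatrix, align_read, codon_calls, tabulate
from .enrichment import EnrichmentMatrix, build_enrichment, rank_enriched

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a shipped data fixture (clone table, annotation, structure)."""
    return _files("ubisel.data") / name
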