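"""Residue-contact geometry on a two-chain complex structure.

Maps enrichment results onto a PB-domain complex (e.g. the NMR ensemble of
the PB_Cdc24/PB_Bem1 complex, PDB entry 2KFK, if a local copy is supplied):
minimum heavy-atom distances between residues, inter-chain contact lists at
a distance cutoff, and an overlay annotating enriched sites with their
contact status.  Structures are parsed with gemmi (PDB and mmCIF); waters
and heteroatoms are dropped.  For NMR ensembles every deposited model is
loaded; distances default to model 1, with helpers for the minimum or
median across models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "StructureModel",
    "ContactRecord",
    "StructureParseError",
    "FetchRequiredError",
    "ResidueLookupError",
    "NumberingMismatchError",
    "load_structure",
    "min_distance",
    "min_distance_across_models",
    "interface_contacts",
    "overlay_enrichment",
    "write_contacts_tsv",
]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


class StructureParseError(ValueError):
    pass


class FetchRequiredError(RuntimeError):
    """An accession was given but no local file exists and fetching needs network."""


class ResidueLookupError(KeyError):
    pass


class NumberingMismatchError(ValueError):
    pass


@dataclass
class StructureModel:
    """One model of a structure: heavy-atom records grouped by residue.

    ``atoms`` rows are (chain_id, residue_number, residue_name, atom_name,
    element, x, y, z).
    """

    model_index: int
    atoms: list[tuple[str, int, str, str, str, float, float, float]]

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, int], list[int]] = {}
        for i, row in enumerate(self.atoms):
            self._index.setdefault((row[0], row[1]), []).append(i)

    def chains(self) -> list[str]:
        return sorted({row[0] for row in self.atoms})

    def residues(self, chain: str) -> list[int]:
        return sorted({r for c, r in self._index if c == chain})

    def residue_name(self, chain: str, number: int) -> str:
        return self.atoms[self._index[(chain, number)][0]][2]

    def residue_coords(
        self, chain: str, number: int, sidechain_only: bool = False
    ) -> tuple[list[str], np.ndarray]:
        """Heavy-atom names and coordinates of one residue.

        With ``sidechain_only`` the backbone (N, CA, C, O, OXT) is dropped;
        glycine, having no side chain, falls back to its CA.
        """
        key = (chain, number)
        if key not in self._index:
            raise ResidueLookupError(f"residue {chain}/{number} not in model {self.model_index}")
        rows = [self.atoms[i] for i in self._index[key]]
        if sidechain_only:
            kept = [r for r in rows if r[3] not in _BACKBONE]
            if not kept:  # glycine (or incomplete residue): fall back to CA
                kept = [r for r in rows if r[3] == "CA"] or rows
            rows = kept
        names = [r[3] for r in rows]
        coords = np.array([[r[5], r[6], r[7]] for r in rows], dtype=float)
        return names, coords


@dataclass(frozen=True)
class ContactRecord:
    """Minimum-distance record between two residues (symmetric in a/b)."""

    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    min_distance: float
    atom_pair: tuple[str, str]

    def swapped(self) -> "ContactRecord":
        return ContactRecord(
            self.residue_b, self.residue_a, self.min_distance, self.atom_pair[::-1]
        )


def load_structure(source: str | Path) -> list[StructureModel]:
    """Load all models of a PDB/mmCIF file, heavy polymer atoms only.

    A bare 4-character accession (no such file on disk) raises
    :class:`FetchRequiredError`: this package never fetches from the network
    implicitly.
    """
    import gemmi

    path = Path(source)
    if not path.exists():
        if len(str(source)) == 4 and str(source).isalnum():
            raise FetchRequiredError(
                f"{source!r} looks like a PDB accession; download it yourself and "
                "pass the file path (no implicit network access)"
            )
        raise StructureParseError(f"no such structure file: {source}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    st.remove_waters()
    models = []
    for m_idx, model in enumerate(st, start=1):
        atoms = []
        for chain in model:
            for residue in chain:
                if residue.het_flag == "H":
                    continue  # heteroatoms/ligands excluded
                for atom in residue:
                    if atom.element.is_hydrogen:
                        continue
                    atoms.append(
                        (
                            chain.name,
                            residue.seqid.num,
                            residue.name,
                            atom.name,
                            atom.element.name,
                            atom.pos.x,
                            atom.pos.y,
                            atom.pos.z,
                        )
                    )
        if atoms:
            models.append(StructureModel(m_idx, atoms))
    if not models:
        raise StructureParseError(f"{path}: no polymer atoms found")
    return models


def min_distance(
    model: StructureModel,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    sidechain_only: bool = True,
) -> ContactRecord:
    """Minimum distance between two residues over admissible heavy-atom pairs."""
    names_a, xyz_a = model.residue_coords(*res_a, sidechain_only=sidechain_only)
    names_b, xyz_b = model.residue_coords(*res_b, sidechain_only=sidechain_only)
    d = np.linalg.norm(xyz_a[:, None, :] - xyz_b[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return ContactRecord(res_a, res_b, float(d[i, j]), (names_a[i], names_b[j]))


def min_distance_across_models(
    models: Sequence[StructureModel],
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    sidechain_only: bool = True,
    statistic: str = "min",
) -> float:
    """Minimum or median of the per-model minimum distance over an NMR ensemble."""
    values = [
        min_distance(m, res_a, res_b, sidechain_only=sidechain_only).min_distance
        for m in models
    ]
    if statistic == "min":
        return float(np.min(values))
    if statistic == "median":
        return float(np.median(values))
    raise ValueError(f"unknown statistic {statistic!r}")


def interface_contacts(
    model: StructureModel, chain_a: str, chain_b: str, cutoff: float = 5.0
) -> list[ContactRecord]:
    """All inter-chain residue pairs with min heavy-atom distance <= cutoff.

    Records are normalized with ``residue_a`` on ``chain_a`` and sorted by
    distance (ties by residue numbers).
    """
    for chain in (chain_a, chain_b):
        if chain not in model.chains():
            raise ResidueLookupError(f"chain {chain!r} not in model (has {model.chains()})")

    def chain_arrays(chain: str):
        rows = [r for r in model.atoms if r[0] == chain]
        xyz = np.array([[r[5], r[6], r[7]] for r in rows])
        resnum = np.array([r[1] for r in rows])
        names = [r[3] for r in rows]
        return rows, xyz, resnum, names

    _, xyz_a, res_a, names_a = chain_arrays(chain_a)
    _, xyz_b, res_b, names_b = chain_arrays(chain_b)
    d = np.linalg.norm(xyz_a[:, None, :] - xyz_b[None, :, :], axis=2)
    within = d <= cutoff
    contacts = {}
    for i, j in np.argwhere(within):
        key = (int(res_a[i]), int(res_b[j]))
        if key not in contacts or d[i, j] < contacts[key][0]:
            contacts[key] = (float(d[i, j]), (names_a[i], names_b[j]))
    records = [
        ContactRecord((chain_a, ra), (chain_b, rb), dist, pair)
        for (ra, rb), (dist, pair) in contacts.items()
    ]
    records.sort(key=lambda c: (c.min_distance, c.residue_a[1], c.residue_b[1]))
    return records


def overlay_enrichment(
    enriched_sites: Sequence[tuple[int, float]],
    contacts: Sequence[ContactRecord],
    structure_residues: Sequence[int] | None = None,
    offset: int = 0,
) -> list[dict]:
    """Annotate enriched sites with their interface-contact status.

    ``offset`` converts analysis numbering to structure numbering
    (structure_residue = residue + offset).  If ``structure_residues`` is
    given and no enriched site maps into it, a
    :class:`NumberingMismatchError` is raised with a hint -- a silently empty
    overlay almost always means the numbering offset is wrong.
    """
    if enriched_sites and structure_residues is not None:
        mapped = {r + offset for r, _ in enriched_sites}
        if not mapped & set(structure_residues):
            raise NumberingMismatchError(
                "no enriched site maps into the structure's residue range "
                f"({min(structure_residues)}..{max(structure_residues)}); "
                "check the numbering offset"
            )
    by_residue: dict[int, ContactRecord] = {}
    for c in contacts:
        r = c.residue_a[1]
        if r not in by_residue or c.min_distance < by_residue[r].min_distance:
            by_residue[r] = c
    rows = []
    for residue, e in enriched_sites:
        hit = by_residue.get(residue + offset)
        rows.append(
            {
                "residue": residue,
                "E": e,
                "is_contact": hit is not None,
                "nearest_partner_residue": None if hit is None else hit.residue_b[1],
                "distance": None if hit is None else hit.min_distance,
            }
        )
    return rows


def write_contacts_tsv(contacts: Sequence[ContactRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chain_a\tresidue_a\tchain_b\tresidue_b\tmin_distance\tatom_a\tatom_b\n")
        for c in contacts:
            fh.write(
                f"{c.residue_a[0]}\t{c.residue_a[1]}\t{c.residue_b[0]}\t{c.residue_b[1]}\t"
                f"{c.min_distance:.3f}\t{c.atom_pair[0]}\t{c.atom_pair[1]}\n"
            )
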