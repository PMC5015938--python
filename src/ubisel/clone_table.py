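"""Sanger-era clone genotype tables: parsing, per-round summaries, hotspots.

Input tables are TSV with columns ``clone_id``, ``round``, ``mutations``
(comma-separated strings such as ``D833G``, ``in-frame deletion from K787
on``, ``Complete rearrangement; no insert``) and ``status`` (``evaluated``,
``not_evaluated`` or ``empty_plasmid``).  A *hotspot* is an identical
missense mutation recurring in at least ``hotspot_min_frac`` of the round's
evaluated clones (and at least twice, so singletons never qualify).

Region classification places residues into the PB domain, its second
alpha-helix, the two acidic interface clusters, and the combined binding
interface; boundaries live in an editable annotation rather than in code
because they are defined by example membership, not crystal-clear limits.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "MutationRecord",
    "CloneRecord",
    "RoundSummary",
    "RegionAnnotation",
    "MutationParseError",
    "parse_mutation_string",
    "format_mutation",
    "read_clone_table",
    "write_clone_table",
    "summarize_round",
    "summarize_table",
    "default_annotation",
    "classify_position",
    "count_interface_hits",
    "mutation_spectrum",
    "mutation_spectrum_plot",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


class MutationParseError(ValueError):
    pass


@dataclass(frozen=True)
class MutationRecord:
    """One parsed mutation token.

    ``kind`` is one of ``missense``, ``silent`` (a positional record with no
    substituted residue, e.g. ``I780``), ``deletion_from`` (an in-frame
    deletion starting at ``residue``), ``rearrangement`` or
    ``empty_plasmid``.
    """

    kind: str
    residue: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    @property
    def is_missense(self) -> bool:
        return self.kind == "missense"


_MISSENSE_RE = re.compile(rf"^([{_AA}])(\d+)([{_AA}*])$")
_SILENT_RE = re.compile(rf"^([{_AA}])(\d+)$")
_DELETION_RE = re.compile(rf"^in-frame deletion from ([{_AA}])(\d+) on$", re.IGNORECASE)


def parse_mutation_string(s: str) -> MutationRecord | None:
    """Parse one mutation token; returns ``None`` for absence markers.

    Grammar: ``<RefAa><Pos><AltAa>`` -> missense; ``<RefAa><Pos>`` ->
    silent/positional; ``in-frame deletion from <RefAa><Pos> on`` ->
    deletion_from; anything containing "rearrangement" -> rearrangement;
    "empty plasmid" -> empty_plasmid; "None"/"" -> absence.
    """
    token = s.strip()
    if token in ("", "None", "none", "-", "."):
        return None
    if "rearrangement" in token.lower():
        return MutationRecord("rearrangement")
    if "empty plasmid" in token.lower():
        return MutationRecord("empty_plasmid")
    m = _DELETION_RE.match(token)
    if m:
        return MutationRecord("deletion_from", int(m.group(2)), m.group(1))
    m = _MISSENSE_RE.match(token)
    if m:
        ref_aa, residue, alt_aa = m.group(1), int(m.group(2)), m.group(3)
        if ref_aa == alt_aa:
            raise MutationParseError(f"mutation {token!r} has identical ref and alt residue")
        return MutationRecord("missense", residue, ref_aa, alt_aa)
    m = _SILENT_RE.match(token)
    if m:
        return MutationRecord("silent", int(m.group(2)), m.group(1))
    raise MutationParseError(f"cannot parse mutation string {token!r}")


def format_mutation(rec: MutationRecord) -> str:
    """Canonical string form; inverse of :func:`parse_mutation_string`."""
    if rec.kind == "missense":
        return f"{rec.ref_aa}{rec.residue}{rec.alt_aa}"
    if rec.kind == "silent":
        return f"{rec.ref_aa}{rec.residue}"
    if rec.kind == "deletion_from":
        return f"in-frame deletion from {rec.ref_aa}{rec.residue} on"
    if rec.kind == "rearrangement":
        return "Complete rearrangement; no insert"
    if rec.kind == "empty_plasmid":
        return "empty plasmid"
    raise ValueError(f"unknown mutation kind {rec.kind!r}")


@dataclass
class CloneRecord:
    clone_id: str
    round: int
    mutations: list[MutationRecord] = field(default_factory=list)
    evaluated: bool = True
    status: str = "evaluated"

    def __post_init__(self) -> None:
        kinds = {m.kind for m in self.mutations}
        if kinds & {"rearrangement", "empty_plasmid"}:
            if any(m.is_missense for m in self.mutations):
                raise MutationParseError(
                    f"clone {self.clone_id}: rearranged/empty clones cannot carry missense records"
                )

    @property
    def missense(self) -> list[MutationRecord]:
        return [m for m in self.mutations if m.is_missense]


@dataclass
class RoundSummary:
    round: int
    clones_sequenced: int
    empty_plasmid: int
    not_evaluated: int
    evaluated: int
    hotspots: list[tuple[MutationRecord, int, float]]

    def hotspot_names(self) -> list[str]:
        return [format_mutation(m) for m, _, _ in self.hotspots]


def read_clone_table(path: str | Path) -> list[CloneRecord]:
    """Read a clone table TSV; parse errors are reported with row numbers."""
    clones = []
    with open(path) as fh:
        rows = [line.rstrip("\n") for line in fh]
    for row_no, line in enumerate(rows, start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "clone_id":
            continue
        if len(fields) != 4:
            raise MutationParseError(f"{path} row {row_no}: expected 4 columns, got {len(fields)}")
        clone_id, rnd, mutations_str, status = fields
        if status not in ("evaluated", "not_evaluated", "empty_plasmid"):
            raise MutationParseError(f"{path} row {row_no}: unknown status {status!r}")
        mutations = []
        try:
            for token in mutations_str.split(","):
                rec = parse_mutation_string(token)
                if rec is not None:
                    mutations.append(rec)
            clones.append(
                CloneRecord(
                    clone_id, int(rnd), mutations, evaluated=status == "evaluated", status=status
                )
            )
        except MutationParseError as exc:
            raise MutationParseError(f"{path} row {row_no}: {exc}") from exc
    return clones


def write_clone_table(clones: Iterable[CloneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("clone_id\tround\tmutations\tstatus\n")
        for c in clones:
            muts = ", ".join(format_mutation(m) for m in c.mutations) or "None"
            fh.write(f"{c.clone_id}\t{c.round}\t{muts}\t{c.status}\n")


def summarize_round(
    clones: Sequence[CloneRecord],
    hotspot_min_frac: float = 0.25,
    hotspot_min_count: int = 3,
) -> RoundSummary:
    """Per-round summary with hotspot calls.

    Hotspot: an identical missense mutation carried either by at least
    ``hotspot_min_count`` evaluated clones or by at least
    ``ceil(hotspot_min_frac * n_evaluated)`` of them (always >= 2, so
    singletons never qualify); fractions are over evaluated clones.
    Empty-plasmid and not-evaluated clones are excluded from the
    denominator.  The two-pronged rule lets a thrice-recurring mutation
    count as a hotspot even in a well-sampled round where three clones fall
    short of the fractional cut.
    """
    rounds = {c.round for c in clones}
    if len(rounds) > 1:
        raise ValueError(f"clones span multiple rounds: {sorted(rounds)}")
    rnd = rounds.pop() if rounds else 0
    n_empty = sum(1 for c in clones if c.status == "empty_plasmid")
    n_not_eval = sum(1 for c in clones if c.status == "not_evaluated")
    evaluated = [c for c in clones if c.evaluated]
    tally: Counter[MutationRecord] = Counter()
    for c in evaluated:
        for m in set(c.missense):
            tally[m] += 1
    frac_threshold = max(2, math.ceil(hotspot_min_frac * len(evaluated))) if evaluated else 2
    threshold = min(max(2, hotspot_min_count), frac_threshold)
    hotspots = [
        (m, k, k / len(evaluated))
        for m, k in tally.items()
        if k >= threshold
    ]
    hotspots.sort(key=lambda t: (-t[1], t[0].residue))
    return RoundSummary(rnd, len(clones), n_empty, n_not_eval, len(evaluated), hotspots)


def summarize_table(
    clones: Sequence[CloneRecord], hotspot_min_frac: float = 0.25
) -> list[RoundSummary]:
    """Summaries for every round present, in round order."""
    by_round: dict[int, list[CloneRecord]] = {}
    for c in clones:
        by_round.setdefault(c.round, []).append(c)
    return [summarize_round(by_round[r], hotspot_min_frac) for r in sorted(by_round)]


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------


@dataclass
class RegionAnnotation:
    """Residue regions of the insert used to classify mutations.

    Defaults: PB domain 781-854; second helix 831-841; acidic cluster 1
    {820, 822, 824}; acidic cluster 2 {833}; interface = both clusters plus
    the other interface-contributing residues {818, 825, 830}.
    """

    pb_domain: tuple[int, int] = (781, 854)
    second_helix: tuple[int, int] = (831, 841)
    acidic_cluster_1: frozenset[int] = frozenset({820, 822, 824})
    acidic_cluster_2: frozenset[int] = frozenset({833})
    interface: frozenset[int] = frozenset({818, 820, 822, 824, 825, 830, 833})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("region\tresidues\n")
            fh.write(f"pb_domain\t{self.pb_domain[0]}-{self.pb_domain[1]}\n")
            fh.write(f"second_helix\t{self.second_helix[0]}-{self.second_helix[1]}\n")
            for name in ("acidic_cluster_1", "acidic_cluster_2", "interface"):
                members = ",".join(str(r) for r in sorted(getattr(self, name)))
                fh.write(f"{name}\t{members}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionAnnotation":
        kwargs = {}
        with open(path) as fh:
            fh.readline()
            for line in fh:
                name, residues = line.rstrip("\n").split("\t")
                if "-" in residues:
                    start, end = residues.split("-")
                    kwargs[name] = (int(start), int(end))
                else:
                    kwargs[name] = frozenset(int(r) for r in residues.split(","))
        return cls(**kwargs)


def default_annotation() -> RegionAnnotation:
    return RegionAnnotation()


def classify_position(residue: int, ann: RegionAnnotation) -> set[str]:
    """All region labels containing the residue (possibly empty)."""
    labels = set()
    if ann.pb_domain[0] <= residue <= ann.pb_domain[1]:
        labels.add("pb_domain")
    if ann.second_helix[0] <= residue <= ann.second_helix[1]:
        labels.add("second_helix")
    if residue in ann.acidic_cluster_1:
        labels.add("acidic_cluster_1")
    if residue in ann.acidic_cluster_2:
        labels.add("acidic_cluster_2")
    if residue in ann.interface:
        labels.add("interface")
    return labels


def count_interface_hits(clone: CloneRecord, ann: RegionAnnotation) -> int:
    """Number of missense mutations in the interface or the second helix.

    Multi-hit clones (two or more interface/helix mutations, none of which
    recurs alone) are the signature of alterations that need to combine to
    break the interaction.
    """
    if not clone.evaluated:
        raise ValueError(f"clone {clone.clone_id} was not evaluated")
    return sum(
        1
        for m in clone.missense
        if classify_position(m.residue, ann) & {"interface", "second_helix"}
    )


# ---------------------------------------------------------------------------
# Mutation spectrum
# ---------------------------------------------------------------------------


def mutation_spectrum(clones: Sequence[CloneRecord]):
    """Tidy per-round mutation frequencies over evaluated clones.

    Returns a DataFrame with columns round, residue, mutation, kind, count,
    fraction.  Deletions are placed at their start residue and keep their
    ``deletion_from`` kind so plots can flag them.
    """
    import pandas as pd

    rows = []
    by_round: dict[int, list[CloneRecord]] = {}
    for c in clones:
        by_round.setdefault(c.round, []).append(c)
    for rnd in sorted(by_round):
        evaluated = [c for c in by_round[rnd] if c.evaluated]
        tally: Counter[MutationRecord] = Counter()
        for c in evaluated:
            for m in set(c.mutations):
                if m.kind in ("missense", "deletion_from"):
                    tally[m] += 1
        for m, k in sorted(tally.items(), key=lambda t: t[0].residue):
            rows.append(
                {
                    "round": rnd,
                    "residue": m.residue,
                    "mutation": format_mutation(m),
                    "kind": m.kind,
                    "count": k,
                    "fraction": k / len(evaluated) if evaluated else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["round", "residue", "mutation", "kind", "count", "fraction"])


def mutation_spectrum_plot(clones: Sequence[CloneRecord], path: str | Path):
    """Per-round bar chart of mutation frequencies (deletions flagged in magenta)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = mutation_spectrum(clones)
    rounds = sorted(df["round"].unique()) if len(df) else []
    fig, axes = plt.subplots(
        max(1, len(rounds)), 1, figsize=(8, 1.8 * max(1, len(rounds))), sharex=True, squeeze=False
    )
    for ax, rnd in zip(axes.ravel(), rounds):
        sub = df[df["round"] == rnd]
        colors = ["magenta" if k == "deletion_from" else "steelblue" for k in sub["kind"]]
        ax.bar(sub["residue"], 100 * sub["fraction"], color=colors, width=2.0)
        ax.set_ylabel(f"round {rnd}\n% clones", fontsize=7)
    if rounds:
        axes.ravel()[len(rounds) - 1].set_xlabel("residue")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return df
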