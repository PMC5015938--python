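"""Per-site enrichment values from count matrices.

A site's signal in round ``r`` is its pseudocounted non-wild-type frequency

    f = (non_wildtype_count + alpha) / (depth + 2*alpha)

and its enrichment value relative to the unselected library (round 0) is
``E = log2(f_r / f_0)``.  Because per-round increments telescope,
``sum_r log2(f_r / f_{r-1}) == log2(f_r / f_0)`` exactly, so combining
per-round scores and taking the ratio to the library are the same thing
under this definition.  Cells whose depth falls below ``min_depth`` in
either the target round or the library are data-deficient and masked
(rendered white / NA).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_model import AA_ALPHABET, AA_INDEX, ReferenceInsert, ValidationError
from .variant_counts import CountMatrix

__all__ = [
    "FrequencyMatrix",
    "EnrichmentMatrix",
    "site_frequency",
    "enrichment_value",
    "build_frequencies",
    "build_enrichment",
    "rank_enriched",
    "export_heatmap",
    "read_enrichment_tsv",
    "read_region_annotation",
]


def site_frequency(non_wt_count, depth, alpha: float = 0.5):
    """Pseudocounted per-site non-wild-type frequency; strictly inside (0, 1).

    Accepts scalars or arrays.  Depth 0 gives 0.5 (pure pseudocount; such
    cells are masked downstream).
    """
    non_wt = np.asarray(non_wt_count, dtype=float)
    d = np.asarray(depth, dtype=float)
    if np.any(non_wt < 0) or np.any(d < 0):
        raise ValidationError("counts and depth must be non-negative")
    if np.any(non_wt > d):
        raise ValidationError("non-wild-type count exceeds depth")
    out = (non_wt + alpha) / (d + 2 * alpha)
    return float(out) if out.ndim == 0 else out


def enrichment_value(f_r, f_0):
    """log2 enrichment of frequency ``f_r`` relative to baseline ``f_0``."""
    f_r = np.asarray(f_r, dtype=float)
    f_0 = np.asarray(f_0, dtype=float)
    if np.any(f_r <= 0) or np.any(f_0 <= 0):
        raise ValidationError("frequencies must be strictly positive")
    out = np.log2(f_r / f_0)
    return float(out) if out.ndim == 0 else out


@dataclass
class FrequencyMatrix:
    """Per-site and per-substitution pseudocounted frequencies."""

    rounds: list[int]
    sites: np.ndarray
    f: np.ndarray  # (n_rounds, n_sites)
    f_sub: np.ndarray  # (n_rounds, n_sites, 21)
    alpha: float


@dataclass
class EnrichmentMatrix:
    """Per-round, per-site log2 enrichment with a data-deficiency mask.

    ``E[r, i]`` compares ``rounds[r]`` against ``baseline_round``;
    ``mask[r, i]`` is True where either round's depth is below ``min_depth``
    (no value is defined there).  ``E_sub`` is the per-substitution analog
    (n_rounds x n_sites x 21) sharing the same mask; the wild-type column is
    NaN.
    """

    rounds: list[int]
    baseline_round: int
    sites: np.ndarray
    E: np.ndarray
    mask: np.ndarray
    min_depth: int
    E_sub: np.ndarray | None = None

    def value(self, round_number: int, residue: int) -> float:
        r = self.rounds.index(round_number)
        i = int(np.searchsorted(self.sites, residue))
        if self.sites[i] != residue:
            raise ValidationError(f"residue {residue} not in matrix")
        if self.mask[r, i]:
            raise ValidationError(f"residue {residue}, round {round_number} is data-deficient")
        return float(self.E[r, i])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("round\tresidue\tE\tmasked\n")
            for r, rnd in enumerate(self.rounds):
                for i, site in enumerate(self.sites):
                    if self.mask[r, i]:
                        fh.write(f"{rnd}\t{site}\tNA\t1\n")
                    else:
                        fh.write(f"{rnd}\t{site}\t{float(self.E[r, i])!r}\t0\n")


def build_frequencies(
    cm: CountMatrix, ref: ReferenceInsert, alpha: float = 0.5
) -> FrequencyMatrix:
    """Pseudocounted frequencies from a count matrix."""
    depth = cm.depth
    wt = cm.wildtype_counts(ref)
    f = site_frequency(depth - wt, depth, alpha)
    f_sub = (cm.counts + alpha) / (depth[:, :, None] + 2 * alpha)
    return FrequencyMatrix(list(cm.rounds), cm.sites, f, f_sub, alpha)


def build_enrichment(
    cm: CountMatrix,
    ref: ReferenceInsert,
    alpha: float = 0.5,
    min_depth: int = 1000,
    baseline_round: int = 0,
) -> EnrichmentMatrix:
    """Site-level enrichment matrix (with per-substitution analog attached).

    Round ``baseline_round`` (the unselected library) must be present; every
    other round is compared against it.  Cells with depth below ``min_depth``
    in either round are masked.
    """
    if baseline_round not in cm.rounds:
        raise ValidationError(
            f"count matrix lacks the library baseline (round {baseline_round})"
        )
    fm = build_frequencies(cm, ref, alpha)
    b = cm.round_index(baseline_round)
    target_rows = [r for r, rnd in enumerate(cm.rounds) if rnd != baseline_round]
    rounds = [cm.rounds[r] for r in target_rows]
    depth = cm.depth
    E = np.log2(fm.f[target_rows] / fm.f[b])
    mask = (depth[target_rows] < min_depth) | (depth[b] < min_depth)[None, :]
    E_sub = np.log2(fm.f_sub[target_rows] / fm.f_sub[b])
    wt_idx = np.array([AA_INDEX[a] for a in ref.translate()])
    E_sub[:, np.arange(len(cm.sites)), wt_idx] = np.nan
    E = np.where(mask, np.nan, E)
    E_sub = np.where(mask[:, :, None], np.nan, E_sub)
    return EnrichmentMatrix(rounds, baseline_round, cm.sites, E, mask, min_depth, E_sub)


def rank_enriched(
    em: EnrichmentMatrix, round_number: int, top_k: int | None = None
) -> list[tuple[int, float]]:
    """Unmasked sites of one round sorted by E descending (ties: residue ascending)."""
    if round_number not in em.rounds:
        raise ValidationError(f"round {round_number} not in enrichment matrix")
    r = em.rounds.index(round_number)
    keep = ~em.mask[r]
    if not keep.any():
        import warnings

        warnings.warn(f"round {round_number}: all sites are data-deficient")
        return []
    sites = em.sites[keep]
    values = em.E[r, keep]
    order = np.lexsort((sites, -values))
    ranked = [(int(sites[i]), float(values[i])) for i in order]
    return ranked if top_k is None else ranked[:top_k]


def read_region_annotation(path: str | Path) -> list[tuple[int, int, str]]:
    """Read a BED-like region file: start_residue <TAB> end_residue <TAB> label."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("start"):
                continue
            start, end, label = line.split("\t")[:3]
            regions.append((int(start), int(end), label))
    return regions


def export_heatmap(
    em: EnrichmentMatrix,
    png_path: str | Path,
    tsv_path: str | Path,
    annotation: Sequence[tuple[int, int, str]] | None = None,
    residue_range: tuple[int, int] | None = None,
    svg_path: str | Path | None = None,
) -> None:
    """Render the site x round heat map (masked cells white) and its TSV twin.

    ``residue_range`` restricts the rendered columns (e.g. to zoom into one
    domain); the TSV always mirrors exactly what is rendered.  ``annotation``
    regions are drawn as labelled spans under the site axis.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if residue_range is None:
        keep = np.ones(len(em.sites), dtype=bool)
    else:
        keep = (em.sites >= residue_range[0]) & (em.sites <= residue_range[1])
    sites = em.sites[keep]
    if len(sites) == 0:
        raise ValidationError("residue_range selects no sites")
    sub = EnrichmentMatrix(
        em.rounds, em.baseline_round, sites, em.E[:, keep], em.mask[:, keep], em.min_depth
    )
    sub.to_tsv(tsv_path)

    data = np.ma.masked_where(sub.mask, sub.E)
    fig, ax = plt.subplots(
        figsize=(max(6.0, len(sites) / 18), 1.0 + 0.55 * len(sub.rounds) + (0.5 if annotation else 0))
    )
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("white")
    im = ax.imshow(data, aspect="auto", cmap=cmap, interpolation="nearest")
    ax.set_yticks(range(len(sub.rounds)), [f"round {r}" for r in sub.rounds])
    step = max(1, len(sites) // 25)
    ax.set_xticks(range(0, len(sites), step), sites[::step], rotation=90, fontsize=6)
    ax.set_xlabel("residue")
    fig.colorbar(im, ax=ax, label="enrichment value (log2)")
    if annotation:
        site_pos = {int(s): i for i, s in enumerate(sites)}
        for start, end, label in annotation:
            cols = [site_pos[s] for s in range(start, end + 1) if s in site_pos]
            if not cols:
                continue
            ax.annotate(
                label,
                xy=((min(cols) + max(cols)) / 2, len(sub.rounds) - 0.5),
                xytext=(0, -28),
                textcoords="offset points",
                ha="center",
                fontsize=7,
                annotation_clip=False,
            )
            ax.plot(
                [min(cols) - 0.5, max(cols) + 0.5],
                [len(sub.rounds) - 0.45] * 2,
                clip_on=False,
                lw=3,
            )
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    if svg_path is not None:
        fig.savefig(svg_path)
    plt.close(fig)


def read_enrichment_tsv(path: str | Path) -> "EnrichmentMatrix":
    """Re-read an enrichment TSV written by :meth:`EnrichmentMatrix.to_tsv`."""
    rows: dict[int, dict[int, tuple[float, bool]]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            rnd, residue, e, masked = line.rstrip("\n").split("\t")
            rows.setdefault(int(rnd), {})[int(residue)] = (
                np.nan if e == "NA" else float(e),
                masked == "1",
            )
    rounds = sorted(rows)
    sites = np.array(sorted(rows[rounds[0]]))
    E = np.array([[rows[r][s][0] for s in sites] for r in rounds])
    mask = np.array([[rows[r][s][1] for s in sites] for r in rounds])
    return EnrichmentMatrix(rounds, -1, sites, E, mask, min_depth=0)
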