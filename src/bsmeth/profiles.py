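"""Genome-scale methylome summaries.

Global per-context methylation levels (site-mean and pooled), bimodal
hypo/mid/hyper classification, CG-density x methylation-level heatmaps per
genomic feature (200 bp windows, per-strand depth >= 10, per-density-bin
median lines) and metagene profiles over six functional elements of a
transcriptional unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import seq_to_codes, _C, _G

METAGENE_ELEMENTS = [
    "upstream", "first_exon", "first_intron", "internal_body", "last_exon", "downstream",
]


@dataclass(frozen=True)
class BimodalSummary:
    context: str
    frac_hypo: float
    frac_mid: float
    frac_hyper: float
    n_sites: int


@dataclass
class DensityHeatmap:
    """Fig.-5-style summary: CG-site abundance by (CG density, level bin)."""

    feature_label: str
    x_densities: np.ndarray          # CG dinucleotides per window, 0..max
    level_bin_edges: np.ndarray      # y-axis bin edges on [0,1]
    cell_counts: np.ndarray          # shape (n_x, n_level_bins)
    median_line: np.ndarray          # per-density median level, NaN if empty
    x_marginal: np.ndarray
    y_marginal: np.ndarray
    n_sites: int

    def to_dict(self) -> dict:
        return {
            "feature_label": self.feature_label,
            "x_densities": self.x_densities.tolist(),
            "level_bin_edges": self.level_bin_edges.tolist(),
            "cell_counts": self.cell_counts.tolist(),
            "median_line": [None if np.isnan(v) else v for v in self.median_line],
            "x_marginal": self.x_marginal.tolist(),
            "y_marginal": self.y_marginal.tolist(),
            "n_sites": self.n_sites,
        }


def global_levels(calls: pd.DataFrame, mode: str = "site_mean") -> dict[str, float]:
    """Genome-wide methylation level per context.

    ``site_mean``: unweighted mean of defined site levels (the default
    reading of genome-wide percentages). ``pooled``: total C over total
    depth. Contexts with no covered site are omitted.
    """
    if mode not in ("site_mean", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    out: dict[str, float] = {}
    for ctx, grp in calls.groupby("context"):
        if mode == "site_mean":
            levels = grp["level"].dropna()
            if len(levels):
                out[ctx] = float(levels.mean())
        else:
            depth = (grp["meth_count"] + grp["unmeth_count"]) if "unmeth_count" in grp else grp["depth"]
            total = depth.sum()
            if total > 0:
                out[ctx] = float(grp["meth_count"].sum() / total)
    return out


def bimodal_fractions(
    calls: pd.DataFrame, lo: float = 0.2, hi: float = 0.8, context: str = "CG"
) -> BimodalSummary:
    """Fractions of sites with level < lo (hypo) and > hi (hyper).

    Inequalities are strict: a site at exactly ``lo`` or ``hi`` is mid.
    Sites with undefined level are excluded from the denominator.
    """
    if lo >= hi:
        raise ValueError(f"lo must be < hi, got lo={lo}, hi={hi}")
    levels = calls.loc[calls["context"] == context, "level"].dropna().to_numpy()
    n = levels.size
    if n == 0:
        return BimodalSummary(context, float("nan"), float("nan"), float("nan"), 0)
    n_hypo = int(np.count_nonzero(levels < lo))
    n_hyper = int(np.count_nonzero(levels > hi))
    n_mid = n - n_hypo - n_hyper
    return BimodalSummary(context, n_hypo / n, n_mid / n, n_hyper / n, n)


def cg_density(genome, contig: str, window_start: int, window_size: int = 200) -> int:
    """Number of CG dinucleotides whose C lies inside the window.

    A dinucleotide spanning the window's right edge counts (its C is
    inside); windows are truncated at the contig end.
    """
    seq = genome.contigs[contig] if hasattr(genome, "contigs") else genome[contig]
    lo = max(0, window_start)
    hi = min(window_start + window_size, len(seq))
    count = 0
    for i in range(lo, hi):
        if seq[i] == "C" and i + 1 < len(seq) and seq[i + 1] == "G":
            count += 1
    return count


def _window_densities(seq: str, fstart: int, fend: int, window: int) -> np.ndarray:
    """CG count per non-overlapping window tiled from the feature start."""
    codes = seq_to_codes(seq)
    is_cg = np.zeros(len(codes), dtype=np.int64)
    if len(codes) >= 2:
        is_cg[:-1] = (codes[:-1] == _C) & (codes[1:] == _G)
    cum = np.concatenate([[0], np.cumsum(is_cg)])
    starts = np.arange(fstart, fend, window)
    ends = np.minimum(starts + window, min(fend, len(codes)))
    ends = np.minimum(ends, len(codes))
    starts = np.minimum(starts, len(codes))
    return cum[ends] - cum[starts]


def density_methylation_heatmap(
    calls: pd.DataFrame,
    genome,
    features: list[tuple[str, int, int]],
    feature_label: str = "feature",
    min_per_strand_depth: int = 10,
    window: int = 200,
    n_level_bins: int = 20,
) -> DensityHeatmap:
    """CG abundance binned by local CG density and methylation level.

    Each CG site with per-strand depth >= ``min_per_strand_depth`` and a
    defined level inside a feature contributes one count at (density of
    its enclosing 200 bp window, its level bin); the median line is the
    per-density-bin median level. Windows tile each feature from its
    start. An input with no qualifying site yields an empty heatmap.
    """
    if not features:
        raise ValueError("features must be non-empty")
    contigs = genome.contigs if hasattr(genome, "contigs") else genome
    edges = np.linspace(0.0, 1.0, n_level_bins + 1)

    densities: list[int] = []
    levels: list[float] = []
    cg = calls[
        (calls["context"] == "CG")
        & (calls["depth"] >= min_per_strand_depth)
        & calls["level"].notna()
    ]
    for contig, fstart, fend in features:
        seq = contigs[contig]
        wdens = _window_densities(seq, fstart, fend, window)
        sub = cg[(cg["contig"] == contig) & (cg["pos"] >= fstart) & (cg["pos"] < fend)]
        if sub.empty:
            continue
        widx = ((sub["pos"].to_numpy() - fstart) // window).astype(int)
        densities.extend(wdens[widx].tolist())
        levels.extend(sub["level"].tolist())

    n_sites = len(levels)
    if n_sites == 0:
        return DensityHeatmap(
            feature_label, np.arange(0), edges, np.zeros((0, n_level_bins), dtype=int),
            np.array([]), np.array([], dtype=int), np.zeros(n_level_bins, dtype=int), 0,
        )
    dens = np.asarray(densities)
    lvls = np.asarray(levels)
    ybin = np.minimum((lvls * n_level_bins).astype(int), n_level_bins - 1)
    max_d = int(dens.max())
    cells = np.zeros((max_d + 1, n_level_bins), dtype=int)
    np.add.at(cells, (dens, ybin), 1)
    median = np.full(max_d + 1, np.nan)
    for d in range(max_d + 1):
        sel = lvls[dens == d]
        if sel.size:
            median[d] = float(np.median(sel))
    return DensityHeatmap(
        feature_label,
        np.arange(max_d + 1),
        edges,
        cells,
        median,
        cells.sum(axis=1),
        cells.sum(axis=0),
        n_sites,
    )


def _element_intervals(gene, flank: int) -> dict[str, tuple[int, int]]:
    """Half-open genomic intervals of the six functional elements, strand-aware.

    ``internal_body`` is the gene body between the first intron and the
    last exon (it contains all intermediate exons and introns); for a
    two-exon gene it is empty and for a single-exon gene only
    ``first_exon`` and the flanks exist.
    """
    exons = sorted(gene.exons)
    iv: dict[str, tuple[int, int]] = {}
    if gene.strand == "+":
        iv["upstream"] = (gene.tx_start - flank, gene.tx_start)
        iv["downstream"] = (gene.tx_end, gene.tx_end + flank)
        iv["first_exon"] = exons[0]
        if len(exons) >= 2:
            iv["first_intron"] = (exons[0][1], exons[1][0])
            iv["last_exon"] = exons[-1]
            iv["internal_body"] = (exons[1][0], exons[-1][0])
    else:
        iv["upstream"] = (gene.tx_end, gene.tx_end + flank)
        iv["downstream"] = (gene.tx_start - flank, gene.tx_start)
        iv["first_exon"] = exons[-1]
        if len(exons) >= 2:
            iv["first_intron"] = (exons[-2][1], exons[-1][0])
            iv["last_exon"] = exons[0]
            iv["internal_body"] = (exons[0][1], exons[-2][1])
    return {k: v for k, v in iv.items() if v[1] > v[0]}


def metagene_profile(
    calls: pd.DataFrame,
    genes,
    flank: int = 2000,
    context: str = "CG",
) -> pd.DataFrame:
    """Mean methylation per functional element across all genes.

    Each covered CG site of a transcriptional unit (plus flanks) is
    assigned to exactly one element of its gene; assignment is
    strand-aware (upstream = 5' of the TSS on the gene's strand, and a
    site exactly at the TSS belongs to the first exon). Returns a frame
    with columns element, mean_level, n_sites in fixed element order.
    """
    sums = {el: 0.0 for el in METAGENE_ELEMENTS}
    counts = {el: 0 for el in METAGENE_ELEMENTS}
    cg = calls[(calls["context"] == context) & calls["level"].notna()]
    by_contig = {c: g.sort_values("pos") for c, g in cg.groupby("contig")}
    for gene in genes:
        sub = by_contig.get(gene.contig)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lvl = sub["level"].to_numpy()
        for element, (s, e) in _element_intervals(gene, flank).items():
            lo, hi = np.searchsorted(pos, [s, e])
            if hi > lo:
                sums[element] += float(lvl[lo:hi].sum())
                counts[element] += int(hi - lo)
    return pd.DataFrame(
        {
            "element": METAGENE_ELEMENTS,
            "mean_level": [
                sums[el] / counts[el] if counts[el] else float("nan")
                for el in METAGENE_ELEMENTS
            ],
            "n_sites": [counts[el] for el in METAGENE_ELEMENTS],
        }
    )


def plot_heatmap(hm: DensityHeatmap, path) -> None:
    """Render a density heatmap with its median line (matplotlib, Agg)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if hm.n_sites:
        ax.imshow(
            hm.cell_counts.T,
            origin="lower",
            aspect="auto",
            cmap="Reds",
            extent=(-0.5, len(hm.x_densities) - 0.5, 0.0, 1.0),
        )
        ax.plot(hm.x_densities, hm.median_line, color="black", lw=1)
    ax.set_xlabel("CG dinucleotides per 200 bp window")
    ax.set_ylabel("methylation level")
    ax.set_title(f"{hm.feature_label} (n={hm.n_sites})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
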