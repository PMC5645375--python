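"""Methylome-transcriptome integration and marker filtering.

Classifies expression changes from a DEG table, derives per-gene
methylation-change direction between two called libraries, cross-tabulates
the two, applies the marker-gene filters (log2FC >= 1, P <= 0.05 against a
human-ICC-evidence reference list), flags hypomethylated markers, and
summarises cohort tumor incidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .calling import region_level

logger = logging.getLogger(__name__)

METH_ROWS = ["meth_up", "meth_down"]
EXPR_COLS = ["expr_up", "expr_down", "expr_unchanged"]

#: Named DEG-threshold presets: the scatter-plot pair (FDR <= 0.001) is the
#: default; the methods pair relaxes FDR to 0.01 but also requires p <= 0.01.
DEG_PRESETS = {
    "figure": {"min_abs_log2fc": 1.0, "max_fdr": 0.001, "max_p": None},
    "methods": {"min_abs_log2fc": 1.0, "max_fdr": 0.01, "max_p": 0.01},
}


@dataclass
class IntegrationTable:
    """2x3 cross-tabulation of methylation direction x expression status."""

    table: pd.DataFrame  # index METH_ROWS, columns EXPR_COLS
    n_meth_unchanged: int
    n_unjoined: int
    n_unclassifiable: int

    def to_dict(self) -> dict:
        return {
            "table": {r: {c: int(self.table.loc[r, c]) for c in EXPR_COLS} for r in METH_ROWS},
            "n_meth_unchanged": self.n_meth_unchanged,
            "n_unjoined": self.n_unjoined,
            "n_unclassifiable": self.n_unclassifiable,
        }


def classify_deg(
    log2fc: float,
    fdr: float,
    p_value: float | None = None,
    min_abs_log2fc: float = 1.0,
    max_fdr: float = 0.001,
    max_p: float | None = None,
) -> str:
    """Expression status: up / down / unchanged (thresholds inclusive).

    A record with a missing fdr (or missing p when a p threshold is set)
    is 'unclassifiable'.
    """
    if fdr is None or (isinstance(fdr, float) and np.isnan(fdr)):
        return "unclassifiable"
    passes = fdr <= max_fdr
    if max_p is not None:
        if p_value is None or (isinstance(p_value, float) and np.isnan(p_value)):
            return "unclassifiable"
        passes = passes and p_value <= max_p
    if passes and log2fc >= min_abs_log2fc:
        return "up"
    if passes and log2fc <= -min_abs_log2fc:
        return "down"
    return "unchanged"


def classify_deg_table(deg: pd.DataFrame, preset: str = "figure", **overrides) -> pd.DataFrame:
    """Add a ``status`` column to a DEG table using a named preset."""
    params = dict(DEG_PRESETS[preset], **overrides)
    out = deg.copy()
    out["status"] = [
        classify_deg(
            row.log2fc, row.fdr,
            p_value=getattr(row, "pvalue", None), **params,
        )
        for row in out.itertuples()
    ]
    return out


def gene_methylation_direction(
    calls_wt: pd.DataFrame,
    calls_tumor: pd.DataFrame,
    gene_regions: pd.DataFrame,
    min_abs_delta: float = 0.1,
    context: str = "CG",
) -> tuple[pd.DataFrame, int]:
    """Per-gene methylation-change direction between two libraries.

    ``gene_regions`` needs columns gene_id, contig, start, end (the
    gene-body span by default convention). The region level (unweighted
    CpG mean) is computed per library; direction is up/down when the
    tumor-minus-WT delta reaches ``min_abs_delta`` in magnitude. Genes
    with an undefined level in either library are dropped; their count is
    returned alongside the frame.
    """
    rows = []
    n_excluded = 0
    for row in gene_regions.itertuples():
        lv_wt = region_level(calls_wt, row.contig, row.start, row.end, context=context)
        lv_tu = region_level(calls_tumor, row.contig, row.start, row.end, context=context)
        if np.isnan(lv_wt) or np.isnan(lv_tu):
            n_excluded += 1
            continue
        delta = lv_tu - lv_wt
        if delta >= min_abs_delta:
            direction = "up"
        elif delta <= -min_abs_delta:
            direction = "down"
        else:
            direction = "unchanged"
        rows.append((row.gene_id, lv_wt, lv_tu, delta, direction))
    df = pd.DataFrame(
        rows, columns=["gene_id", "level_wt", "level_tumor", "delta", "direction"]
    )
    return df, n_excluded


def cross_tabulate(deltas: pd.DataFrame, deg: pd.DataFrame) -> IntegrationTable:
    """Count genes by (methylation direction) x (expression status).

    Only genes with methylation direction up or down populate the table
    (mirroring the two-row presentation of such comparisons); joins are
    inner on gene_id, with unmatched and unclassifiable genes counted.
    Duplicate gene ids in either input are rejected.
    """
    for name, df in (("deltas", deltas), ("deg", deg)):
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        if dup:
            raise ValueError(f"duplicate gene_id in {name}: {sorted(set(dup))}")
    if "status" not in deg.columns:
        deg = classify_deg_table(deg)
    joined = deltas.merge(deg[["gene_id", "status"]], on="gene_id", how="left")
    unjoined = joined["status"].isna()
    n_unjoined = int(unjoined.sum())
    joined = joined[~unjoined]
    unclass = joined["status"] == "unclassifiable"
    n_unclassifiable = int(unclass.sum())
    joined = joined[~unclass]
    n_meth_unchanged = int((joined["direction"] == "unchanged").sum())
    table = pd.DataFrame(0, index=METH_ROWS, columns=EXPR_COLS, dtype=int)
    for direction, row in (("up", "meth_up"), ("down", "meth_down")):
        sub = joined[joined["direction"] == direction]
        for status, col in (("up", "expr_up"), ("down", "expr_down"), ("unchanged", "expr_unchanged")):
            table.loc[row, col] = int((sub["status"] == status).sum())
    return IntegrationTable(table, n_meth_unchanged, n_unjoined, n_unclassifiable)


def filter_marker_genes(
    deg_table: pd.DataFrame,
    marker_reference: pd.DataFrame,
    min_log2fc: float = 1.0,
    max_p: float = 0.05,
) -> pd.DataFrame:
    """Candidate markers passing log2FC >= min and p <= max, intersected
    with the human-evidence reference list (flags carried through)."""
    if marker_reference.empty:
        logger.warning("empty marker reference: no candidate markers to screen")
        return pd.DataFrame(
            columns=["gene_id", "log2fc", "pvalue", "human_mutated_flag", "human_expressed_flag"]
        )
    ref = marker_reference.rename(columns={"symbol": "gene_id"})
    merged = deg_table.merge(ref, on="gene_id", how="inner")
    keep = (merged["log2fc"] >= min_log2fc) & (merged["pvalue"] <= max_p)
    cols = ["gene_id", "log2fc", "pvalue", "human_mutated_flag", "human_expressed_flag"]
    return merged.loc[keep, cols].reset_index(drop=True)


def hypomethylated_markers(
    markers: pd.DataFrame, deltas: pd.DataFrame | None
) -> pd.DataFrame:
    """Subset of markers whose gene methylation direction is down."""
    out = markers.copy()
    if deltas is None or len(deltas) == 0:
        out["hypomethylated"] = False
        return out[out["hypomethylated"]]
    down = set(deltas.loc[deltas["direction"] == "down", "gene_id"])
    out["hypomethylated"] = out["gene_id"].isin(down)
    return out[out["hypomethylated"]].reset_index(drop=True)


def incidence_percentage(tumor_count: int, total_count: int, decimals: int = 1) -> tuple[float, str]:
    """Tumor incidence as a percentage, rounded half-up.

    Returns (value, formatted) where the formatted string drops a
    trailing '.0' (86.0% prints as '86').
    """
    if total_count < 1:
        raise ValueError(f"total_count must be >= 1, got {total_count}")
    if not 0 <= tumor_count <= total_count:
        raise ValueError(f"tumor_count {tumor_count} outside [0, {total_count}]")
    q = Decimal(10) ** -decimals
    pct = (Decimal(tumor_count) * 100 / Decimal(total_count)).quantize(q, rounding=ROUND_HALF_UP)
    if pct == pct.to_integral_value():
        return float(pct), str(int(pct))
    return float(pct), str(pct.normalize())


def incidence_summary(cohorts: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Per-timepoint tumor percentages from (label, tumor_count, total_count)."""
    rows = []
    for row in cohorts.itertuples():
        value, formatted = incidence_percentage(row.tumor_count, row.total_count, decimals)
        rows.append((row.label, row.tumor_count, row.total_count, value, formatted))
    return pd.DataFrame(
        rows, columns=["label", "tumor_count", "total_count", "percentage", "formatted"]
    )
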