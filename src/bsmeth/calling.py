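"""Methylation calling with spike-in error calibration.

The library-wide bisulfite error rate (non-conversion plus T/C sequencing
error) is estimated from the unmethylated lambda spike-in as total C
observations over total depth at lambda cytosines. Each covered cytosine
is then tested against Binomial(n, error_rate) with a one-sided upper-tail
exact test; Benjamini-Hochberg q-values below the threshold (default 0.01)
define methylated cytosines. Site levels are C/(C+T) and are reported only
at per-strand depth >= 4; region levels are unweighted means over covered
CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

CALL_COLUMNS = [
    "contig", "pos", "strand", "context", "depth", "meth_count",
    "level", "p_value", "q_value", "is_methylated",
]


@dataclass(frozen=True)
class ConversionControl:
    """Library-wide bisulfite error rate from the unmethylated spike-in."""

    library_id: str
    error_rate: float
    total_c_observed: int
    total_depth: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"error_rate must be in [0,1), got {self.error_rate}")


def estimate_error_rate(
    pileup: pd.DataFrame, control_contig: str, library_id: str = "library"
) -> ConversionControl:
    """Total C observations / total depth over all control-contig cytosines."""
    sub = pileup[pileup["contig"] == control_contig]
    total_c = int(sub["meth_count"].sum())
    total_depth = int((sub["meth_count"] + sub["unmeth_count"]).sum())
    if total_depth == 0:
        raise ValueError(
            f"control contig {control_contig!r} has zero covered cytosines; "
            "cannot estimate the bisulfite error rate"
        )
    return ConversionControl(library_id, total_c / total_depth, total_c, total_depth)


def binomial_site_test(meth_count, depth, error_rate: float):
    """Exact one-sided upper-tail p-value P(X >= k), X ~ Binomial(n, e).

    Accepts scalars or arrays; k > n raises.
    """
    k = np.asarray(meth_count)
    n = np.asarray(depth)
    if np.any(k < 0) or np.any(n < 1):
        raise ValueError("need 0 <= meth_count and depth >= 1")
    if np.any(k > n):
        raise ValueError("meth_count exceeds depth")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate must be in [0,1), got {error_rate}")
    p = binom.sf(k - 1, n, error_rate)
    return float(p) if np.isscalar(meth_count) else p


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, aligned to the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def site_level(meth_count: int, depth: int) -> float:
    """Methylation level C/(C+T); undefined (NaN) at zero depth."""
    if depth < 1:
        return float("nan")
    return meth_count / depth


def call_methylation(
    pileup: pd.DataFrame,
    control: ConversionControl,
    q_threshold: float = 0.01,
    min_level_depth: int = 4,
    control_contig: str | None = None,
    per_context_fdr: bool = False,
) -> pd.DataFrame:
    """Per-site binomial test, BH adjustment and level estimation.

    Every cytosine with depth >= 1 is tested; the BH adjustment pools all
    tested sites of the library (all contexts) unless ``per_context_fdr``.
    ``is_methylated`` means q < q_threshold. Levels are defined only at
    per-strand depth >= ``min_level_depth``. Control-contig sites are
    excluded from the call set when ``control_contig`` is given.
    """
    df = pileup.copy()
    if control_contig is not None:
        df = df[df["contig"] != control_contig].copy()
    df["depth"] = df["meth_count"] + df["unmeth_count"]
    df["level"] = np.where(
        df["depth"] >= min_level_depth, df["meth_count"] / df["depth"].replace(0, np.nan), np.nan
    )
    df["p_value"] = np.nan
    df["q_value"] = np.nan
    tested = df["depth"] >= 1
    if tested.any():
        p = binomial_site_test(
            df.loc[tested, "meth_count"].to_numpy(),
            df.loc[tested, "depth"].to_numpy(),
            control.error_rate,
        )
        df.loc[tested, "p_value"] = p
        if per_context_fdr:
            q = np.empty_like(p)
            ctx = df.loc[tested, "context"].to_numpy()
            for c in np.unique(ctx):
                m = ctx == c
                q[m] = adjust_fdr(p[m])
        else:
            q = adjust_fdr(p)
        df.loc[tested, "q_value"] = q
    df["is_methylated"] = (df["q_value"] < q_threshold).fillna(False).astype(bool)
    df = df.sort_values(["contig", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    return df[CALL_COLUMNS]


def region_level(
    calls: pd.DataFrame,
    contig: str,
    start: int,
    end: int,
    strand: str | None = None,
    context: str = "CG",
) -> float:
    """Unweighted mean of defined site levels of CpGs in [start, end).

    Per the region formula, every covered CpG contributes equally
    regardless of its depth. NaN when no covered CpG falls in the region.
    """
    if end <= start:
        raise ValueError(f"empty region [{start},{end})")
    sub = calls[
        (calls["contig"] == contig)
        & (calls["pos"] >= start)
        & (calls["pos"] < end)
        & (calls["context"] == context)
    ]
    if strand is not None:
        sub = sub[sub["strand"] == strand]
    levels = sub["level"].dropna()
    if levels.empty:
        return float("nan")
    return float(levels.mean())
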