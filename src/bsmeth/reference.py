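"""Bundled study-design reference tables.

The zebrafish nras(61K) intrahepatic-cholangiocarcinoma study design that
this toolkit emulates reports three small printed tables that serve as
inputs to the integration stage: the eleven candidate ICC marker genes
conserved with human (with their expression log2 fold changes, p-values
and human-evidence flags), the CG-hypomethylation flags for three of them
(ehf, epha4, itgb6), and cohort tumor-incidence counts by age in months
post fertilization. They are typed here verbatim as plain literals.
"""

from __future__ import annotations

import pandas as pd

# ensembl_id, symbol, log2fc, pvalue, qpcr_log2fc, human_mutated, human_expressed, cg_down
_MARKERS = [
    ("ENSDARG00000070480", "agr2", 3.89, 3.28e-20, 4.20, False, True, False),
    ("ENSDARG00000087841", "ece2", 3.36, 1.21e-13, 4.23, True, False, False),
    ("ENSDARG00000052115", "ehf", 2.16, 1.30e-08, 1.80, False, True, True),
    ("ENSDARG00000040534", "epcam", 2.51, 3.63e-58, 2.08, False, True, False),
    ("ENSDARG00000011600", "epha4", 3.62, 2.44e-25, 5.07, True, False, True),
    ("ENSDARG00000077296", "eps8l3", 2.18, 1.40e-25, 3.40, False, True, False),
    ("ENSDARG00000002494", "itgb6", 2.78, 1.41e-08, 2.47, False, True, True),
    ("ENSDARG00000017127", "pdzk1ip1", 1.75, 9.51e-34, 1.12, False, True, False),
    ("ENSDARG00000102381", "slc44a4", 4.75, 8.07e-08, 3.26, False, True, False),
    ("ENSDARG00000029866", "slc6a", 3.65, 4.81e-42, 2.85, False, True, False),
    ("ENSDARG00000069476", "spint2", 1.98, 4.05e-91, 1.18, False, True, False),
]

# (age label, tumor_count, total_count)
_COHORTS = [
    ("3 mpf", 0, 103),
    ("6 mpf", 0, 85),
    ("9 mpf", 43, 64),
    ("12 mpf", 53, 65),
    ("24 mpf", 43, 50),
]


def marker_table() -> pd.DataFrame:
    """Full marker table: ids, expression statistics and evidence flags."""
    return pd.DataFrame(
        _MARKERS,
        columns=[
            "ensembl_id", "symbol", "log2fc", "pvalue", "qpcr_log2fc",
            "human_mutated_flag", "human_expressed_flag", "cg_down",
        ],
    )


def marker_reference() -> pd.DataFrame:
    """Candidate-symbol reference with human-evidence flags (filter input)."""
    return marker_table()[["symbol", "human_mutated_flag", "human_expressed_flag"]].copy()


def marker_expression() -> pd.DataFrame:
    """Marker expression statistics shaped like a DEG table slice."""
    df = marker_table()[["symbol", "log2fc", "pvalue"]].rename(columns={"symbol": "gene_id"})
    return df


def hypomethylation_directions() -> pd.DataFrame:
    """Per-marker CG methylation direction implied by the CG-down flags."""
    tab = marker_table()
    return pd.DataFrame(
        {
            "gene_id": tab["symbol"],
            "direction": ["down" if f else "unchanged" for f in tab["cg_down"]],
        }
    )


def tumor_incidence() -> pd.DataFrame:
    """Cohort tumor counts by age (months post fertilization)."""
    return pd.DataFrame(_COHORTS, columns=["label", "tumor_count", "total_count"])
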