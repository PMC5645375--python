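"""File I/O: FASTA/FASTQ via Biopython, BED/TSV/JSON via pandas and json.

Positions are 0-based half-open in memory; the cytosine-report and call
TSVs are written 1-based (column ``pos1``) as is conventional for
per-cytosine reports, and converted back on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .qc import Read
from .simulate import GeneModel, Genome, RepeatAnnotation

PILEUP_TSV_COLUMNS = [
    "contig", "pos1", "strand", "meth_count", "unmeth_count",
    "context", "trinucleotide", "other_count",
]
CALL_TSV_COLUMNS = [
    "contig", "pos1", "strand", "context", "depth", "meth_count",
    "level", "p_value", "q_value", "is_methylated",
]


def write_fasta(genome: Genome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, control_contig: str | None = None) -> Genome:
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if control_contig is None and "lambda_control" in contigs:
        control_contig = "lambda_control"
    return Genome(contigs, control_contig=control_contig)


def write_fastq(reads: list[Read], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq_with_truth(fastq_path, truth_path) -> list[Read]:
    """Reconstruct position-annotated reads from FASTQ plus the truth table."""
    truth = read_tsv(truth_path).set_index("read_id")
    reads = []
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        row = truth.loc[rec.id]
        reads.append(
            Read(
                rec.id,
                str(row["contig"]),
                int(row["start"]),
                str(row["strand"]),
                str(rec.seq),
                np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16),
            )
        )
    return reads


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pileup_tsv(pileup: pd.DataFrame, path) -> None:
    out = pileup.copy()
    out["pos1"] = out["pos"] + 1
    out[PILEUP_TSV_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos1"] - 1
    return df.drop(columns=["pos1"])


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    out = calls.copy()
    out["pos1"] = out["pos"] + 1
    out[CALL_TSV_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos1"] - 1
    return df.drop(columns=["pos1"])


def write_genes_bed(genes: list[GeneModel], path) -> None:
    rows = [
        (g.contig, g.tx_start, g.tx_end, g.gene_id, 0, g.strand) for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_exons_bed(genes: list[GeneModel], path) -> None:
    rows = [
        (g.contig, s, e, g.gene_id, 0, g.strand)
        for g in genes
        for s, e in g.exons
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_repeats_bed(repeats: list[RepeatAnnotation], path) -> None:
    rows = [(r.contig, r.start, r.end, r.family) for r in repeats]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    names = ["contig", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    return df


def write_gene_table(genes: list[GeneModel], path) -> None:
    rows = [
        (
            g.gene_id, g.contig, g.strand, g.tx_start, g.tx_end, g.biotype,
            ",".join(f"{s}-{e}" for s, e in g.exons),
        )
        for g in genes
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "contig", "strand", "tx_start", "tx_end", "biotype", "exons"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    genes = []
    for row in df.itertuples():
        exons = [
            (int(s), int(e))
            for s, e in (pair.split("-") for pair in str(row.exons).split(","))
        ]
        genes.append(
            GeneModel(
                row.gene_id, row.contig, row.strand,
                int(row.tx_start), int(row.tx_end), exons, row.biotype,
            )
        )
    return genes


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
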