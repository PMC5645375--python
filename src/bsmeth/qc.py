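"""Read-level quality control and strand-specific cytosine pileups.

Implements the pre-calling filters of a WGBS pipeline -- adaptor screening,
N-content and low-quality-read removal, PCR-duplicate collapsing, per-base
quality masking -- and builds per-cytosine C/T counts with CpG/CHG/CHH
context labels on both strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# context codes used in the vectorised arrays
CTX_NONE, CTX_CG, CTX_CHG, CTX_CHH = 0, 1, 2, 3
CONTEXT_NAMES = {CTX_CG: "CG", CTX_CHG: "CHG", CTX_CHH: "CHH"}

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")

_COMPLEMENT = np.full(256, _N, dtype=np.uint8)
for _x, _y in ((_A, _T), (_T, _A), (_C, _G), (_G, _C), (_N, _N)):
    _COMPLEMENT[_x] = _y

PILEUP_COLUMNS = [
    "contig", "pos", "strand", "context", "trinucleotide",
    "meth_count", "unmeth_count", "other_count",
]


@dataclass(slots=True)
class Read:
    """A position-annotated sequencing read (alignment assumed known)."""

    read_id: str
    contig: str
    start: int  # 0-based leftmost genomic position covered
    strand: str  # '+' or '-'
    sequence: str  # physical read sequence, 5'->3' on its strand
    qualities: np.ndarray  # Phred scores, same length as sequence

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} != "
                f"qualities length {len(self.qualities)}"
            )

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.qualities))


def seq_to_codes(seq: str) -> np.ndarray:
    """Nucleotide string to uint8 ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def codes_to_seq(codes: np.ndarray) -> str:
    return codes.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return codes_to_seq(_COMPLEMENT[seq_to_codes(seq)][::-1])


def context_arrays(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-position context codes for both strands of a contig.

    Returns (plus, minus) uint8 arrays of length len(seq): 0 where the
    strand's base is not C, else CG/CHG/CHH codes. Positions with
    insufficient flanking sequence follow the N->H convention (a missing
    or N base never completes a CG or CHG).
    """
    codes = seq_to_codes(seq)
    n = len(codes)
    plus = np.zeros(n, dtype=np.uint8)
    minus = np.zeros(n, dtype=np.uint8)
    if n == 0:
        return plus, minus

    nxt1 = np.full(n, _N, dtype=np.uint8)
    nxt2 = np.full(n, _N, dtype=np.uint8)
    if n >= 2:
        nxt1[:-1] = codes[1:]
    if n >= 3:
        nxt2[:-2] = codes[2:]
    is_c = codes == _C
    plus[is_c & (nxt1 == _G)] = CTX_CG
    plus[is_c & (nxt1 != _G) & (nxt2 == _G)] = CTX_CHG
    plus[is_c & (plus == CTX_NONE)] = CTX_CHH

    # minus-strand cytosines sit at plus-strand G; their downstream bases are
    # the complements of the preceding plus-strand bases.
    prv1 = np.full(n, _N, dtype=np.uint8)
    prv2 = np.full(n, _N, dtype=np.uint8)
    if n >= 2:
        prv1[1:] = codes[:-1]
    if n >= 3:
        prv2[2:] = codes[:-2]
    is_g = codes == _G
    minus[is_g & (prv1 == _C)] = CTX_CG
    minus[is_g & (prv1 != _C) & (prv2 == _C)] = CTX_CHG
    minus[is_g & (minus == CTX_NONE)] = CTX_CHH
    return plus, minus


def classify_context(genome, contig: str, position: int, strand: str) -> str:
    """Context (CG/CHG/CHH) of a single strand-specific cytosine.

    Raises ValueError when the reference base on that strand is not C.
    """
    seq = genome.contigs[contig] if hasattr(genome, "contigs") else genome[contig]
    base = seq[position]
    ref_on_strand = base if strand == "+" else revcomp(base)
    if ref_on_strand != "C":
        raise ValueError(
            f"reference base at {contig}:{position}({strand}) is "
            f"{ref_on_strand}, not C"
        )
    plus, minus = context_arrays(seq)
    code = plus[position] if strand == "+" else minus[position]
    return CONTEXT_NAMES[int(code)]


def trinucleotide(seq: str, position: int, strand: str) -> str:
    """3-mer starting at the cytosine, read 5'->3' on the cytosine's strand."""
    n = len(seq)
    if strand == "+":
        tri = seq[position : min(position + 3, n)]
        return (tri + "NN")[:3]
    lo = max(position - 2, 0)
    tri = revcomp(seq[lo : position + 1])
    return (tri + "NN")[:3]


def filter_reads(
    reads: list[Read],
    adaptor: str = "",
    max_n_fraction: float = 0.10,
    low_q_threshold: int = 5,
    low_q_fraction: float = 0.50,
) -> tuple[list[Read], dict[str, int]]:
    """Apply the read-level filters; thresholds are strict inequalities.

    A read is removed when it (a) contains the adaptor as an exact
    substring, (b) has more than ``max_n_fraction`` unknown bases, or
    (c) has more than ``low_q_fraction`` of its bases at Phred <=
    ``low_q_threshold``. Equality keeps the read. Returns the kept reads
    and per-rule removal counts.
    """
    if not 0.0 <= max_n_fraction <= 1.0:
        raise ValueError(f"max_n_fraction must be in [0,1], got {max_n_fraction}")
    if not 0.0 <= low_q_fraction <= 1.0:
        raise ValueError(f"low_q_fraction must be in [0,1], got {low_q_fraction}")
    if not adaptor:
        logger.info("empty adaptor sequence: adaptor filter disabled")
    kept: list[Read] = []
    counts = {"adaptor": 0, "n_fraction": 0, "low_quality": 0, "kept": 0}
    for read in reads:
        n = len(read.sequence)
        if adaptor and adaptor in read.sequence:
            counts["adaptor"] += 1
            continue
        if n and read.sequence.count("N") > max_n_fraction * n:
            counts["n_fraction"] += 1
            continue
        if n and int(np.count_nonzero(read.qualities <= low_q_threshold)) > low_q_fraction * n:
            counts["low_quality"] += 1
            continue
        kept.append(read)
    counts["kept"] = len(kept)
    return kept, counts


def remove_duplicates(reads: list[Read]) -> list[Read]:
    """Collapse PCR duplicates: one read per (contig, start, strand).

    The retained read is the one with the highest mean base quality; ties
    break on lexicographically smallest read_id. Output is position-sorted,
    so the result is deterministic regardless of input order.
    """
    best: dict[tuple[str, int, str], Read] = {}
    for read in reads:
        key = (read.contig, read.start, read.strand)
        cur = best.get(key)
        if cur is None:
            best[key] = read
            continue
        mq_new, mq_cur = read.mean_quality, cur.mean_quality
        if mq_new > mq_cur or (mq_new == mq_cur and read.read_id < cur.read_id):
            best[key] = read
    return sorted(best.values(), key=lambda r: (r.contig, r.start, r.strand, r.read_id))


def mask_low_quality(read: Read, min_q: int = 20) -> np.ndarray:
    """Boolean mask of bases usable for methylation counting (Phred >= min_q).

    Masked bases are not discarded from the read; the pileup counts them
    under ``other_count`` instead of depth.
    """
    return np.asarray(read.qualities) >= min_q


def build_pileup(
    reads: list[Read],
    genome,
    min_base_quality: int = 20,
) -> pd.DataFrame:
    """Strand-specific per-cytosine counts over the whole genome.

    Plus-strand cytosines are counted only from plus-strand reads and vice
    versa. For each site, ``meth_count`` is the number of usable C
    observations, ``unmeth_count`` usable T observations, and
    ``other_count`` everything else (masked bases included). All cytosines
    are emitted, zero-depth sites included. Reads extending past their
    contig are rejected and counted in ``df.attrs['stats']``.
    """
    contigs = genome.contigs if hasattr(genome, "contigs") else genome
    counts: dict[tuple[str, str], np.ndarray] = {}
    for name, seq in contigs.items():
        n = len(seq)
        for strand in "+-":
            counts[(name, strand)] = np.zeros((3, n), dtype=np.int64)  # meth, unmeth, other

    stats = {"reads_used": 0, "reads_rejected_out_of_bounds": 0}

    # group reads so each group shares contig, strand and length -> one matrix op
    groups: dict[tuple[str, str, int], list[Read]] = {}
    for read in reads:
        seq = contigs.get(read.contig)
        if seq is None or read.start < 0 or read.start + len(read.sequence) > len(seq):
            stats["reads_rejected_out_of_bounds"] += 1
            continue
        groups.setdefault((read.contig, read.strand, len(read.sequence)), []).append(read)
        stats["reads_used"] += 1

    for (contig, strand, rlen), grp in groups.items():
        if rlen == 0:
            continue
        starts = np.array([r.start for r in grp], dtype=np.int64)
        seqmat = np.frombuffer(
            "".join(r.sequence for r in grp).encode("ascii"), dtype=np.uint8
        ).reshape(len(grp), rlen)
        qualmat = np.vstack([np.asarray(r.qualities, dtype=np.int16) for r in grp])
        if strand == "-":
            # reorient to ascending genome coordinates; bases stay minus-strand
            seqmat = seqmat[:, ::-1]
            qualmat = qualmat[:, ::-1]
        pos = starts[:, None] + np.arange(rlen, dtype=np.int64)[None, :]
        usable = qualmat >= min_base_quality
        arr = counts[(contig, strand)]
        meth = usable & (seqmat == _C)
        unmeth = usable & (seqmat == _T)
        other = ~(meth | unmeth)
        np.add.at(arr[0], pos[meth], 1)
        np.add.at(arr[1], pos[unmeth], 1)
        np.add.at(arr[2], pos[other], 1)

    frames = []
    for name, seq in contigs.items():
        ctx_plus, ctx_minus = context_arrays(seq)
        for strand, ctx in (("+", ctx_plus), ("-", ctx_minus)):
            sites = np.nonzero(ctx)[0]
            if sites.size == 0:
                continue
            arr = counts[(name, strand)]
            tri = [trinucleotide(seq, int(p), strand) for p in sites]
            frames.append(
                pd.DataFrame(
                    {
                        "contig": name,
                        "pos": sites,
                        "strand": strand,
                        "context": [CONTEXT_NAMES[int(c)] for c in ctx[sites]],
                        "trinucleotide": tri,
                        "meth_count": arr[0, sites],
                        "unmeth_count": arr[1, sites],
                        "other_count": arr[2, sites],
                    }
                )
            )
    if frames:
        df = pd.concat(frames, ignore_index=True)
        df = df.sort_values(["contig", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=PILEUP_COLUMNS)
    if stats["reads_rejected_out_of_bounds"]:
        logger.warning(
            "%d reads rejected (extend past contig end or unknown contig)",
            stats["reads_rejected_out_of_bounds"],
        )
    df.attrs["stats"] = stats
    return df
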