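"""Synthetic WGBS study generator.

Generates a toy genome with gene/repeat annotations and CpG-island-like
promoters, a ground-truth methylome with bimodal CG methylation and
near-zero non-CG methylation, bisulfite reads carrying conversion failures
and sequencing errors (plus an unmethylated lambda spike-in), per-cytosine
count reports, and differential-expression tables with embedded marker
genes. Every output is deterministic given the configuration seed, and
ground-truth tables are emitted for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BetaMixture, SimConfig
from .qc import (
    CTX_CG,
    CONTEXT_NAMES,
    Read,
    _COMPLEMENT,
    codes_to_seq,
    context_arrays,
    seq_to_codes,
    trinucleotide,
)

LAMBDA_CONTIG = "lambda_control"
MAIN_CONTIG = "chr1"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_T_CODE = ord("T")
_C_CODE = ord("C")
_N_CODE = ord("N")

# alternatives table for purine miscalls: row indexed by base code
_PURINE_ALTS = {ord("A"): np.frombuffer(b"CGT", dtype=np.uint8),
                ord("G"): np.frombuffer(b"ACT", dtype=np.uint8)}


@dataclass
class Genome:
    """Contig sequences plus the name of the unmethylated control contig."""

    contigs: dict[str, str]
    control_contig: str | None = None

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name} is empty")
            if set(seq) - set("ACGTN"):
                raise ValueError(f"contig {name} has bases outside ACGTN")
        if self.control_contig is not None and self.control_contig not in self.contigs:
            raise ValueError(f"control_contig {self.control_contig} not in contigs")

    def main_contigs(self) -> dict[str, str]:
        return {k: v for k, v in self.contigs.items() if k != self.control_contig}


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < prev_end or e > self.tx_end or s >= e:
                raise ValueError(f"{self.gene_id}: malformed exon ({s},{e})")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start coordinate (strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass
class RepeatAnnotation:
    contig: str
    start: int
    end: int
    family: str


@dataclass
class Methylome:
    """True methylation probability for every strand-specific cytosine.

    ``levels[(contig, strand)]`` is a float array over contig positions,
    NaN where the strand's base is not a cytosine; ``contexts`` holds the
    matching CG/CHG/CHH codes (0 at non-cytosines).
    """

    levels: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    contexts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def copy(self) -> "Methylome":
        return Methylome(
            {k: v.copy() for k, v in self.levels.items()},
            {k: v.copy() for k, v in self.contexts.items()},
        )

    def site_levels(self, context: str | None = None) -> np.ndarray:
        """Flat array of true levels, optionally restricted to one context."""
        out = []
        code = {v: k for k, v in CONTEXT_NAMES.items()}.get(context)
        for key, lv in self.levels.items():
            mask = ~np.isnan(lv)
            if code is not None:
                mask &= self.contexts[key] == code
            out.append(lv[mask])
        return np.concatenate(out) if out else np.array([])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (contig, strand), lv in sorted(self.levels.items()):
            sites = np.nonzero(~np.isnan(lv))[0]
            ctx = self.contexts[(contig, strand)]
            rows.append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "pos": sites,
                        "strand": strand,
                        "context": [CONTEXT_NAMES[int(c)] for c in ctx[sites]],
                        "true_level": lv[sites],
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=["contig", "pos", "strand", "context", "true_level"])
        df = pd.concat(rows, ignore_index=True)
        return df.sort_values(["contig", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def _iid_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _island_sequence(rng: np.random.Generator, length: int, gc: float, cpg_boost: float) -> np.ndarray:
    """First-order chain boosting P(G | previous C) to enrich CpG dinucleotides."""
    p_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    p_after_c = p_bg * (1 - cpg_boost) / (1 - p_bg[2])
    p_after_c[2] = cpg_boost + p_bg[2] * (1 - cpg_boost) / (1 - p_bg[2])
    p_after_c /= p_after_c.sum()
    out = np.empty(length, dtype=np.uint8)
    prev_c = False
    u = rng.random(length)
    for i in range(length):
        probs = p_after_c if prev_c else p_bg
        out[i] = _BASES[int(np.searchsorted(np.cumsum(probs), u[i]))]
        prev_c = out[i] == _C_CODE
    return out


def simulate_genome(
    config: SimConfig,
) -> tuple[Genome, list[GeneModel], list[RepeatAnnotation]]:
    """Toy genome: one main contig with genes, repeats, CpG islands at
    transcription starts, plus a fully synthetic unmethylated spike-in contig."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    codes = _iid_sequence(rng, config.genome_length, config.gc_content)

    genes: list[GeneModel] = []
    if config.n_genes > 0:
        slot = config.genome_length // config.n_genes
        for i in range(config.n_genes):
            slot_start = i * slot
            glen = max(30, int(slot * rng.uniform(0.4, 0.7)))
            glen = min(glen, slot - 2)
            tx_start = slot_start + int(rng.integers(0, slot - glen))
            tx_end = tx_start + glen
            n_ex = int(rng.integers(2, 5))
            n_ex = min(n_ex, max(2, glen // 10))
            cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_ex - 2, replace=False))
            bounds = np.concatenate([[0], cuts, [glen]])
            exons = [
                (tx_start + int(bounds[j]), tx_start + int(bounds[j + 1]))
                for j in range(0, 2 * n_ex - 1, 2)
            ]
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = "ncRNA" if rng.random() < 0.15 else "coding"
            genes.append(
                GeneModel(f"gene{i + 1:04d}", MAIN_CONTIG, strand, tx_start, tx_end, exons, biotype)
            )

    # CpG-island-like sequence centred on each TSS
    half = config.island_length // 2
    for gene in genes:
        lo = max(0, gene.tss - half)
        hi = min(config.genome_length, gene.tss + half)
        if hi > lo:
            codes[lo:hi] = _island_sequence(
                rng, hi - lo, config.island_gc_content, config.island_cpg_boost
            )

    repeats: list[RepeatAnnotation] = []
    families = ["DNA", "LINE", "SINE", "LTR"]
    for i in range(config.n_repeats):
        rlen = int(rng.integers(100, 401))
        start = int(rng.integers(0, max(1, config.genome_length - rlen)))
        repeats.append(
            RepeatAnnotation(MAIN_CONTIG, start, start + rlen, families[i % len(families)])
        )

    lam = _iid_sequence(rng, config.lambda_length, 0.5)
    genome = Genome(
        {MAIN_CONTIG: codes_to_seq(codes), LAMBDA_CONTIG: codes_to_seq(lam)},
        control_contig=LAMBDA_CONTIG,
    )
    return genome, genes, repeats


def _draw_mixture(rng: np.random.Generator, mixture: BetaMixture, n: int,
                  components: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Draw n levels; returns (levels, component labels 0=hypo,1=mid,2=hyper)."""
    if components is None:
        components = rng.choice(
            3, size=n, p=[mixture.weight_hypo, mixture.weight_mid, mixture.weight_hyper]
        )
    if mixture.point_mass is not None:
        return np.full(n, float(mixture.point_mass)), components
    levels = np.empty(n)
    for comp, (a, b) in enumerate((mixture.hypo_shape, mixture.mid_shape, mixture.hyper_shape)):
        mask = components == comp
        levels[mask] = rng.beta(a, b, size=int(mask.sum()))
    return levels, components


def simulate_methylome(
    genome: Genome, genes: list[GeneModel], config: SimConfig
) -> Methylome:
    """Ground-truth methylome for every cytosine on both strands.

    CG dyads draw one level per dyad from the beta mixture (symmetric CpG
    pairs identical by default; ``cpg_pair_correlation`` < 1 re-draws the
    minus strand independently with the complementary probability). The
    hypo component's labels are preferentially permuted onto CpG-island
    dyads around transcription starts, so promoters carry the
    hypo-to-hyper transition while the genome-wide component fractions
    remain exactly the configured weights. CHG/CHH sites draw from a
    low-mean beta; every control-contig cytosine is exactly 0.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    meth = Methylome()

    island_windows: dict[str, list[tuple[int, int]]] = {}
    half = config.island_length // 2
    for gene in genes:
        island_windows.setdefault(gene.contig, []).append(
            (max(0, gene.tss - half), gene.tss + half)
        )

    n_cg_total = 0
    for contig, seq in genome.contigs.items():
        codes = seq_to_codes(seq)
        ctx_plus, ctx_minus = context_arrays(seq)
        n = len(codes)
        plus = np.full(n, np.nan)
        minus = np.full(n, np.nan)
        is_control = contig == genome.control_contig

        # CG dyads: plus-strand C at i with G at i+1; minus partner at i+1
        dyads = np.nonzero(ctx_plus == CTX_CG)[0]
        n_cg_total += dyads.size
        if dyads.size and not is_control:
            comps = rng.choice(
                3,
                size=dyads.size,
                p=[
                    config.cg_mixture.weight_hypo,
                    config.cg_mixture.weight_mid,
                    config.cg_mixture.weight_hyper,
                ],
            )
            comps = _assign_hypo_to_islands(
                rng, comps, dyads, island_windows.get(contig, [])
            )
            lv, _ = _draw_mixture(rng, config.cg_mixture, dyads.size, components=comps)
            plus[dyads] = lv
            if config.cpg_pair_correlation >= 1.0:
                minus[dyads + 1] = lv
            else:
                indep, _ = _draw_mixture(rng, config.cg_mixture, dyads.size, components=comps)
                use_pair = rng.random(dyads.size) < config.cpg_pair_correlation
                minus[dyads + 1] = np.where(use_pair, lv, indep)
        elif dyads.size:
            plus[dyads] = 0.0
            minus[dyads + 1] = 0.0

        # non-CG cytosines, each strand independently
        for strand, ctx, arr in (("+", ctx_plus, plus), ("-", ctx_minus, minus)):
            non_cg = np.nonzero((ctx != 0) & (ctx != CTX_CG))[0]
            if non_cg.size:
                if is_control or config.non_cg_mean == 0.0:
                    arr[non_cg] = 0.0
                else:
                    a = 0.1
                    b = a * (1 - config.non_cg_mean) / config.non_cg_mean
                    arr[non_cg] = rng.beta(a, b, size=non_cg.size)
            # minus-strand CG sites not covered by a plus dyad cannot occur:
            # a minus CG at p implies plus C at p-1 followed by G at p.

        if is_control:
            plus[~np.isnan(plus)] = 0.0
            minus[~np.isnan(minus)] = 0.0

        meth.levels[(contig, "+")] = plus
        meth.levels[(contig, "-")] = minus
        meth.contexts[(contig, "+")] = ctx_plus
        meth.contexts[(contig, "-")] = ctx_minus

    if n_cg_total == 0:
        raise ValueError("genome contains no CG site")
    return meth


def _assign_hypo_to_islands(
    rng: np.random.Generator,
    comps: np.ndarray,
    dyads: np.ndarray,
    windows: list[tuple[int, int]],
) -> np.ndarray:
    """Permute component labels so hypo labels land on island dyads first.

    Pure label permutation: the multiset of components (hence the global
    mixture fractions) is unchanged.
    """
    if not windows or comps.size == 0:
        return comps
    island_mask = np.zeros(comps.size, dtype=bool)
    starts = np.array([w[0] for w in windows])
    ends = np.array([w[1] for w in windows])
    for s, e in zip(starts, ends):
        island_mask |= (dyads >= s) & (dyads < e)
    donors = np.nonzero((comps == 0) & ~island_mask)[0]
    receivers = np.nonzero((comps != 0) & island_mask)[0]
    k = min(donors.size, receivers.size)
    if k == 0:
        return comps
    donors = rng.permutation(donors)[:k]
    receivers = rng.permutation(receivers)[:k]
    comps = comps.copy()
    moved = comps[receivers].copy()
    comps[receivers] = 0
    comps[donors] = moved
    return comps


def plant_gene_body_deltas(
    methylome: Methylome,
    genes: list[GeneModel],
    gene_ids: set[str] | list[str],
    delta: float,
    context: str = "CG",
) -> Methylome:
    """Return a copy with gene-body cytosine levels shifted by ``delta``
    (clipped to [0,1]) for the selected genes; used to engineer tumor-vs-WT
    methylation differences with known truth."""
    wanted = set(gene_ids)
    code = {v: k for k, v in CONTEXT_NAMES.items()}[context]
    out = methylome.copy()
    for gene in genes:
        if gene.gene_id not in wanted:
            continue
        for strand in "+-":
            key = (gene.contig, strand)
            lv = out.levels[key]
            ctx = out.contexts[key]
            sl = slice(gene.tx_start, gene.tx_end)
            mask = (ctx[sl] == code) & ~np.isnan(lv[sl])
            lv[sl][mask] = np.clip(lv[sl][mask] + delta, 0.0, 1.0)
    return out


def _apply_conversion_and_errors(
    obs: np.ndarray,
    levels: np.ndarray,
    cf: float,
    err: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bisulfite-convert then miscall a matrix of strand-oriented bases.

    ``obs`` holds the read-strand bases in ascending genome coordinates;
    cytosines are converted to T unless methylated (or unless conversion
    fails). Sequencing errors flip C<->T at pyrimidines and substitute a
    random different base at purines, matching the T/C-confusion error
    mode that the spike-in error-rate formula measures.
    """
    obs = obs.copy()
    cyt = obs == _C_CODE
    if cyt.any():
        methylated = rng.random(obs.shape) < levels
        converted = ~methylated & ~(rng.random(obs.shape) < cf)
        obs[cyt & converted] = _T_CODE
    if err > 0:
        bad = rng.random(obs.shape) < err
        if bad.any():
            is_c = bad & (obs == _C_CODE)
            is_t = bad & (obs == _T_CODE)
            obs[is_c] = _T_CODE
            obs[is_t] = _C_CODE
            for base, alts in _PURINE_ALTS.items():
                m = bad & (obs == base)
                if m.any():
                    obs[m] = alts[rng.integers(0, 3, size=int(m.sum()))]
    return obs


def simulate_bisulfite_reads(
    genome: Genome, methylome: Methylome, config: SimConfig
) -> tuple[list[Read], pd.DataFrame]:
    """Position-sorted single-end bisulfite reads plus a truth table.

    Read counts give ``target_depth`` mean per-strand depth on every
    non-control contig; control-contig reads are added so they make up
    ``lambda_fraction`` of the library. The truth table maps read_id to
    (contig, start, strand). Base qualities are a constant Phred 40.
    """
    config.validate()
    if config.target_depth <= 0:
        raise ValueError(f"target_depth must be positive, got {config.target_depth}")
    rng = np.random.default_rng([config.seed, 2])
    rl = config.read_length

    plan: list[tuple[str, str, int]] = []
    n_main_total = 0
    for contig, seq in genome.main_contigs().items():
        if len(seq) < rl:
            continue
        n = int(round(config.target_depth * len(seq) / rl))
        for strand in "+-":
            plan.append((contig, strand, n))
            n_main_total += n
    if genome.control_contig is not None and config.lambda_fraction > 0:
        n_lam = int(round(config.lambda_fraction / (1 - config.lambda_fraction) * n_main_total))
        plan.append((genome.control_contig, "+", n_lam // 2))
        plan.append((genome.control_contig, "-", n_lam - n_lam // 2))

    reads: list[Read] = []
    truth_rows: list[tuple[str, str, int, str]] = []
    quals = np.full(rl, 40, dtype=np.int16)
    counter = 0
    for contig, strand, n in plan:
        if n <= 0:
            continue
        seq = genome.contigs[contig]
        codes = seq_to_codes(seq)
        if config.paired_end:
            # mates cover the two ends of a fragment_length insert; pairing
            # changes fragment sampling only, not any downstream formula
            frag = min(max(config.fragment_length, rl), len(seq))
            n_frag = max(n // 2, 1)
            frag_starts = rng.integers(0, len(seq) - frag + 1, size=n_frag)
            starts = np.concatenate([frag_starts, frag_starts + frag - rl])
        else:
            starts = rng.integers(0, len(seq) - rl + 1, size=n)
        n = starts.size
        idx = starts[:, None] + np.arange(rl)[None, :]
        ref = codes[idx]
        if strand == "+":
            obs = ref
        else:
            obs = _COMPLEMENT[ref]  # minus-strand bases, ascending genome coords
        lv = methylome.levels[(contig, strand)][idx]
        lv = np.nan_to_num(lv, nan=0.0)
        obs = _apply_conversion_and_errors(
            obs, lv, config.conversion_failure_rate, config.sequencing_error_rate, rng
        )
        if strand == "-":
            obs = obs[:, ::-1]  # physical 5'->3' read on the minus strand
        blob = obs.tobytes()
        for i in range(n):
            rid = f"read{counter:08d}"
            counter += 1
            reads.append(
                Read(rid, contig, int(starts[i]), strand,
                     blob[i * rl : (i + 1) * rl].decode("ascii"), quals)
            )
            truth_rows.append((rid, contig, int(starts[i]), strand))

    reads.sort(key=lambda r: (r.contig, r.start, r.strand, r.read_id))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "contig", "start", "strand"])
    truth = truth.sort_values(
        ["contig", "start", "strand", "read_id"], kind="mergesort"
    ).reset_index(drop=True)
    return reads, truth


def simulate_site_counts(
    methylome: Methylome,
    genome: Genome,
    mean_depth: float,
    conversion_failure_rate: float = 0.004,
    sequencing_error_rate: float = 0.001,
    seed: int = 0,
    fixed_depth: bool = False,
) -> pd.DataFrame:
    """Pre-built per-cytosine count report drawn directly from the truth.

    The read-free counterpart of ``simulate_bisulfite_reads`` +
    ``build_pileup``: per-site depth is Poisson(mean_depth) (or fixed) and
    each covering read shows C with probability
    m(1-e) + (1-m)(cf(1-e) + (1-cf)e), the exact expectation of the
    read-level generative model. Returns the standard pileup frame.
    """
    if mean_depth <= 0:
        raise ValueError(f"mean_depth must be positive, got {mean_depth}")
    rng = np.random.default_rng([seed, 3])
    cf, e = conversion_failure_rate, sequencing_error_rate
    frames = []
    for (contig, strand), lv in sorted(methylome.levels.items()):
        sites = np.nonzero(~np.isnan(lv))[0]
        if sites.size == 0:
            continue
        m = lv[sites]
        ctx = methylome.contexts[(contig, strand)][sites]
        if fixed_depth:
            depth = np.full(sites.size, int(mean_depth))
        else:
            depth = rng.poisson(mean_depth, size=sites.size)
        p_c = m * (1 - e) + (1 - m) * (cf * (1 - e) + (1 - cf) * e)
        meth = rng.binomial(depth, p_c)
        seq = genome.contigs[contig]
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "pos": sites,
                    "strand": strand,
                    "context": [CONTEXT_NAMES[int(c)] for c in ctx],
                    "trinucleotide": [trinucleotide(seq, int(p), strand) for p in sites],
                    "meth_count": meth,
                    "unmeth_count": depth - meth,
                    "other_count": 0,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["contig", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def simulate_deg_table(
    n_genes: int,
    embedded_markers: pd.DataFrame | list[dict] | None = None,
    seed: int = 0,
    null_log2fc_sd: float = 0.5,
) -> pd.DataFrame:
    """Differential-expression table with embedded marker rows.

    Background genes draw null log2 fold changes (mean 0, sd
    ``null_log2fc_sd``) with uniform p-values (BH-adjusted to fdr);
    embedded markers keep exactly the statistics supplied for them. Total
    rows = ``n_genes``. Duplicate gene ids are rejected.
    """
    from statsmodels.stats.multitest import multipletests

    markers = pd.DataFrame(embedded_markers) if embedded_markers is not None else pd.DataFrame()
    if len(markers) > n_genes:
        raise ValueError("more embedded markers than genes")
    if len(markers) and markers["gene_id"].duplicated().any():
        dups = markers.loc[markers["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_id in embedded markers: {dups}")

    rng = np.random.default_rng([seed, 4])
    n_bg = n_genes - len(markers)
    bg_ids = [f"gene{i + 1:05d}" for i in range(n_bg)]
    if len(markers) and set(bg_ids) & set(markers["gene_id"]):
        raise ValueError("embedded marker gene_id collides with background naming")
    log2fc = rng.normal(0.0, null_log2fc_sd, size=n_bg)
    pvals = rng.uniform(size=n_bg)
    fdr = multipletests(pvals, method="fdr_bh")[1] if n_bg else np.array([])
    fpkm_a = rng.lognormal(mean=3.0, sigma=1.0, size=n_bg)
    bg = pd.DataFrame(
        {
            "gene_id": bg_ids,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "fpkm_a": fpkm_a,
            "fpkm_b": fpkm_a * 2.0 ** log2fc,
        }
    )
    if len(markers):
        mk = markers.copy()
        if "fdr" not in mk:
            mk["fdr"] = mk["pvalue"]
        if "fpkm_a" not in mk:
            mk["fpkm_a"] = float(np.exp(3.0))
        if "fpkm_b" not in mk:
            mk["fpkm_b"] = mk["fpkm_a"] * 2.0 ** mk["log2fc"]
        out = pd.concat([mk[bg.columns.tolist()], bg], ignore_index=True)
    else:
        out = bg
    return out.reset_index(drop=True)
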