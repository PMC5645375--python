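# Methods

## Scope and data flow

`bsmeth` implements a whole-genome bisulfite sequencing (WGBS) analysis
chain — read-level QC, PCR-duplicate removal, base-quality masking,
strand-specific cytosine pileups, spike-in error calibration, binomial
methylation calling with FDR control, genome-scale profiling, and
methylome–transcriptome integration — plus a generator that produces
synthetic inputs with known truth. Alignment is out of scope: the
simulator emits each read's true origin (contig, 0-based start, strand)
in a truth table, and the analysis starts from position-annotated reads.
Differential-expression inference is likewise out of scope; DEG tables
are inputs.

## Read-level QC

A read is removed when it contains the adaptor as an exact substring,
when more than 10% of its bases are N, or when more than 50% of its bases
have Phred ≤ 5. All three thresholds are strict inequalities; equality
keeps the read. An empty adaptor disables the adaptor rule (logged).
Reads sharing (contig, start, strand) are treated as PCR duplicates and
collapsed to one; the paper-style key does not disambiguate coincident
distinct molecules, so realized depth falls below the configured target
(≈ 15% loss at 30× with 90 bp reads) — a known, conservative property of
position-based deduplication. The retained duplicate is the one with the
highest mean base quality, ties broken by lexicographic read id; the rule
is arbitrary but deterministic. Bases with Phred < 20 are never discarded
from reads but are excluded from methylation counting (they appear in
`other_count`).

## Contexts and pileups

Context is defined on the cytosine's own strand: CG if the next base is
G; CHG if the next base is not G and the base after next is G; CHH
otherwise. Missing or N flanking bases count as H, so cytosines at contig
ends are CHH/CHG by the N→H convention. On the minus strand the rule is
evaluated on the reverse complement, which reduces to tests on the
*preceding* plus-strand bases; the exhaustive dinucleotide enumeration in
the test suite pins this down. Pileups are strand-separated: plus-strand
cytosines are counted only from plus-strand reads and vice versa. All
cytosines are emitted, zero-depth sites included, so downstream code can
distinguish "untested" from "absent".

## Error calibration and calling

The library error rate e (non-conversion plus T/C sequencing error) is
Σ C-observations / Σ depth over all cytosines of the unmethylated control
contig, both strands pooled. A library without control coverage cannot be
called — this is an error, not a warning. Each site with depth ≥ 1 is
tested with the exact upper tail P(X ≥ k), X ~ Binomial(n, e) (scipy's
`binom.sf`; no normal approximation), one-sided because the only
alternative of interest is an excess of C over what the error rate
explains. Benjamini–Hochberg q-values are computed once across all tested
sites of a library, all contexts pooled (per-context adjustment is an
option); sites with q < 0.01 are called methylated. Site levels k/n are
reported only at per-strand depth ≥ 4, matching the level formula's
denominator (masked bases excluded). Control-contig sites are excluded
from the genome-wide call set and from all profiles. The per-strand
depth ≥ 10 rule is applied by the density heatmap only, not by calling.

Region level is the **unweighted** mean of defined CpG site levels in the
region — a deliberately depth-agnostic estimator per the stated formula;
a depth-weighted pooled mean generally differs and both global modes
(`site_mean`, `pooled`) are reported at genome scale.

## Profiles

Bimodal classification uses strict thresholds: hypo < 0.2, hyper > 0.8,
everything else (including exactly 0.2/0.8) mid. CG density is the number
of CG dinucleotides whose C lies in a 200 bp window; windows tile each
feature from its start (non-overlapping — the simplest reading of
fixed-width windows), and density is computed on the plus strand only
since a CpG is strand-symmetric. The heatmap's y-axis uses 20 equal bins
on [0,1] (level 1.0 falls in the top bin); the median line is the exact
per-density-bin median. The six metagene elements (upstream, first exon,
first intron, internal body, last exon, downstream; flank 2000 bp) are a
documented interpretation of "six functional elements of a
transcriptional unit" and are configurable; element assignment is
strand-aware, partitions each unit, and puts a site exactly at the TSS in
the first exon (half-open intervals). Single-exon genes have only a first
exon and flanks.

## Integration

DEG status defaults to the scatter-plot thresholds (|log2FC| ≥ 1,
FDR ≤ 0.001); the alternative pair (FDR ≤ 0.01 and p ≤ 0.01) is the
`methods` preset. Comparisons are inclusive. Per-gene methylation
direction compares gene-body CpG region levels between libraries
(gene-body rather than promoter because hypomethylated loci in this
design concentrate in gene bodies); |Δ| ≥ 0.1 defines up/down. That 0.1
is a documented default of this package, not a literature constant, and
no validation result depends on its exact value (planted deltas are 0.3).
The cross-tabulation counts only genes with methylation direction up or
down, joins DEG records by gene id, and reports unjoined, unclassifiable
and methylation-unchanged genes separately so the counts always total the
input. Marker screening intersects the DEG table with a reference list of
candidate symbols carrying human-evidence flags and keeps genes with
log2FC ≥ 1 and p ≤ 0.05; hypomethylated markers are those whose direction
is down. Cohort incidence is 100·k/n rounded half-up to one decimal, with
a trailing ".0" suppressed in the formatted string (86.0 → "86"),
mirroring the mixed precision of such summary tables.

## The generator: what it emulates, and what it does not

Defaults describe the emulated study conditions:

| parameter | default | rationale |
|---|---|---|
| read_length | 90 bp | HiSeq-2000-era 90 nt reads |
| conversion_failure_rate | 0.004 | with sequencing error, ≈ 0.5% false-C floor |
| sequencing_error_rate | 0.001 | per-base miscall rate |
| cg_mixture weights | 0.06 hypo / 0.62 hyper | bimodal landscape: ~6% of CG sites < 20%, ~62% > 80% |
| cg_mixture shapes | B(1,30), B(5,5), B(20,1) | sharp components; mixture mean ≈ 0.752 |
| non_cg_mean | 5·10⁻⁴ | true non-CG methylation is near zero; the *observed* level adds the error floor and lands near 0.5% |
| lambda_fraction | 0.10 | spike-in share of the library |
| gc_content | 0.40 | vertebrate-like background |
| fragment_length | 200 bp | nominal library size; no fidelity claim |

Sequencing errors are modelled as C↔T flips at pyrimidines (uniform
substitution at purines). This is the confusion mode the spike-in
error-rate formula actually measures: the expected lambda C-rate is then
cf·(1−e) + (1−cf)·e ≈ 0.005, matching the formula "non-conversion plus
T/C sequencing errors". Symmetric CpG dyads share one true level by
default (`cpg_pair_correlation` = 1.0; strand symmetry is an assumption,
so it is configurable). Component labels for CG dyads are drawn from the
global weights and then *permuted* so that hypo labels land on
CpG-island dyads around transcription starts first: promoters show the
hypo→hyper transition while genome-wide component fractions equal the
configured weights exactly. Lambda cytosines are always exactly 0.

Besides the read-level path (FASTQ + truth table), the generator offers a
pre-built per-cytosine count report: depth ~ Poisson(mean), C-count ~
Binomial(depth, p) with p the exact expectation of the read-level model.
It is used where exact depth control matters.

Not emulated: alignment and mapping error, indels, quality-score
variation along reads (qualities are constant Phred 40), M-bias,
fragment-length variation, strand-biased coverage, CNVs, and biological
replicate variance. Passing recovery tests therefore demonstrates
correctness of the statistical machinery under the stated generative
model, not robustness to real-data artefacts upstream of the pileup.

## Validation studies and problem sizes

The `bsmeth.experiments` module fixes one problem size per study, chosen
so Monte-Carlo error is well inside each tolerance and each study runs in
seconds on one core:

- **Spike-in error recovery:** 30 kb genome + 30 kb control at 35% of
  reads, 30×; > 150,000 post-dedup lambda observations; tolerance ±0.001
  around 0.005 (binomial SE ≈ 1.7·10⁻⁵).
- **Global CG level:** 150 kb genome, 50 genes, 30×, > 10,000 CG
  strand-sites; recovered site-mean vs the analytic mixture mean,
  tolerance ±0.015 (the error floor adds ≈ +0.001 net bias).
- **Bimodal fractions:** count-report path at exactly 50× over a 120 kb
  genome; tolerance ±0.02 on the component weights (binomial smearing
  around the 0.2/0.8 cuts contributes ≈ +0.01 to the hypo fraction).
- **FDR calibration:** 10 replicates × ~20,000 all-null sites at 20×,
  known e = 0.005; mean called fraction must be ≤ 1%.
- **Planted deltas:** 220 genes / 132 kb, 20 genes shifted by −0.3 in the
  gene body, both libraries at 30×; recall ≥ 90% and false-down ≤ 5% at
  the default |Δ| ≥ 0.1 rule; the cross-tab is checked against a
  brute-force join oracle.
- **Determinism:** two full pipeline runs at one seed compared
  byte-for-byte (reads, truth, calls, DEG, control JSON) and the run
  reports compared with the output paths normalised.

All randomness flows from a single master seed through named
`numpy.random.default_rng([seed, stream])` streams, so every artefact is
reproducible bit-for-bit from the run report's echoed configuration.

## Numerical choices and degenerate inputs

Exact binomial tails, no continuity corrections. BH is delegated to
statsmodels and cross-checked against an independent step-up
implementation in the tests. Undefined levels are NaN, never 0: a site
with depth 0 is untested, a region without covered CpGs has no level,
and a context with no covered site is omitted from global summaries.
Zero-gene genomes, empty DEG tables, empty marker references, empty
feature sets and all-zero methylomes are valid inputs with documented
degenerate outputs; a missing or uncovered control contig, duplicate gene
ids at join keys, k > n, and lo ≥ hi thresholds are errors. Ties in
duplicate removal and mergesort-stable sorts keep every output
order-deterministic.

## Known limitations

Single-end simulation only affects fragment sampling (paired-end changes
no downstream formula and is not separately modelled); the pileup engine
holds per-contig count arrays in memory, sized for desk-scale genomes
(megabases, not gigabases); and no between-library single-site
differential test is provided — per-gene direction-of-change is the
integration currency.
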