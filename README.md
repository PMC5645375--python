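# bsmeth

Whole-genome bisulfite sequencing (WGBS) methylome analysis and
methylome–transcriptome integration, built around the analysis design used
to characterise *nras*-driven intrahepatic cholangiocarcinoma (ICC) in a
transgenic zebrafish liver model — together with a synthetic-data
generator that emulates the study's inputs, so the entire pipeline runs
and is testable at desk scale.

**Who it is for:** epigenomics analysts who want a small, fully
deterministic, end-to-end WGBS calling and integration pipeline whose
every statistical step is unit-tested against independent oracles, and
methods developers who need a ground-truth bisulfite simulator for
calibration studies.

## The model

Bisulfite treatment converts unmethylated cytosines to uracil (read as T)
while 5-methylcytosines stay C. For each strand-specific cytosine with
*k* C-reads out of *n* total (C+T) reads:

- **Error calibration.** An unmethylated lambda spike-in is sequenced with
  every library. The library error rate *e* — the sum of the
  non-conversion rate and T/C sequencing errors — is the total number of
  sequenced Cs divided by the total depth over lambda cytosines
  (typically ≈ 0.5%).
- **Calling.** Each site is tested against the null *X* ~ B(*n*, *e*)
  with the exact one-sided upper tail P(*X* ≥ *k*); Benjamini–Hochberg
  q-values < 0.01 define methylated cytosines (mCs).
- **Levels.** Site level = *k*/*n*, reported only at per-strand depth ≥ 4;
  region level = the unweighted mean of site levels of covered CpGs.
- **Profiles.** Cytosines are classified by context (CpG / CHG / CHH,
  H = A, C or T) on each strand; CG sites are summarised as hypo (< 20%),
  mid, or hyper (> 80%) methylated, as CG-density × methylation-level
  heatmaps (CG dinucleotides per 200 bp window, per-strand depth ≥ 10,
  with per-density median lines), and as metagene profiles over six
  functional elements (upstream, first exon, first intron, internal body,
  last exon, downstream).
- **Integration.** DEG status (|log2FC| ≥ 1, FDR ≤ 0.001 by default) is
  cross-tabulated against per-gene methylation direction (gene-body CpG
  region level, tumor − WT, |Δ| ≥ 0.1); candidate tumor markers are
  screened with log2FC ≥ 1 and P ≤ 0.05 against a human-ICC-evidence
  reference list, and hypomethylated markers are flagged.

The simulator generates the matching inputs: a toy genome with genes,
repeats and CpG-island promoters; a bimodal true methylome (beta mixture,
global CG mean ≈ 0.75, near-zero non-CG); bisulfite reads with
conversion failures and sequencing errors plus the lambda spike-in; and
DEG tables with embedded markers — all with ground-truth tables.

## Worked example

```sh
bsmeth all --seed 1 --out demo
```

or equivalently from Python:

```python
from bsmeth.pipeline import PipelineConfig, run_all

cfg = PipelineConfig.from_dict({
    "seed": 1, "out_dir": "demo",
    "simulate": {"seed": 1, "genome_length": 40_000, "n_genes": 16,
                 "target_depth": 20, "lambda_length": 8_000,
                 "lambda_fraction": 0.15},
})
report = run_all(cfg)
```

This simulates a 40 kb study at 20× per-strand depth, runs QC →
deduplication → pileup → spike-in calibration → calling → profiling →
integration for a WT and a tumor library, and prints (from
`demo/report.json`):

```
error_rate        0.00531
global_site_mean  {'CG': 0.7517, 'CHG': 0.0056, 'CHH': 0.0055}
bimodal           {'frac_hypo': 0.0856, 'frac_mid': 0.2983, 'frac_hyper': 0.6161, 'n_sites': 3668}
markers           11  hypomethylated: ['ehf', 'epha4', 'itgb6']
incidence         [('3 mpf', '0'), ('6 mpf', '0'), ('9 mpf', '67.2'), ('12 mpf', '81.5'), ('24 mpf', '86')]
```

Reading these: the spike-in recovers the configured ≈ 0.5% combined
conversion-failure + sequencing-error rate; the CG methylome is high and
bimodal (site-mean ≈ 75%, most sites > 80% or < 20%) while non-CG levels
sit at the error floor (≈ 0.5%); all 11 embedded marker genes pass the
expression filter, and exactly the three genes whose gene bodies were
simulated with a −0.3 methylation shift in the tumor library (*ehf*,
*epha4*, *itgb6*) are recovered as hypomethylated markers; the cohort
table reproduces the tumor-incidence percentages from the bundled counts.

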