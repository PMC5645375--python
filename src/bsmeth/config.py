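"""Simulation and pipeline configuration.

The defaults describe the study conditions the toolkit emulates: a
vertebrate liver methylome with bimodal CG methylation (global mean near
0.75, most sites either <20% or >80% methylated), essentially unmethylated
CHG/CHH cytosines, a fully unmethylated lambda spike-in, 90 bp reads, and a
combined bisulfite-conversion-failure plus sequencing error rate near 0.5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class BetaMixture:
    """Three-component beta mixture for true CG methylation levels.

    Components are hypo (near 0), mid, and hyper (near 1); ``weight_mid``
    is the remainder of the two configured weights. ``point_mass``, when
    set, short-circuits the mixture and places every site at that level
    (useful for degenerate/uniform methylomes).

    The default shapes are sharp enough that the <0.2 / >0.8 site fractions
    land close to the component weights themselves, and the mixture mean is
    ~0.752 -- the bimodal landscape reported for zebrafish liver.
    """

    weight_hypo: float = 0.06
    weight_hyper: float = 0.62
    hypo_shape: tuple[float, float] = (1.0, 30.0)
    mid_shape: tuple[float, float] = (5.0, 5.0)
    hyper_shape: tuple[float, float] = (20.0, 1.0)
    point_mass: float | None = None

    @property
    def weight_mid(self) -> float:
        return 1.0 - self.weight_hypo - self.weight_hyper

    @property
    def mean(self) -> float:
        """Analytic mean of the mixture (expected true CG level)."""
        if self.point_mass is not None:
            return self.point_mass
        m = 0.0
        for w, (a, b) in zip(
            (self.weight_hypo, self.weight_mid, self.weight_hyper),
            (self.hypo_shape, self.mid_shape, self.hyper_shape),
        ):
            m += w * a / (a + b)
        return m

    def validate(self) -> None:
        if not 0.0 <= self.weight_hypo <= 1.0:
            raise ValueError(f"weight_hypo must be in [0,1], got {self.weight_hypo}")
        if not 0.0 <= self.weight_hyper <= 1.0:
            raise ValueError(f"weight_hyper must be in [0,1], got {self.weight_hyper}")
        if self.weight_mid < -1e-12:
            raise ValueError("mixture weights must sum to at most 1")
        for name in ("hypo_shape", "mid_shape", "hyper_shape"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} must have positive alpha/beta, got {(a, b)}")
        if self.point_mass is not None and not 0.0 <= self.point_mass <= 1.0:
            raise ValueError(f"point_mass must be in [0,1], got {self.point_mass}")


@dataclass
class SimConfig:
    """Parameters of the synthetic WGBS study.

    seed                      master seed; every stage derives its own stream.
    genome_length             length of the single main contig (bp).
    n_genes / n_repeats       annotation density of the toy genome.
    target_depth              mean per-strand read depth on non-control contigs.
    read_length               bases per (single-end) read; 90 mirrors the
                              HiSeq 2000 libraries the design emulates.
    fragment_length           insert size; only affects paired-end sampling.
    conversion_failure_rate   P(unmethylated C escapes conversion), default 0.004.
    sequencing_error_rate     per-base miscall rate (C<->T at pyrimidines),
                              default 0.001; together ~0.5% false-C floor.
    cg_mixture                beta mixture of true CG methylation levels.
    non_cg_mean               mean TRUE CHG/CHH level; the observed level adds
                              the ~0.5% error floor on top.
    cpg_pair_correlation      1.0 = symmetric CpG dyads share one level.
    lambda_fraction           proportion of reads drawn from the control contig.
    lambda_length             length of the synthetic unmethylated spike-in.
    gc_content                background G+C of the main contig (zebrafish-like).
    island_* parameters       CpG-island mimicry around transcription starts.
    """

    seed: int = 0
    genome_length: int = 100_000
    n_genes: int = 40
    n_repeats: int = 30
    target_depth: float = 30.0
    read_length: int = 90
    fragment_length: int = 200
    paired_end: bool = False
    conversion_failure_rate: float = 0.004
    sequencing_error_rate: float = 0.001
    cg_mixture: BetaMixture = field(default_factory=BetaMixture)
    non_cg_mean: float = 5e-4
    cpg_pair_correlation: float = 1.0
    lambda_fraction: float = 0.10
    lambda_length: int = 20_000
    gc_content: float = 0.40
    island_gc_content: float = 0.60
    island_length: int = 150
    island_cpg_boost: float = 0.25

    def validate(self) -> None:
        """Raise ValueError naming the first offending field."""
        for name in (
            "conversion_failure_rate",
            "sequencing_error_rate",
            "non_cg_mean",
            "cpg_pair_correlation",
            "gc_content",
            "island_gc_content",
            "island_cpg_boost",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.lambda_fraction < 1.0:
            raise ValueError(f"lambda_fraction must be in [0,1), got {self.lambda_fraction}")
        for name in ("genome_length", "read_length", "fragment_length", "lambda_length"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name in ("n_genes", "n_repeats"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.target_depth <= 0:
            raise ValueError(f"target_depth must be positive, got {self.target_depth}")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")
        if self.read_length > self.lambda_length:
            raise ValueError("read_length exceeds lambda_length")
        if self.n_genes > 0 and self.genome_length // self.n_genes < 50:
            raise ValueError(
                f"n_genes={self.n_genes} too dense for genome_length={self.genome_length}"
            )
        self.cg_mixture.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        """Build from a plain mapping (e.g. a YAML section); unknown keys rejected."""
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
        if "cg_mixture" in d and isinstance(d["cg_mixture"], dict):
            mix = dict(d["cg_mixture"])
            mknown = {f.name for f in fields(BetaMixture)}
            munknown = set(mix) - mknown
            if munknown:
                raise ValueError(f"unknown cg_mixture keys: {sorted(munknown)}")
            for k in ("hypo_shape", "mid_shape", "hyper_shape"):
                if k in mix:
                    mix[k] = tuple(mix[k])
            d["cg_mixture"] = BetaMixture(**mix)
        cfg = cls(**d)
        cfg.validate()
        return cfg
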