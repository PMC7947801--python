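"""Configuration containers for simulation and pipeline runs.

Defaults mirror the structure of the Chinese soybean germplasm panel that
motivates the package: 341 inbred accessions in three evolutionary
subpopulations (76 wild accessions, 83 landraces, 182 released cultivars),
biallelic SNPs organised into LD blocks whose haplotypes act as multi-allelic
markers (2-11 alleles per block), tens of additive multi-allelic QTLs jointly
explaining about half of the phenotypic variance, and a replicated incomplete
block phenotyping design with trait heritability around 0.7-0.8.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence


class ConfigError(ValueError):
    """Raised when a configuration is internally inconsistent or infeasible."""


# Per-time-point error-variance multipliers (relative to the best time point).
# U-shaped so that a single interior measurement attains the maximum
# heritability: early and late canopy measurements are the noisiest, and the
# minimum sits at index 5 of 9 (the sixth measurement), giving a heritability
# sweep from roughly 0.16 to the target when target_h2 = 0.783.
DEFAULT_ERROR_SCHEDULE = (19.0, 10.0, 6.0, 3.0, 1.8, 1.0, 1.4, 2.5, 5.0)


@dataclass
class SimConfig:
    """Ground-truth simulation parameters for a structured germplasm panel."""

    # subpopulation sizes: wild accessions, landraces, released cultivars
    n_wa: int = 76
    n_lr: int = 83
    n_rc: int = 182

    # genome layout
    n_chromosomes: int = 20
    chrom_length_bp: int = 50_000_000
    snp_count: int = 2000
    block_mean_span_bp: int = 20_000
    haplotypes_per_block: int = 11       # upper bound on alleles per block
    singleton_fraction: float = 0.3      # fraction of blocks that are lone SNPs
    maf_floor: float = 0.02

    # trait architecture
    n_qtl: int = 10
    alleles_per_qtl: tuple[int, int] = (2, 6)
    qtl_pv_share: float = 0.5            # variance share of the planted QTLs
    qtl_sd: float = 0.02                 # SD of the summed QTL genetic values
    target_h2: float = 0.75
    trait: str = "NDVI"
    trait_mean: float = 0.11

    # planted allele-evolution events (wild -> landrace -> cultivar)
    n_emerged_lr: int = 2                # novel alleles appearing in LR
    n_excluded_lr: int = 3               # WA alleles lost in LR
    n_emerged_rc: int = 2                # novel alleles appearing in RC
    n_excluded_rc: int = 2               # LR alleles lost in RC
    n_recovered_rc: int = 2              # WA alleles lost in LR, restored in RC
    n_new_loci_lr: int = 0               # of the LR emergences, at new loci
    n_new_loci_rc: int = 0               # of the RC emergences, at new loci
    emerged_freq: float = 0.08           # target frequency of a planted allele
    min_carriers: int = 2                # enforced presence floor on QTL blocks
    drift: float = 30.0                  # Dirichlet concentration multiplier

    # phenotyping design
    n_replicates: int = 2
    n_blocks_per_replicate: int = 8
    n_timepoints: int = 9
    error_schedule: Optional[Sequence[float]] = None
    block_sd: float = 0.01
    group_shift_sd: float = 0.01

    seed: int = 0

    @property
    def n_accessions(self) -> int:
        return self.n_wa + self.n_lr + self.n_rc

    def schedule(self) -> tuple[float, ...]:
        if self.error_schedule is not None:
            sched = tuple(float(v) for v in self.error_schedule)
        else:
            sched = DEFAULT_ERROR_SCHEDULE
        if len(sched) != self.n_timepoints:
            # resample the default shape to the requested number of time points
            if self.error_schedule is not None:
                raise ConfigError(
                    f"error_schedule has {len(sched)} entries for "
                    f"{self.n_timepoints} time points"
                )
            import numpy as np

            x = np.linspace(0, 1, self.n_timepoints)
            x0 = np.linspace(0, 1, len(DEFAULT_ERROR_SCHEDULE))
            sched = tuple(float(v) for v in np.interp(x, x0, DEFAULT_ERROR_SCHEDULE))
        return sched

    def validate(self) -> None:
        counts = {
            "n_wa": self.n_wa, "n_lr": self.n_lr, "n_rc": self.n_rc,
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": self.chrom_length_bp,
            "snp_count": self.snp_count,
            "block_mean_span_bp": self.block_mean_span_bp,
            "haplotypes_per_block": self.haplotypes_per_block,
            "n_qtl": self.n_qtl, "n_replicates": self.n_replicates,
            "n_blocks_per_replicate": self.n_blocks_per_replicate,
            "n_timepoints": self.n_timepoints,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if not (0.0 < self.target_h2 <= 1.0):
            raise ConfigError(f"target_h2 must be in (0, 1], got {self.target_h2}")
        lo, hi = self.alleles_per_qtl
        if not (2 <= lo <= hi <= 11):
            raise ConfigError(
                f"alleles_per_qtl range must lie within [2, 11], got {self.alleles_per_qtl}"
            )
        if not (0.0 < self.qtl_pv_share <= self.target_h2):
            raise ConfigError(
                "qtl_pv_share must be in (0, target_h2]: the QTLs cannot explain "
                "more variance than the whole genotype"
            )
        if self.haplotypes_per_block > 11 or self.haplotypes_per_block < 2:
            raise ConfigError("haplotypes_per_block must be within [2, 11]")
        for name in ("n_emerged_lr", "n_excluded_lr", "n_emerged_rc",
                     "n_excluded_rc", "n_recovered_rc",
                     "n_new_loci_lr", "n_new_loci_rc"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.n_recovered_rc > self.n_excluded_lr:
            raise ConfigError(
                "cannot recover more alleles in RC than were excluded in LR"
            )
        if self.n_new_loci_lr > self.n_emerged_lr or self.n_new_loci_rc > self.n_emerged_rc:
            raise ConfigError("new loci must be a subset of the planted emergences")
        n_events = (self.n_emerged_lr + self.n_excluded_lr + self.n_emerged_rc
                    + self.n_excluded_rc)
        if n_events > self.n_qtl * (self.alleles_per_qtl[1] - 1):
            raise ConfigError("more planted allele changes than QTL block capacity")


@dataclass
class RunConfig:
    """End-to-end pipeline parameters.

    Either ``sim`` is set (fully synthetic run) or the three input paths point
    at genotype/phenotype/metadata files on disk.
    """

    sim: Optional[SimConfig] = None
    genotype_path: Optional[str] = None
    genotype_format: str = "vcf"          # "vcf" | "tsv"
    phenotype_path: Optional[str] = None
    metadata_path: Optional[str] = None

    maf_floor: float = 0.02
    max_block_span_bp: int = 100_000
    strong_ci_low: float = 0.70
    strong_ci_high: float = 0.98
    recomb_ci_high: float = 0.90
    strong_fraction: float = 0.95
    eigen_share: float = 0.5
    alpha1: float = 0.05
    alpha: float = 0.05
    n_progeny: int = 2000
    percentiles: tuple[int, ...] = (50, 99)
    cm_per_mb: float = 2.2
    n_crosses_sample: Optional[int] = 2000  # None = every pair

    seed: int = 0
    out_dir: str = "haploqtl_out"

    def validate(self) -> None:
        if self.sim is None and self.genotype_path is None:
            raise ConfigError("either a simulation config or input paths are required")
        if self.sim is not None:
            self.sim.validate()
        if not (0.0 < self.maf_floor < 0.5):
            raise ConfigError("maf_floor must be in (0, 0.5)")
        for name in ("alpha1", "alpha"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ConfigError(f"{name} must be in (0, 1)")
        if self.cm_per_mb <= 0:
            raise ConfigError("cm_per_mb must be positive")

    def config_hash(self) -> str:
        payload = asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
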