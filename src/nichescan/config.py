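"""Configuration objects for the simulator and the end-to-end pipeline.

All randomness in a run flows from a single integer seed.  Sub-streams are
derived with fixed offsets (see :data:`STREAM_OFFSETS`) so that each stage is
independently reproducible: re-running only the genotype stage with the same
config yields the same genotypes regardless of what else ran before.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


#: fixed offsets deriving per-stage RNG streams from the master seed
STREAM_OFFSETS = {
    "frequencies": 0,
    "genotypes": 1,
    "info_fields": 2,
    "annotation": 3,
    "broods": 4,
}


def substream(seed: int, stage: str) -> np.random.Generator:
    """Return the RNG for *stage* derived from the master *seed*."""
    return np.random.default_rng([int(seed), STREAM_OFFSETS[stage]])


@dataclass(frozen=True)
class PlantedLocus:
    """A selected locus on one focal branch.

    The locus is modelled as a selective-sweep footprint: every SNP within
    ``sweep_width`` bp of ``position`` draws its focal-population frequency
    with drift ``f_sel`` instead of the background branch F, emulating the
    coherent allele-frequency shift that genetic hitchhiking produces around
    a selected site.  Sites outside the footprint remain independent.
    """

    contig: str
    position: int  # 0-based
    focal_population: str
    f_sel: float
    sweep_width: int = 1200


@dataclass
class SimConfig:
    """Study conditions for the synthetic three-population data set.

    Defaults mirror the study design this package targets: two neighbouring
    focal populations of 40 diploid individuals each plus a distant outgroup
    of 22, weak background drift on the focal branches (F = 0.01, putting
    genome-wide weighted F_ST at the observed 0.01 order of magnitude) and
    stronger drift (F = 0.05) on the outgroup branch.
    """

    n_contigs: int = 2
    contig_length: int = 1_000_000
    n_snps: int = 20_000
    #: 'uniform' keeps scans informative (no near-fixed sites); 'neutral'
    #: draws p0 from a truncated 1/x law approximating the equilibrium
    #: frequency spectrum (use with a wide range, e.g. (0.001, 0.999))
    ancestral_freq_law: str = "uniform"
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    branch_drift: Mapping[str, float] = field(
        default_factory=lambda: {"gamlingay": 0.01, "waresley": 0.01, "wales": 0.05}
    )
    planted_loci: Sequence[PlantedLocus] = field(default_factory=tuple)
    sample_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"gamlingay": 40, "waresley": 40, "wales": 22}
    )
    gene_length: int = 2000
    gene_spacing: int = 2000
    n_go_terms: int = 20
    planted_go_term: str = "GO:SYN0001"
    planted_set_size: int = 15
    #: fraction of VCF records drawn to fail the GATK-style hard filter
    filter_fail_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.n_contigs < 1 or self.contig_length < 1:
            raise ConfigError("need at least one contig of positive length")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be positive")
        if self.n_snps > self.n_contigs * self.contig_length:
            raise ConfigError("more SNPs requested than available positions")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError("ancestral_freq_range must satisfy 0 < lo < hi < 1")
        if self.ancestral_freq_law not in ("uniform", "neutral"):
            raise ConfigError("ancestral_freq_law must be 'uniform' or 'neutral'")
        for pop, f in self.branch_drift.items():
            if not (0.0 <= f < 1.0):
                raise ConfigError(f"branch drift F for {pop!r} must be in [0, 1)")
        for pop, n in self.sample_sizes.items():
            if pop not in self.branch_drift:
                raise ConfigError(f"sample size given for unknown population {pop!r}")
            if n < 2:
                raise ConfigError(f"need >= 2 diploids per population, got {n} for {pop!r}")
        if set(self.sample_sizes) != set(self.branch_drift):
            raise ConfigError("sample_sizes and branch_drift must name the same populations")
        for locus in self.planted_loci:
            if locus.contig not in self.contig_names:
                raise ConfigError(f"planted locus on unknown contig {locus.contig!r}")
            if not (0 <= locus.position < self.contig_length):
                raise ConfigError("planted locus position outside contig bounds")
            if locus.focal_population not in self.branch_drift:
                raise ConfigError(
                    f"planted locus names unknown population {locus.focal_population!r}"
                )
            if not (0.0 <= locus.f_sel < 1.0):
                raise ConfigError("f_sel must be in [0, 1)")
            if locus.f_sel <= self.branch_drift[locus.focal_population]:
                raise ConfigError(
                    "planted locus f_sel must exceed the background branch F "
                    f"({locus.f_sel} <= {self.branch_drift[locus.focal_population]})"
                )
        if self.gene_length + self.gene_spacing > self.contig_length:
            raise ConfigError("gene_length + gene_spacing exceeds contig_length")
        if self.n_go_terms < 1:
            raise ConfigError("need at least one GO term")
        if not (0.0 <= self.filter_fail_fraction < 1.0):
            raise ConfigError("filter_fail_fraction must be in [0, 1)")

    # -- helpers ---------------------------------------------------------
    @property
    def contig_names(self) -> list[str]:
        return [f"contig{i + 1}" for i in range(self.n_contigs)]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: self.contig_length for name in self.contig_names}

    @property
    def populations(self) -> list[str]:
        return list(self.branch_drift)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["branch_drift"] = dict(self.branch_drift)
        d["sample_sizes"] = dict(self.sample_sizes)
        d["planted_loci"] = [asdict(p) for p in self.planted_loci]
        d["ancestral_freq_range"] = list(self.ancestral_freq_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "planted_loci" in d:
            d["planted_loci"] = tuple(
                p if isinstance(p, PlantedLocus) else PlantedLocus(**p)
                for p in d["planted_loci"]
            )
        if "ancestral_freq_range" in d:
            d["ancestral_freq_range"] = tuple(d["ancestral_freq_range"])
        return cls(**d)


@dataclass
class GseaConfig:
    n_perm: int = 1000
    weight: float = 1.0
    min_size: int = 10
    max_size: int = 500


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Exactly three population roles must be assigned: two focal populations
    and one outgroup; PBS is computed for all three branches but outlier
    classes refer to the focal pair only.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    focal1: str = "gamlingay"
    focal2: str = "waresley"
    outgroup: str = "wales"
    scan_window: int = 2000
    profile_window: int = 500
    profile_step: int = 100
    estimator: str = "hudson"
    fst_mode: str = "weighted"
    outlier_threshold: float = 0.05
    missing_filter_policy: str = "pass"
    gsea: GseaConfig = field(default_factory=GseaConfig)
    outdir: str = "nichescan_run"
    seed: int = 0

    def __post_init__(self) -> None:
        roles = (self.focal1, self.focal2, self.outgroup)
        if len(set(roles)) != 3:
            raise ConfigError("focal1, focal2 and outgroup must be three distinct populations")
        missing = set(roles) - set(self.sim.populations)
        if missing:
            raise ConfigError(f"roles name unknown populations: {sorted(missing)}")
        for name in ("scan_window", "profile_window", "profile_step"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.estimator not in ("hudson", "weir-cockerham"):
            raise ConfigError("estimator must be 'hudson' or 'weir-cockerham'")
        if self.fst_mode not in ("weighted", "unweighted"):
            raise ConfigError("fst_mode must be 'weighted' or 'unweighted'")

    @property
    def branches(self) -> tuple[str, str, str]:
        return (self.focal1, self.focal2, self.outgroup)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and not isinstance(d["sim"], SimConfig):
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "gsea" in d and not isinstance(d["gsea"], GseaConfig):
            d["gsea"] = GseaConfig(**d["gsea"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
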