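"""Synthetic genomic, annotation and brood-phenotype data.

The genomic generator follows the Balding–Nichols model: each population's
allele frequency at a SNP is a Beta draw around the ancestral frequency p0,

    p_k ~ Beta(p0 (1-F_k)/F_k, (1-p0)(1-F_k)/F_k),

whose variance is F_k p0 (1-p0) — branch-specific drift of magnitude F_k.
Sites are independent (no linkage), except that a planted locus shifts every
SNP inside its sweep footprint with the stronger drift F_sel on the focal
branch only, emulating hitchhiking around a selected site.

The brood generator emits split-sibling dyads: one arm breeds on a small
carcass, the other on a large one, with clutch size Poisson around a linear
predictor in carcass class and population.  A positive ``elevation_offset``
raises the derived population's clutch size in BOTH environments (an
elevation shift of the reaction norm, not a slope change).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig, substream
from .popgen import GenotypeMatrix

__all__ = [
    "simulate_frequencies",
    "simulate_genotypes",
    "simulate_info_fields",
    "generate_annotation",
    "BroodArm",
    "BroodDyad",
    "simulate_broods",
    "dyads_to_frame",
    "frame_to_dyads",
]


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def _balding_nichols(rng: np.random.Generator, p0: np.ndarray, f) -> np.ndarray:
    """Draw population frequencies; F = 0 copies p0 exactly (zero drift)."""
    f = np.broadcast_to(np.asarray(f, dtype=float), p0.shape)
    out = p0.copy()
    drift = f > 0
    if np.any(drift):
        ratio = (1 - f[drift]) / f[drift]
        out[drift] = rng.beta(p0[drift] * ratio, (1 - p0[drift]) * ratio)
    return out


def simulate_frequencies(config: SimConfig) -> pd.DataFrame:
    """Latent per-population allele frequencies (the PopFreqTable).

    Columns: contig, pos (0-based), p0, then one column per population.
    Rows sorted by (contig, pos); positions unique per contig.  Planted
    positions are forced into the SNP set.
    """
    rng = substream(config.seed, "frequencies")
    per_contig = _split_snps(config)
    frames = []
    for ctg in config.contig_names:
        n = per_contig[ctg]
        forced = np.array(
            sorted({p.position for p in config.planted_loci if p.contig == ctg}),
            dtype=np.int64,
        )
        pos = rng.choice(config.contig_length, size=n, replace=False)
        pos = np.unique(np.concatenate([pos, forced]))[:]
        if len(pos) > n:  # keep the configured count, never dropping forced sites
            drop = np.setdiff1d(pos, forced, assume_unique=False)
            keep = rng.choice(len(drop), size=n - len(forced), replace=False)
            pos = np.sort(np.concatenate([forced, drop[np.sort(keep)]]))
        lo, hi = config.ancestral_freq_range
        if config.ancestral_freq_law == "uniform":
            p0 = rng.uniform(lo, hi, size=len(pos))
        else:  # truncated 1/x law, the neutral equilibrium spectrum shape
            p0 = lo * (hi / lo) ** rng.random(len(pos))
        cols = {"contig": ctg, "pos": pos, "p0": p0}
        for pop in config.populations:
            f = np.full(len(pos), config.branch_drift[pop])
            for locus in config.planted_loci:
                if locus.contig != ctg or locus.focal_population != pop:
                    continue
                half = locus.sweep_width // 2
                inside = np.abs(pos - locus.position) <= half
                f[inside] = locus.f_sel
            cols[pop] = _balding_nichols(rng, p0, f)
        frames.append(pd.DataFrame(cols))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["populations"] = config.populations
    return out


def _split_snps(config: SimConfig) -> dict[str, int]:
    base = config.n_snps // config.n_contigs
    rem = config.n_snps % config.n_contigs
    return {
        name: base + (1 if i < rem else 0)
        for i, name in enumerate(config.contig_names)
    }


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(freqs: pd.DataFrame, config: SimConfig) -> GenotypeMatrix:
    """Binomial(2, p_k) diploid genotypes per sample from the frequency table."""
    rng = substream(config.seed, "genotypes")
    samples: list[str] = []
    sample_pops: list[str] = []
    blocks = []
    for pop in config.populations:
        n = config.sample_sizes[pop]
        samples.extend(f"{pop}_{i + 1:03d}" for i in range(n))
        sample_pops.extend([pop] * n)
        p = freqs[pop].to_numpy()
        blocks.append(rng.binomial(2, p[:, None], size=(len(p), n)).astype(np.int8))
    return GenotypeMatrix(
        contig=freqs["contig"].to_numpy(dtype=object),
        pos=freqs["pos"].to_numpy(dtype=np.int64),
        geno=np.concatenate(blocks, axis=1),
        samples=samples,
        sample_pops=np.asarray(sample_pops, dtype=object),
    )


def simulate_info_fields(config: SimConfig, n_records: int) -> pd.DataFrame:
    """Synthetic QD/SOR/FS INFO values.

    A ``filter_fail_fraction`` of records is drawn to violate exactly one of
    the hard-filter criteria (QD < 2.0, SOR > 3.0, FS > 200), giving the
    filter a non-trivial test surface; the rest pass comfortably.
    """
    rng = substream(config.seed, "info_fields")
    qd = rng.uniform(5.0, 35.0, n_records)
    sor = rng.uniform(0.3, 2.5, n_records)
    fs = rng.uniform(0.0, 20.0, n_records)
    n_fail = int(round(config.filter_fail_fraction * n_records))
    if n_fail:
        idx = rng.choice(n_records, size=n_fail, replace=False)
        which = rng.integers(0, 3, size=n_fail)
        qd[idx[which == 0]] = rng.uniform(0.0, 1.9, (which == 0).sum())
        sor[idx[which == 1]] = rng.uniform(3.1, 9.0, (which == 1).sum())
        fs[idx[which == 2]] = rng.uniform(201.0, 400.0, (which == 2).sum())
    return pd.DataFrame({"qd": qd, "sor": sor, "fs": fs})


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tile genes along each contig and assign GO terms.

    Genes of ``gene_length`` bp start every ``gene_length + gene_spacing``
    bp (0-based half-open internally).  Every gene receives one background
    GO term; the planted term's member set contains every gene overlapping a
    planted locus footprint plus seeded decoys up to ``planted_set_size``.

    Returns (genes, gene_go): genes with columns gene_id/contig/start/end,
    gene_go with gene_id/go_id rows.
    """
    rng = substream(config.seed, "annotation")
    period = config.gene_length + config.gene_spacing
    rows = []
    k = 0
    for ctg in config.contig_names:
        start = 0
        while start + config.gene_length <= config.contig_length:
            k += 1
            rows.append((f"g{k:05d}", ctg, start, start + config.gene_length))
            start += period
    genes = pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end"])

    terms = [f"GO:SYN{i + 1:04d}" for i in range(config.n_go_terms)]
    if config.planted_go_term not in terms:
        terms = [config.planted_go_term] + terms[:-1]
    background = [t for t in terms if t != config.planted_go_term]
    if not background:
        raise ConfigError("need at least one non-planted GO term")

    planted_members: set[str] = set()
    for locus in config.planted_loci:
        half = locus.sweep_width // 2
        lo, hi = locus.position - half, locus.position + half + 1
        hit = genes[(genes["contig"] == locus.contig)
                    & (genes["start"] < hi) & (genes["end"] > lo)]
        if hit.empty:
            raise ConfigError(
                f"planted locus at {locus.contig}:{locus.position} overlaps no gene"
            )
        planted_members.update(hit["gene_id"])

    assignments = []
    bg_choice = rng.integers(0, len(background), size=len(genes))
    for gid, b in zip(genes["gene_id"], bg_choice):
        assignments.append((gid, background[b]))
    if config.planted_loci:
        decoy_pool = [g for g in genes["gene_id"] if g not in planted_members]
        n_decoys = max(0, config.planted_set_size - len(planted_members))
        n_decoys = min(n_decoys, len(decoy_pool))
        decoys = rng.choice(len(decoy_pool), size=n_decoys, replace=False)
        members = sorted(planted_members) + sorted(decoy_pool[i] for i in decoys)
        for gid in sorted(members):
            assignments.append((gid, config.planted_go_term))
    gene_go = pd.DataFrame(assignments, columns=["gene_id", "go_id"])
    gene_go = gene_go.sort_values(["go_id", "gene_id"], ignore_index=True)
    return genes, gene_go


# ---------------------------------------------------------------------------
# brood dyads
# ---------------------------------------------------------------------------

@dataclass
class BroodArm:
    """One breeding attempt of a dyad (one carcass-size treatment)."""

    carcass_mass: float
    clutch_size: int
    egg_lengths: list[float] = field(default_factory=list)   # mm, measurable eggs
    egg_widths: list[float] = field(default_factory=list)    # mm
    brood_size: int = 0
    brood_mass: float = 0.0                                  # g


@dataclass
class BroodDyad:
    """Paired sibling breeding records on a small vs. a large carcass."""

    dyad_id: str
    population: str
    block: str
    small: BroodArm | None
    large: BroodArm | None

    @property
    def complete(self) -> bool:
        return self.small is not None and self.large is not None


def simulate_broods(
    n_dyads_per_population: int,
    elevation_offset: float = 5.0,
    culling_on_small: bool = False,
    seed: int = 0,
    populations: tuple[str, str] = ("gamlingay", "waresley"),
    derived_population: str = "waresley",
    base_clutch: float = 15.0,
    carcass_effect: float = 4.0,
    cull_fraction: float = 0.3,
    measurable_fraction: float = 0.65,
    failure_rate: float = 0.0,
) -> list[BroodDyad]:
    """Generate split-brood dyads with a population elevation offset.

    Clutch size ~ Poisson(mu) with
    ``mu = base_clutch + carcass_effect * 1[large] + elevation_offset * 1[derived]``.
    Brood size equals clutch size minus a Binomial(clutch, cull_fraction)
    culling deficit applied only to the derived population on small
    carcasses when ``culling_on_small`` is set.  Egg length/width are normal
    with mean width shrinking slightly as clutch size grows (an egg-size /
    egg-number trade-off); only a ``measurable_fraction`` of eggs carry
    measurements.  ``failure_rate`` drops single arms to emulate breeding
    failure; affected dyads are incomplete and excluded downstream.
    """
    mu_small = {p: base_clutch + (elevation_offset if p == derived_population else 0.0)
                for p in populations}
    for p, mu in mu_small.items():
        if mu < 0 or mu + carcass_effect < 0:
            raise ConfigError(f"negative clutch mean for population {p!r}")
    if derived_population not in populations:
        raise ConfigError("derived_population must be one of populations")
    rng = np.random.default_rng([int(seed), 4])
    dyads = []
    for pop in populations:
        for d in range(n_dyads_per_population):
            arms = {}
            for treatment in ("small", "large"):
                if failure_rate > 0 and rng.random() < failure_rate:
                    arms[treatment] = None
                    continue
                carcass = (rng.uniform(12.0, 17.0) if treatment == "small"
                           else rng.uniform(26.0, 31.0))
                mu = mu_small[pop] + (carcass_effect if treatment == "large" else 0.0)
                clutch = int(rng.poisson(mu))
                deficit = 0
                if (culling_on_small and treatment == "small"
                        and pop == derived_population and clutch > 0):
                    deficit = int(rng.binomial(clutch, cull_fraction))
                brood = clutch - deficit
                n_measurable = int(rng.binomial(clutch, measurable_fraction))
                w_mean = max(0.6, 1.0 - 0.004 * (clutch - base_clutch))
                widths = np.maximum(rng.normal(w_mean, 0.05, n_measurable), 0.3)
                lengths = np.maximum(rng.normal(1.7, 0.1, n_measurable), widths)
                larvae = np.maximum(rng.normal(0.18, 0.02, brood), 0.01) if brood else []
                arms[treatment] = BroodArm(
                    carcass_mass=round(float(carcass), 3),
                    clutch_size=clutch,
                    egg_lengths=[round(float(x), 4) for x in lengths],
                    egg_widths=[round(float(x), 4) for x in widths],
                    brood_size=brood,
                    brood_mass=round(float(np.sum(larvae)), 4),
                )
            dyads.append(BroodDyad(
                dyad_id=f"{pop}_d{d + 1:03d}",
                population=pop,
                block="block1",
                small=arms["small"],
                large=arms["large"],
            ))
    return dyads


def dyads_to_frame(dyads: list[BroodDyad]) -> pd.DataFrame:
    """One row per dyad arm; egg measurement lists are ';'-joined."""
    rows = []
    for d in dyads:
        for treatment in ("small", "large"):
            arm = getattr(d, treatment)
            if arm is None:
                continue
            rows.append({
                "dyad_id": d.dyad_id,
                "population": d.population,
                "block": d.block,
                "treatment": treatment,
                "carcass_mass_g": arm.carcass_mass,
                "clutch_size": arm.clutch_size,
                "brood_size": arm.brood_size,
                "brood_mass_g": arm.brood_mass,
                "egg_lengths_mm": ";".join(f"{x:.4f}" for x in arm.egg_lengths),
                "egg_widths_mm": ";".join(f"{x:.4f}" for x in arm.egg_widths),
            })
    return pd.DataFrame(rows)


def frame_to_dyads(df: pd.DataFrame) -> list[BroodDyad]:
    dyads = []
    for (dyad_id, pop, block), grp in df.groupby(
            ["dyad_id", "population", "block"], sort=True):
        arms: dict[str, BroodArm | None] = {"small": None, "large": None}
        for row in grp.itertuples():
            arms[row.treatment] = BroodArm(
                carcass_mass=float(row.carcass_mass_g),
                clutch_size=int(row.clutch_size),
                egg_lengths=_split_floats(row.egg_lengths_mm),
                egg_widths=_split_floats(row.egg_widths_mm),
                brood_size=int(row.brood_size),
                brood_mass=float(row.brood_mass_g),
            )
        dyads.append(BroodDyad(dyad_id, pop, block, arms["small"], arms["large"]))
    return dyads


def _split_floats(s) -> list[float]:
    if not isinstance(s, str) or not s:
        return []
    return [float(x) for x in s.split(";")]
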