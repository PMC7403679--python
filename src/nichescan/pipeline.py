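"""End-to-end orchestration: simulate -> filter -> F_ST -> PBS -> genes -> GSEA.

Every stage writes plain-text artifacts into the run directory and records
them (with SHA-256 checksums) in ``manifest.json`` together with the config
hash and seed, so identical configurations reproduce identical artifacts
byte for byte.  Stages never mutate another stage's outputs; the pipeline
can be re-entered from any completed stage by calling the stage functions
directly with the on-disk artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import branch as branchmod
from . import generank, popgen, simulate, vcfio
from .config import PipelineConfig

log = logging.getLogger("nichescan")

__all__ = ["run_pipeline", "PipelineResult"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    outdir: str
    artifacts: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    @property
    def manifest_path(self) -> str:
        return os.path.join(self.outdir, "manifest.json")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    # hash the scientific configuration only, not the run location
    d = cfg.to_dict()
    d.pop("outdir", None)
    return hashlib.sha256(
        json.dumps(d, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage in dependency order and write the run manifest."""
    os.makedirs(cfg.outdir, exist_ok=True)
    res = PipelineResult(cfg, cfg.outdir)
    chash = _config_hash(cfg)
    comments = [f"config_hash={chash}", f"seed={cfg.seed}"]

    def emit(name: str, path: str) -> None:
        res.artifacts[name] = path
        log.info("stage artifact %s -> %s", name, path)

    p = lambda name: os.path.join(cfg.outdir, name)

    # -- stage 1: simulate ------------------------------------------------
    sim = cfg.sim
    freqs = simulate.simulate_frequencies(sim)
    vcfio.write_track(freqs, p("frequencies.tsv"), comments)
    emit("frequencies", p("frequencies.tsv"))
    gm = simulate.simulate_genotypes(freqs, sim)
    info = simulate.simulate_info_fields(sim, gm.n_snps)
    vcfio.write_vcf(gm, p("variants.vcf"), sim.contig_lengths, info)
    emit("vcf", p("variants.vcf"))
    vcfio.write_popmap(dict(zip(gm.samples, gm.sample_pops)), p("popmap.tsv"))
    emit("popmap", p("popmap.tsv"))
    genes, gene_go = simulate.generate_annotation(sim)
    vcfio.write_gff3(genes, p("genes.gff3"))
    emit("gff3", p("genes.gff3"))
    vcfio.write_gene_go(gene_go, p("gene_go.tsv"))
    emit("gene_go", p("gene_go.tsv"))

    # -- stage 2: hard filter ---------------------------------------------
    keep, report = popgen.hard_filter_arrays(
        info["qd"], info["sor"], info["fs"], cfg.missing_filter_policy)
    vcfio.write_table(report.to_frame(), p("filter_report.tsv"))
    emit("filter_report", p("filter_report.tsv"))
    gm_f = popgen.GenotypeMatrix(
        gm.contig[keep], gm.pos[keep], gm.geno[keep], gm.samples, gm.sample_pops)
    res.summary["n_snps_retained"] = int(keep.sum())

    # -- stage 3: counts, F_ST, diversity ---------------------------------
    b1, b2, b3 = cfg.branches
    counts = popgen.allele_counts(gm_f, list(cfg.branches))
    scan = popgen.make_windows(sim.contig_lengths, cfg.scan_window)
    pairs = [(b1, b2), (b1, b3), (b2, b3)]
    tracks = {}
    for pa, pb in pairs:
        t = popgen.window_fst(counts, pa, pb, scan, cfg.estimator, cfg.fst_mode)
        tracks[(pa, pb)] = t
        name = f"fst_{cfg.scan_window}bp_{pa}_{pb}.tsv"
        vcfio.write_track(t.df, p(name), comments + [f"estimator={t.estimator}",
                                                     f"mode={t.mode}"])
        emit(f"fst_{pa}_{pb}", p(name))
    unw, wgt = popgen.genome_wide_fst(counts, b1, b2, cfg.estimator)
    gw = pd.DataFrame([{"pair": f"{b1}-{b2}", "estimator": cfg.estimator,
                        "unweighted_fst": unw, "weighted_fst": wgt}])
    vcfio.write_table(gw, p("genome_wide_fst.tsv"))
    emit("genome_wide_fst", p("genome_wide_fst.tsv"))
    res.summary["unweighted_fst"] = unw
    res.summary["weighted_fst"] = wgt
    for pop in (b1, b2):
        div = popgen.nucleotide_diversity(counts, pop, scan)
        taj = popgen.tajimas_d(counts, pop, scan)
        div["tajimas_d"] = taj["tajimas_d"]
        vcfio.write_track(div, p(f"diversity_{pop}.tsv"), comments)
        emit(f"diversity_{pop}", p(f"diversity_{pop}.tsv"))
        res.summary[f"pi_{pop}"] = float(div["pi"].mean())
        res.summary[f"tajimas_d_{pop}"] = float(np.nanmean(taj["tajimas_d"]))

    # -- stage 4: PBS scan, zF_ST, outliers -------------------------------
    pbs_scan_track = branchmod.pbs_scan(
        tracks[(b1, b2)], tracks[(b1, b3)], tracks[(b2, b3)])
    vcfio.write_track(pbs_scan_track.df, p("pbs_scan.tsv"), comments)
    emit("pbs_scan", p("pbs_scan.tsv"))
    res.summary["mean_pbs"] = pbs_scan_track.branch_means()
    ztrack = branchmod.zfst(tracks[(b1, b2)])
    vcfio.write_track(ztrack.df, p("zfst.tsv"),
                      comments + [f"mean={ztrack.mean:.10g}", f"sd={ztrack.sd:.10g}"])
    emit("zfst", p("zfst.tsv"))
    outliers = branchmod.flag_outliers(pbs_scan_track, cfg.outlier_threshold)
    vcfio.write_track(outliers, p("pbs_outliers.tsv"),
                      comments + [f"threshold={cfg.outlier_threshold}"])
    emit("pbs_outliers", p("pbs_outliers.tsv"))
    res.summary["n_outlier_windows"] = int(len(outliers))

    # -- stage 5: sliding PBS and gene scores -----------------------------
    sliding = popgen.make_windows(sim.contig_lengths, cfg.profile_window,
                                  cfg.profile_step)
    stracks = [popgen.window_fst(counts, pa, pb, sliding, cfg.estimator,
                                 cfg.fst_mode) for pa, pb in pairs]
    pbs_sliding = branchmod.pbs_scan(*stracks)
    vcfio.write_track(pbs_sliding.df, p("pbs_sliding.tsv"), comments)
    emit("pbs_sliding", p("pbs_sliding.tsv"))

    collection = {go: set(grp["gene_id"])
                  for go, grp in gene_go.groupby("go_id")}
    for pop in cfg.branches:
        scorestbl = generank.score_genes(pbs_sliding, genes, pop)
        ranked = generank.rank_genes(scorestbl)
        vcfio.write_table(ranked, p(f"gene_scores_{pop}.tsv"))
        emit(f"gene_scores_{pop}", p(f"gene_scores_{pop}.tsv"))
        enr = generank.gsea(
            ranked, collection, n_perm=cfg.gsea.n_perm, seed=cfg.seed,
            weight=cfg.gsea.weight, min_size=cfg.gsea.min_size,
            max_size=cfg.gsea.max_size, branch=pop)
        vcfio.write_table(enr, p(f"enrichment_{pop}.tsv"))
        emit(f"enrichment_{pop}", p(f"enrichment_{pop}.tsv"))

    # -- stage 6: report + manifest ---------------------------------------
    _write_report(res, p("report.txt"))
    emit("report", p("report.txt"))
    manifest = {
        "config_hash": chash,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "artifacts": {k: {"path": os.path.basename(v), "sha256": _sha256(v)}
                      for k, v in sorted(res.artifacts.items())},
        "summary": _jsonable(res.summary),
    }
    with open(res.manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return res


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def _write_report(res: PipelineResult, path: str) -> None:
    s = res.summary
    cfg = res.config
    lines = [
        "nichescan run report",
        "====================",
        f"populations: focal {cfg.focal1}, {cfg.focal2}; outgroup {cfg.outgroup}",
        f"SNPs retained after hard filter: {s.get('n_snps_retained')}",
        f"genome-wide F_ST ({cfg.focal1} vs {cfg.focal2}, {cfg.estimator}): "
        f"unweighted {s.get('unweighted_fst'):.4g}, weighted {s.get('weighted_fst'):.4g}",
    ]
    for pop in (cfg.focal1, cfg.focal2):
        lines.append(
            f"{pop}: pi {s.get('pi_' + pop):.4g}, "
            f"Tajima's D {s.get('tajimas_d_' + pop):.3g}"
        )
    mp = s.get("mean_pbs", {})
    lines.append("mean PBS per branch: " + ", ".join(
        f"{k} {v:.4g}" for k, v in mp.items()))
    lines.append(f"PBS outlier windows (> {cfg.outlier_threshold}): "
                 f"{s.get('n_outlier_windows')}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
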