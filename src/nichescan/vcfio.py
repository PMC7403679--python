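"""File-format boundary: VCF v4.2, GFF3, population maps and track TSVs.

Internal coordinates are 0-based half-open; VCF POS (1-based) and GFF3
(1-based inclusive) are converted exactly here and nowhere else.
"""

from __future__ import annotations

import io
import os
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF, Writer

import gffutils

from .popgen import DataError, FilterReport, GenotypeMatrix, hard_filter_arrays

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path: str,
              contig_lengths: Mapping[str, int],
              info: pd.DataFrame | None = None) -> None:
    """Write a sorted biallelic VCF v4.2 (REF=A, ALT=T placeholder alleles).

    ``info`` may carry per-record QD/SOR/FS columns for filter testing.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##source=nichescan",
    ]
    for ctg, length in contig_lengths.items():
        lines.append(f"##contig=<ID={ctg},length={length}>")
    lines += [
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant Confidence/Quality by Depth">',
        '##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric Odds Ratio of 2x2 contingency table to detect strand bias">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled p-value using Fishers exact test to detect strand bias">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples),
    ]
    buf = io.StringIO()
    buf.write("\n".join(lines) + "\n")
    have_info = info is not None
    for i in range(gm.n_snps):
        if have_info:
            row = info.iloc[i]
            info_str = f"QD={row.qd:.4f};SOR={row.sor:.4f};FS={row.fs:.4f}"
        else:
            info_str = "."
        gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.geno[i])
        buf.write(
            f"{gm.contig[i]}\t{gm.pos[i] + 1}\t.\tA\tT\t.\t.\t{info_str}\tGT\t{gts}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_vcf(path: str, popmap: Mapping[str, str]) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read biallelic SNPs into a :class:`GenotypeMatrix` plus INFO table.

    Multi-allelic records are skipped (and counted in the returned table's
    ``attrs['n_skipped_multiallelic']``).  Samples absent from ``popmap``
    raise :class:`DataError`.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in popmap]
    if missing:
        raise DataError(f"samples missing from population map: {missing[:5]}")
    contigs, poss, genos = [], [], []
    qd, sor, fs = [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        contigs.append(var.CHROM)
        poss.append(var.POS - 1)  # to 0-based
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
        genos.append(dosage.astype(np.int8))
        qd.append(_info_float(var, "QD"))
        sor.append(_info_float(var, "SOR"))
        fs.append(_info_float(var, "FS"))
    vcf.close()
    if not poss:
        raise DataError(f"no biallelic SNPs in {path}")
    gm = GenotypeMatrix(
        contig=np.asarray(contigs, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        geno=np.vstack(genos),
        samples=samples,
        sample_pops=np.asarray([popmap[s] for s in samples], dtype=object),
    )
    info = pd.DataFrame({"qd": qd, "sor": sor, "fs": fs})
    info.attrs["n_skipped_multiallelic"] = n_multi
    return gm, info


def _info_float(var, key: str) -> float:
    val = var.INFO.get(key)
    if val is None:
        return np.nan
    try:
        return float(val)
    except (TypeError, ValueError):
        return np.nan


def filter_vcf(in_path: str, out_path: str,
               missing_policy: str = "pass") -> FilterReport:
    """Stream a VCF through the hard filter, writing retained records."""
    vcf = VCF(in_path)
    qd, sor, fs = [], [], []
    for var in vcf:
        qd.append(_info_float(var, "QD"))
        sor.append(_info_float(var, "SOR"))
        fs.append(_info_float(var, "FS"))
    vcf.close()
    keep, report = hard_filter_arrays(qd, sor, fs, missing_policy)
    vcf = VCF(in_path)
    writer = Writer(out_path, vcf)
    for i, var in enumerate(vcf):
        if keep[i]:
            writer.write_record(var)
    writer.close()
    vcf.close()
    return report


# ---------------------------------------------------------------------------
# population map
# ---------------------------------------------------------------------------

def write_popmap(sample_pops: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for sample, pop in sample_pops.items():
            fh.write(f"{sample}\t{pop}\n")


def read_popmap(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    if df["sample"].duplicated().any():
        raise DataError(f"duplicate samples in population map {path}")
    return dict(zip(df["sample"], df["population"]))


# ---------------------------------------------------------------------------
# GFF3 / gene sets
# ---------------------------------------------------------------------------

def write_gff3(genes: pd.DataFrame, path: str) -> None:
    """Write gene features; ``genes`` has 0-based half-open start/end columns."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            attrs = f"ID={row.gene_id}"
            fh.write(
                f"{row.contig}\tnichescan\tgene\t{row.start + 1}\t{row.end}\t.\t+\t.\t{attrs}\n"
            )


def read_gff3(path: str, feature_type: str = "gene") -> pd.DataFrame:
    """Parse gene features into 0-based half-open intervals."""
    db = gffutils.create_db(path, dbfn=":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gene_id, feat.seqid, feat.start - 1, feat.end))
    if not rows:
        raise DataError(f"no {feature_type!r} features in {path}")
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end"])


def write_gene_go(gene_go: pd.DataFrame, path: str) -> None:
    """Two-column gene -> GO-term TSV (one row per assignment)."""
    gene_go[["gene_id", "go_id"]].to_csv(path, sep="\t", index=False, header=False)


def read_gene_go(path: str) -> dict[str, set[str]]:
    """Read a gene->GO TSV into a term -> gene-set collection."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "go_id"],
                     dtype=str, comment="#")
    collection: dict[str, set[str]] = {}
    for go_id, grp in df.groupby("go_id"):
        collection[go_id] = set(grp["gene_id"])
    return collection


# ---------------------------------------------------------------------------
# BED-like track TSVs
# ---------------------------------------------------------------------------

def write_track(df: pd.DataFrame, path: str, comments: list[str] | None = None) -> None:
    """Write a BED-like TSV with optional '#'-prefixed header comments."""
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_track(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
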