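"""Per-site and per-window population-genetic statistics.

Everything here operates on called diploid genotypes.  Coordinates are
0-based half-open throughout; conversion to/from the 1-based conventions of
VCF and GFF3 happens only at the I/O boundary (:mod:`nichescan.vcfio`).

Two F_ST estimators are provided and always labelled in output:

* ``hudson`` — Hudson's estimator in the ratio-of-averages form of
  Bhatia et al. (2013); the standard substrate for population branch
  statistics and robust to unequal sample sizes.
* ``weir-cockerham`` — Weir & Cockerham (1984) variance components
  (a, b, c) computed from genotype counts including observed heterozygosity.

"Weighted" window values are the ratio of summed numerator components to
summed denominator components; "unweighted" values are the mean of per-site
ratios over sites with a positive denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "AlleleCounts",
    "WindowSet",
    "FstTrack",
    "FilterReport",
    "allele_counts",
    "hudson_site",
    "weir_cockerham_site",
    "site_components",
    "make_windows",
    "window_fst",
    "genome_wide_fst",
    "nucleotide_diversity",
    "tajimas_d",
    "hard_filter_arrays",
]

MISSING = -1
#: sites where any population has fewer called alleles than this are skipped
MIN_ALLELES = 4


class DataError(ValueError):
    """Raised when input data violate the contracts of an operation."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes with population labels.

    ``geno`` holds derived-allele dosages (0, 1, 2) with ``-1`` for missing,
    shaped (n_snps, n_samples).  SNP coordinates are sorted and unique per
    contig; every sample belongs to exactly one population.
    """

    contig: np.ndarray          # (n_snps,) str
    pos: np.ndarray             # (n_snps,) int64, 0-based
    geno: np.ndarray            # (n_snps, n_samples) int8
    samples: list[str]
    sample_pops: np.ndarray     # (n_samples,) str

    def __post_init__(self) -> None:
        self.contig = np.asarray(self.contig, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.sample_pops = np.asarray(self.sample_pops, dtype=object)
        if self.geno.shape != (len(self.pos), len(self.samples)):
            raise DataError("genotype matrix shape does not match coordinates/samples")
        for ctg in pd.unique(self.contig):
            p = self.pos[self.contig == ctg]
            if np.any(np.diff(p) <= 0):
                raise DataError(f"positions not sorted/unique on {ctg}")

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.sample_pops))

    def pop_columns(self, pop: str) -> np.ndarray:
        idx = np.flatnonzero(self.sample_pops == pop)
        if idx.size == 0:
            raise DataError(f"no samples in population {pop!r}")
        return idx


@dataclass
class AlleleCounts:
    """Per-SNP per-population derived-allele counts.

    ``counts``/``totals``/``hets`` are (n_snps, n_pops); totals are twice the
    number of non-missing genotypes (always even), ``hets`` the number of
    heterozygous genotypes (needed by the Weir–Cockerham estimator).
    """

    contig: np.ndarray
    pos: np.ndarray
    populations: list[str]
    counts: np.ndarray
    totals: np.ndarray
    hets: np.ndarray

    def pop_index(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise DataError(f"unknown population {pop!r}") from None

    @property
    def n_snps(self) -> int:
        return len(self.pos)


def allele_counts(gm: GenotypeMatrix, populations: Sequence[str] | None = None) -> AlleleCounts:
    """Tally derived-allele counts, called totals and het counts per population."""
    pops = list(populations) if populations is not None else gm.populations
    S = gm.n_snps
    counts = np.zeros((S, len(pops)), dtype=np.int64)
    totals = np.zeros((S, len(pops)), dtype=np.int64)
    hets = np.zeros((S, len(pops)), dtype=np.int64)
    for j, pop in enumerate(pops):
        cols = gm.pop_columns(pop)
        g = gm.geno[:, cols]
        called = g >= 0
        counts[:, j] = np.where(called, g, 0).sum(axis=1)
        totals[:, j] = 2 * called.sum(axis=1)
        hets[:, j] = (g == 1).sum(axis=1)
    return AlleleCounts(gm.contig.copy(), gm.pos.copy(), pops, counts, totals, hets)


# ---------------------------------------------------------------------------
# per-site F_ST components
# ---------------------------------------------------------------------------

def hudson_site(count1, total1, count2, total2):
    """Hudson per-site F_ST components (numerator, denominator).

    With sample frequencies ``p_i = count_i/total_i`` and allele totals
    ``n_i``::

        num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        den = p1(1-p2) + p2(1-p1)

    Sites where either total is below :data:`MIN_ALLELES` contribute (0, 0).
    A zero denominator (both populations fixed for the same allele) also
    contributes (0, 0) and is excluded from unweighted window means.
    """
    c1 = np.asarray(count1, dtype=float)
    c2 = np.asarray(count2, dtype=float)
    n1 = np.asarray(total1, dtype=float)
    n2 = np.asarray(total2, dtype=float)
    ok = (n1 >= MIN_ALLELES) & (n2 >= MIN_ALLELES)
    n1s = np.where(ok, n1, 2.0)  # placeholder avoids 0/0 warnings
    n2s = np.where(ok, n2, 2.0)
    p1 = np.where(ok, c1 / n1s, 0.0)
    p2 = np.where(ok, c2 / n2s, 0.0)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1s - 1) - p2 * (1 - p2) / (n2s - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(ok & (den > 0), num, 0.0)
    den = np.where(ok & (den > 0), den, 0.0)
    return num, den


def weir_cockerham_site(count1, total1, het1, count2, total2, het2):
    """Weir & Cockerham (1984) two-population variance components.

    Returns (a, a+b+c): the among-population component and the total, from
    which theta = a / (a+b+c).  ``het_i`` is the observed heterozygote count;
    individuals genotyped ``n_i = total_i / 2``.
    """
    n1 = np.asarray(total1, dtype=float) / 2.0
    n2 = np.asarray(total2, dtype=float) / 2.0
    ok = (np.asarray(total1) >= MIN_ALLELES) & (np.asarray(total2) >= MIN_ALLELES)
    n1 = np.where(ok, n1, 2.0)
    n2 = np.where(ok, n2, 2.0)
    p1 = np.asarray(count1, dtype=float) / (2 * n1)
    p2 = np.asarray(count2, dtype=float) / (2 * n2)
    h1 = np.asarray(het1, dtype=float) / n1
    h2 = np.asarray(het2, dtype=float) / n2
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    c = hbar / 2
    num = a
    den = a + b + c
    bad = ~ok | ~np.isfinite(den) | (den <= 0)
    num = np.where(bad, 0.0, num)
    den = np.where(bad, 0.0, den)
    return num, den


def site_components(counts: AlleleCounts, pop1: str, pop2: str, estimator: str = "hudson"):
    """Per-site (numerator, denominator) for a population pair."""
    i, j = counts.pop_index(pop1), counts.pop_index(pop2)
    if estimator == "hudson":
        return hudson_site(
            counts.counts[:, i], counts.totals[:, i],
            counts.counts[:, j], counts.totals[:, j],
        )
    if estimator == "weir-cockerham":
        return weir_cockerham_site(
            counts.counts[:, i], counts.totals[:, i], counts.hets[:, i],
            counts.counts[:, j], counts.totals[:, j], counts.hets[:, j],
        )
    raise DataError(f"unknown estimator {estimator!r}")


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass
class WindowSet:
    """Half-open 0-based genomic windows of fixed size and step."""

    contig: np.ndarray
    start: np.ndarray
    end: np.ndarray
    partial: np.ndarray
    size: int
    step: int

    def __len__(self) -> int:
        return len(self.start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"contig": self.contig, "start": self.start, "end": self.end,
             "partial": self.partial}
        )


def make_windows(contig_lengths: Mapping[str, int], size: int, step: int | None = None) -> WindowSet:
    """Tile windows over contigs.

    ``step is None`` or ``step == size`` gives the non-overlapping scan mode,
    in which a terminal partial window is emitted (flagged).  A smaller step
    gives sliding mode with full-size windows only (``size`` must be a
    multiple of ``step``).  A contig shorter than ``size`` yields a single
    partial window covering the whole contig.
    """
    if step is None:
        step = size
    if size <= 0 or step <= 0 or step > size:
        raise DataError("need 0 < step <= size")
    if size % step != 0:
        raise DataError("window size must be a multiple of the step")
    ctgs, starts, ends = [], [], []
    for ctg, length in contig_lengths.items():
        if length <= 0:
            raise DataError(f"non-positive length for contig {ctg!r}")
        if length < size:
            ctgs.append(ctg); starts.append(0); ends.append(length)
            continue
        if step == size:
            s = np.arange(0, length, size)
        else:
            s = np.arange(0, length - size + 1, step)
        e = np.minimum(s + size, length)
        ctgs.extend([ctg] * len(s)); starts.extend(s); ends.extend(e)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    return WindowSet(
        contig=np.asarray(ctgs, dtype=object),
        start=starts,
        end=ends,
        partial=(ends - starts) < size,
        size=size,
        step=step,
    )


def _window_sums(windows: WindowSet, contig: np.ndarray, pos: np.ndarray,
                 values: np.ndarray) -> np.ndarray:
    """Sum per-site ``values`` (n_sites, k) into each window; returns (n_windows, k).

    Works for both scan and sliding modes; a site falling in several sliding
    windows contributes to each.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != len(pos):
        values = values.T
    out = np.zeros((len(windows), values.shape[1]))
    n_cover = windows.size // windows.step
    wdf = windows.to_frame()
    for ctg, widx in wdf.groupby("contig", sort=False).groups.items():
        widx = np.asarray(widx)
        sel = np.flatnonzero(contig == ctg)
        if sel.size == 0:
            continue
        p = pos[sel]
        v = values[sel]
        w0 = int(windows.start[widx[0]])  # starts form a grid w0 + k*step
        base = (p - w0) // windows.step
        for j in range(n_cover):
            k = base - j
            keep = (k >= 0) & (k < len(widx))
            if not np.any(keep):
                continue
            kk = k[keep]
            # guard: site must actually fall inside the window interval
            inside = (p[keep] >= windows.start[widx[kk]].astype(np.int64)) & (
                p[keep] < windows.end[widx[kk]].astype(np.int64))
            kk = kk[inside]
            vv = v[keep][inside]
            for col in range(values.shape[1]):
                out[widx, col] += np.bincount(kk, weights=vv[:, col], minlength=len(widx))
    return out


def default_min_sites(window_size: int) -> int:
    """Default site minimum: 5 for >= 2-kb scan windows, 2 for short sliding windows."""
    return 5 if window_size >= 2000 else 2


# ---------------------------------------------------------------------------
# F_ST tracks
# ---------------------------------------------------------------------------

@dataclass
class FstTrack:
    """Per-window F_ST values plus their numerator/denominator sums."""

    df: pd.DataFrame            # contig, start, end, n_sites, num_sum, den_sum, fst, valid
    estimator: str
    mode: str
    pair: tuple[str, str]
    window_size: int = 0
    window_step: int = 0

    @property
    def valid(self) -> pd.DataFrame:
        return self.df[self.df["valid"]]

    def same_windows(self, other: "FstTrack") -> bool:
        a, b = self.df, other.df
        return (
            len(a) == len(b)
            and (a["contig"].values == b["contig"].values).all()
            and (a["start"].values == b["start"].values).all()
            and (a["end"].values == b["end"].values).all()
        )


def window_fst(counts: AlleleCounts, pop1: str, pop2: str, windows: WindowSet,
               estimator: str = "hudson", mode: str = "weighted",
               min_sites: int | None = None) -> FstTrack:
    """Aggregate per-site F_ST components into windows.

    ``n_sites`` counts sites with a positive denominator; windows with fewer
    than ``min_sites`` such sites are emitted but flagged invalid.
    """
    if mode not in ("weighted", "unweighted"):
        raise DataError(f"unknown mode {mode!r}")
    if min_sites is None:
        min_sites = default_min_sites(windows.size)
    num, den = site_components(counts, pop1, pop2, estimator)
    usable = den > 0
    with np.errstate(invalid="ignore"):
        ratio = np.where(usable, num / np.where(usable, den, 1.0), 0.0)
    sums = _window_sums(
        windows, counts.contig, counts.pos,
        np.column_stack([num, den, usable.astype(float), ratio]),
    )
    num_sum, den_sum, n_sites, ratio_sum = sums.T
    n_sites = n_sites.astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        weighted = np.where(den_sum > 0, num_sum / np.where(den_sum > 0, den_sum, 1.0), np.nan)
        unweighted = np.where(n_sites > 0, ratio_sum / np.maximum(n_sites, 1), np.nan)
    fst = weighted if mode == "weighted" else unweighted
    df = windows.to_frame().drop(columns="partial")
    df["n_sites"] = n_sites
    df["num_sum"] = num_sum
    df["den_sum"] = den_sum
    df["fst"] = fst
    df["valid"] = (n_sites >= min_sites) & np.isfinite(fst)
    return FstTrack(df, estimator, mode, (pop1, pop2), windows.size, windows.step)


def genome_wide_fst(counts: AlleleCounts, pop1: str, pop2: str,
                    estimator: str = "hudson") -> tuple[float, float]:
    """Genome-wide (unweighted, weighted) F_ST over all usable sites."""
    num, den = site_components(counts, pop1, pop2, estimator)
    usable = den > 0
    if not np.any(usable):
        raise DataError("no usable sites")
    weighted = float(num[usable].sum() / den[usable].sum())
    unweighted = float(np.mean(num[usable] / den[usable]))
    return unweighted, weighted


# ---------------------------------------------------------------------------
# diversity and Tajima's D
# ---------------------------------------------------------------------------

def nucleotide_diversity(counts: AlleleCounts, pop: str, windows: WindowSet) -> pd.DataFrame:
    """Per-window nucleotide diversity pi.

    Per site the unbiased heterozygosity ``2 p (1-p) n/(n-1)`` (n = called
    alleles); the window value divides the summed site values by the full
    window span in bp (an all-sites denominator: invariant sites contribute
    zero diversity but full span).
    """
    j = counts.pop_index(pop)
    t = counts.totals[:, j].astype(float)
    ok = t >= 2
    ts = np.where(ok, t, 2.0)
    p = np.where(ok, counts.counts[:, j] / ts, 0.0)
    h = np.where(ok, 2.0 * p * (1 - p) * ts / (ts - 1), 0.0)
    sums = _window_sums(windows, counts.contig, counts.pos,
                        np.column_stack([h, ok.astype(float)]))
    df = windows.to_frame().drop(columns="partial")
    span = (df["end"] - df["start"]).to_numpy(dtype=float)
    df["n_sites"] = sums[:, 1].astype(int)
    df["pi"] = sums[:, 0] / span
    return df


def _tajima_constants(n: int) -> dict[str, float]:
    """Classical sample-size constants for Tajima's D (n = alleles sampled)."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(counts: AlleleCounts, pop: str, windows: WindowSet,
              min_segregating: int = 3) -> pd.DataFrame:
    """Per-window Tajima's D.

    ``D = (pi_sum - S/a1) / sqrt(e1 S + e2 S (S-1))`` with the classical
    constants evaluated at the window's mean called-allele count (rounded).
    Windows with fewer than ``min_segregating`` segregating sites, or with
    n < 4 alleles, are reported as NaN.
    """
    j = counts.pop_index(pop)
    t = counts.totals[:, j].astype(float)
    c = counts.counts[:, j].astype(float)
    seg = (t >= MIN_ALLELES) & (c > 0) & (c < t)
    ts = np.where(seg, t, 2.0)
    p = np.where(seg, c / ts, 0.0)
    h = np.where(seg, 2.0 * p * (1 - p) * ts / (ts - 1), 0.0)
    sums = _window_sums(
        windows, counts.contig, counts.pos,
        np.column_stack([h, seg.astype(float), np.where(seg, t, 0.0)]),
    )
    pi_sum, S, t_sum = sums.T
    df = windows.to_frame().drop(columns="partial")
    D = np.full(len(df), np.nan)
    for w in range(len(df)):
        s = S[w]
        if s < max(min_segregating, 1):
            continue
        n = int(round(t_sum[w] / s))
        if n < 4:
            continue
        k = _tajima_constants(n)
        var = k["e1"] * s + k["e2"] * s * (s - 1)
        if var <= 0:
            continue
        D[w] = (pi_sum[w] - s / k["a1"]) / np.sqrt(var)
    df["n_segregating"] = S.astype(int)
    df["tajimas_d"] = D
    return df


# ---------------------------------------------------------------------------
# GATK-style hard filter
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Counts from one pass of the hard filter.

    Per-criterion counts tally every violation, so their sum can exceed
    ``n_removed`` when a record fails several criteria at once.
    """

    n_total: int = 0
    n_removed: int = 0
    removed_qd: int = 0
    removed_sor: int = 0
    removed_fs: int = 0
    n_missing: int = 0
    missing_policy: str = "pass"

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_removed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("total", self.n_total), ("retained", self.n_retained),
                ("removed", self.n_removed), ("removed_qd", self.removed_qd),
                ("removed_sor", self.removed_sor), ("removed_fs", self.removed_fs),
                ("records_with_missing_info", self.n_missing),
            ],
            columns=["category", "count"],
        )


def hard_filter_arrays(qd, sor, fs, missing_policy: str = "pass"):
    """Apply the hard-filter rule ``QD < 2.0 || SOR > 3.0 || FS > 200``.

    Returns (keep_mask, FilterReport).  NaN values are "missing":
    ``missing_policy='pass'`` treats a missing annotation as satisfying its
    criterion, ``'fail'`` as violating it.
    """
    if missing_policy not in ("pass", "fail"):
        raise DataError("missing_policy must be 'pass' or 'fail'")
    qd = np.asarray(qd, dtype=float)
    sor = np.asarray(sor, dtype=float)
    fs = np.asarray(fs, dtype=float)
    miss_default = missing_policy == "fail"
    bad_qd = np.where(np.isnan(qd), miss_default, qd < 2.0)
    bad_sor = np.where(np.isnan(sor), miss_default, sor > 3.0)
    bad_fs = np.where(np.isnan(fs), miss_default, fs > 200.0)
    removed = bad_qd | bad_sor | bad_fs
    report = FilterReport(
        n_total=len(qd),
        n_removed=int(removed.sum()),
        removed_qd=int(bad_qd.sum()),
        removed_sor=int(bad_sor.sum()),
        removed_fs=int(bad_fs.sum()),
        n_missing=int((np.isnan(qd) | np.isnan(sor) | np.isnan(fs)).sum()),
        missing_policy=missing_policy,
    )
    return ~removed, report
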