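"""Population branch statistics from pairwise F_ST tracks.

For three populations (A, B, O) with pairwise F_ST values transformed to
branch lengths ``T = -log(1 - F_ST)``, the population branch statistic of A
is ``PBS_A = (T_AB + T_AO - T_BO) / 2``: the amount of allele-frequency
change on A's own branch since its divergence from B, polarized by the
outgroup.  Identities used as invariants: ``PBS_A + PBS_B = T_AB`` and
``PBS_A + PBS_B + PBS_O = (T_AB + T_AO + T_BO) / 2``.

F_ST inputs are clamped to [0, 1 - 1e-6] before the log: negatives (noise
around zero divergence) map to branch length 0; values at the cap are kept
finite and flagged by the caller's raw track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import DataError, FstTrack

__all__ = [
    "branch_length",
    "pbs",
    "PbsTrack",
    "pbs_scan",
    "ZTrack",
    "zfst",
    "flag_outliers",
    "gene_profile",
]

FST_CAP = 1.0 - 1e-6


def branch_length(fst):
    """Divergence branch length ``T = -log(1 - F_ST)``, clamped to [0, cap]."""
    f = np.clip(np.asarray(fst, dtype=float), 0.0, FST_CAP)
    return -np.log1p(-f)


def pbs(t12, t13, t23):
    """All three branch values from the pairwise branch lengths.

    Arguments are T between populations (1,2), (1,3) and (2,3); returns
    (PBS_1, PBS_2, PBS_3).
    """
    t12 = np.asarray(t12, dtype=float)
    t13 = np.asarray(t13, dtype=float)
    t23 = np.asarray(t23, dtype=float)
    pbs1 = (t12 + t13 - t23) / 2.0
    pbs2 = (t12 + t23 - t13) / 2.0
    pbs3 = (t13 + t23 - t12) / 2.0
    return pbs1, pbs2, pbs3


@dataclass
class PbsTrack:
    """Per-window PBS for each branch of the three-population tree."""

    df: pd.DataFrame         # contig,start,end,n_sites,fst_*,pbs_<pop>...,valid
    branches: tuple[str, str, str]
    window_size: int = 0
    window_step: int = 0

    @property
    def valid(self) -> pd.DataFrame:
        return self.df[self.df["valid"]]

    def branch_means(self) -> dict[str, float]:
        """Genome-wide mean PBS per branch over valid windows."""
        v = self.valid
        return {b: float(v[f"pbs_{b}"].mean()) for b in self.branches}


def pbs_scan(track12: FstTrack, track13: FstTrack, track23: FstTrack) -> PbsTrack:
    """Per-window PBS from three pairwise F_ST tracks on one window set.

    Track pairs must cover populations (1,2), (1,3), (2,3) consistently and
    share identical windows; PBS is defined only where all three window
    values are valid.
    """
    if not (track12.same_windows(track13) and track12.same_windows(track23)):
        raise DataError("F_ST tracks are not on identical window sets")
    p1, p2 = track12.pair
    p1b, p3 = track13.pair
    p2b, p3b = track23.pair
    if p1 != p1b or p2 != p2b or p3 != p3b:
        raise DataError(
            "track pairs must be (A,B), (A,O), (B,O); got "
            f"{track12.pair}, {track13.pair}, {track23.pair}"
        )
    f12 = track12.df["fst"].to_numpy()
    f13 = track13.df["fst"].to_numpy()
    f23 = track23.df["fst"].to_numpy()
    valid = (
        track12.df["valid"].to_numpy(dtype=bool)
        & track13.df["valid"].to_numpy(dtype=bool)
        & track23.df["valid"].to_numpy(dtype=bool)
    )
    b1, b2, b3 = pbs(branch_length(f12), branch_length(f13), branch_length(f23))
    df = track12.df[["contig", "start", "end", "n_sites"]].copy()
    df[f"fst_{p1}_{p2}"] = f12
    df[f"fst_{p1}_{p3}"] = f13
    df[f"fst_{p2}_{p3}"] = f23
    for name, vals in zip((p1, p2, p3), (b1, b2, b3)):
        df[f"pbs_{name}"] = np.where(valid, vals, np.nan)
    df["valid"] = valid
    return PbsTrack(df, (p1, p2, p3), track12.window_size, track12.window_step)


@dataclass
class ZTrack:
    """z-standardized window F_ST with one-sided upper-tail p-values."""

    df: pd.DataFrame         # contig,start,end,fst,zfst,pvalue,valid
    mean: float
    sd: float


def zfst(track: FstTrack) -> ZTrack:
    """Standardize window F_ST by the genome-wide mean/SD of valid windows.

    ``z = (F_ST - mean) / sd``; ``p`` is the one-sided upper-tail standard
    normal probability at z.  Ranking by z is identical to ranking by raw
    F_ST (strictly monotone transform).
    """
    vals = track.df["fst"].to_numpy(dtype=float)
    valid = track.df["valid"].to_numpy() & np.isfinite(vals)
    if valid.sum() < 2:
        raise DataError("need >= 2 valid windows to standardize")
    mean = float(vals[valid].mean())
    sd = float(vals[valid].std(ddof=0))
    if sd == 0:
        raise DataError("zero variance across windows; zF_ST undefined")
    z = np.where(valid, (vals - mean) / sd, np.nan)
    df = track.df[["contig", "start", "end", "fst"]].copy()
    df["zfst"] = z
    df["pvalue"] = np.where(valid, stats.norm.sf(z), np.nan)
    df["valid"] = valid
    return ZTrack(df, mean, sd)


def flag_outliers(track: PbsTrack, threshold: float = 0.05) -> pd.DataFrame:
    """Windows whose focal-branch PBS exceeds ``threshold``.

    Classes mirror the scan scatterplot: ``focal1-only``, ``focal2-only``
    or ``both``, judged on the first two branches of the track.
    """
    focal1, focal2 = track.branches[:2]
    v = track.valid
    e1 = v[f"pbs_{focal1}"] > threshold
    e2 = v[f"pbs_{focal2}"] > threshold
    out = v[e1 | e2].copy()
    cls = np.where(
        e1[e1 | e2] & e2[e1 | e2], "both",
        np.where(e1[e1 | e2], f"{focal1}-only", f"{focal2}-only"),
    )
    out["outlier_class"] = cls
    return out.reset_index(drop=True)


def gene_profile(track: PbsTrack, contig: str, start: int, end: int,
                 branch: str, flank: int = 0) -> pd.DataFrame:
    """Sliding-window PBS profile across a gene body (± flank).

    Returns the ordered windows overlapping [start - flank, end + flank) on
    ``contig`` with an ``argmax`` flag on the peak window (ties broken by
    the smallest start coordinate).  Only valid windows compete for the peak.
    """
    if branch not in track.branches:
        raise DataError(f"unknown branch {branch!r}")
    lo, hi = start - flank, end + flank
    df = track.df
    sel = (df["contig"] == contig) & (df["start"] < hi) & (df["end"] > lo)
    prof = df[sel].sort_values("start").reset_index(drop=True)
    col = f"pbs_{branch}"
    prof["argmax"] = False
    valid = prof[prof["valid"]]
    if not valid.empty:
        peak = valid[col].to_numpy()
        best = valid.index[int(np.argmax(peak))]  # argmax takes first on ties
        prof.loc[best, "argmax"] = True
    return prof
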