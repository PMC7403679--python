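"""Per-gene divergence scores and ranked gene-set enrichment.

A gene's divergence score on a branch is the maximum PBS among sliding
windows overlapping the gene body (>= 1 bp intersection of half-open
intervals).  Enrichment is the cutoff-free weighted Kolmogorov–Smirnov
statistic of Subramanian et al.: walking down the ranked list, member genes
("hits") increment the running sum by |score|^p normalized over the in-set
sum, non-members decrement by 1/(N - N_hit); ES is the signed maximum
deviation.  The null is gene-label permutation: one permutation of the
gene labels per iteration, shared across all terms so inter-term overlap
structure is preserved.  NES divides ES by the mean |null ES| of matching
sign; FDR q follows the sign-stratified NES-comparison procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .branch import PbsTrack
from .popgen import DataError

__all__ = [
    "score_genes",
    "rank_genes",
    "EnrichmentScore",
    "enrichment_score",
    "gsea",
]


# ---------------------------------------------------------------------------
# gene scoring and ranking
# ---------------------------------------------------------------------------

def score_genes(track: PbsTrack, genes: pd.DataFrame, branch: str) -> pd.DataFrame:
    """Max-PBS divergence score per gene on one branch.

    ``genes`` carries gene_id/contig/start/end (0-based half-open).  Genes
    with no valid overlapping window — including genes on contigs absent
    from the track — are flagged ``scored=False``.
    """
    if branch not in track.branches:
        raise DataError(f"unknown branch {branch!r}")
    col = f"pbs_{branch}"
    tdf = track.df
    out = genes[["gene_id", "contig", "start", "end"]].copy()
    scores = np.full(len(genes), np.nan)
    n_windows = np.zeros(len(genes), dtype=int)
    for ctg, widx in tdf.groupby("contig", sort=False).groups.items():
        wsub = tdf.loc[widx]
        wstart = wsub["start"].to_numpy()
        wend = wsub["end"].to_numpy()
        wval = wsub[col].to_numpy()
        wok = wsub["valid"].to_numpy()
        gsel = np.flatnonzero(genes["contig"].to_numpy() == ctg)
        for gi in gsel:
            gs, ge = out["start"].iat[gi], out["end"].iat[gi]
            # windows sorted by start with sorted ends: overlap iff end>gs and start<ge
            first = np.searchsorted(wend, gs, side="right")
            last = np.searchsorted(wstart, ge, side="left")
            if last <= first:
                continue
            ok = wok[first:last]
            n_windows[gi] = int(ok.sum())
            if n_windows[gi]:
                scores[gi] = float(np.max(wval[first:last][ok]))
    out["branch"] = branch
    out["score"] = scores
    out["n_windows"] = n_windows
    out["scored"] = n_windows > 0
    return out


def rank_genes(table: pd.DataFrame) -> pd.DataFrame:
    """Rank genes from most to least diverged.

    Descending by score with a stable lexicographic gene-ID tie-break;
    unscored genes are excluded (their count is in ``attrs['n_unscored']``).
    """
    scored = table[table["scored"]].copy()
    ranked = scored.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranked.attrs["n_unscored"] = int((~table["scored"]).sum())
    return ranked


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentScore:
    es: float
    running: np.ndarray
    leading_edge: list[str]
    hit_positions: np.ndarray


def _es_batch(scores: np.ndarray, hits: np.ndarray, weight: float):
    """Vectorized running-sum ES for a batch of hit indicator rows.

    ``scores`` (N,) are the ranked scores (descending); ``hits`` is a
    boolean (B, N) matrix.  Returns (es (B,), running (B, N)).
    """
    B, N = hits.shape
    k = hits.sum(axis=1)
    if np.any(k == 0) or np.any(k == N):
        raise DataError("gene set must hit a strict, non-empty subset of the list")
    w = np.abs(scores) ** weight if weight != 0 else np.ones_like(scores, dtype=float)
    wh = hits * w[None, :]
    tot = wh.sum(axis=1)
    # degenerate all-zero hit weights: fall back to unweighted increments
    flat = tot == 0
    if np.any(flat):
        wh[flat] = hits[flat].astype(float)
        tot[flat] = k[flat]
    inc = wh / tot[:, None]
    dec = (~hits) / (N - k)[:, None]
    running = np.cumsum(inc - dec, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    es = running[np.arange(B), idx]
    return es, running


def enrichment_score(ranked: pd.DataFrame, gene_set, weight: float = 1.0) -> EnrichmentScore:
    """ES of one gene set against a ranked gene table.

    The leading edge contains set members at/before the running-sum
    extremum for positive ES, and at/after it for negative ES.
    """
    ids = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    hits = np.isin(ids, list(gene_set))
    if not hits.any():
        raise DataError("gene set does not intersect the ranked list")
    es, running = _es_batch(scores, hits[None, :], weight)
    es = float(es[0])
    running = running[0]
    ext = int(np.argmax(np.abs(running)))
    pos = np.flatnonzero(hits)
    if es >= 0:
        edge = ids[pos[pos <= ext]]
    else:
        edge = ids[pos[pos >= ext]]
    return EnrichmentScore(es, running, list(edge), pos)


# ---------------------------------------------------------------------------
# GSEA with permutation null
# ---------------------------------------------------------------------------

def gsea(ranked: pd.DataFrame, collection: dict, n_perm: int = 1000,
         seed: int = 0, weight: float = 1.0, min_size: int = 10,
         max_size: int = 500, branch: str | None = None,
         term_names: dict | None = None) -> pd.DataFrame:
    """Ranked gene-set enrichment over a GO-term collection.

    Returns one row per term within the size bounds, with ES, NES, nominal
    permutation p and FDR q.  Terms outside the bounds are reported in
    ``attrs['skipped_terms']``.  Output is deterministic under a fixed seed.
    """
    if n_perm < 100:
        import warnings
        warnings.warn(f"n_perm={n_perm} is low; p and q estimates will be coarse")
    ids = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    N = len(ids)
    pos_of = {g: i for i, g in enumerate(ids)}
    terms, hit_idx, skipped = [], [], []
    for term in sorted(collection):
        members = [pos_of[g] for g in collection[term] if g in pos_of]
        size = len(members)
        if size < min_size or size > max_size or size == N:
            skipped.append((term, size))
            continue
        terms.append(term)
        hit_idx.append(np.sort(np.asarray(members)))
    if not terms:
        out = pd.DataFrame(columns=["go_id", "go_name", "size", "es", "nes",
                                    "pval", "fdr_q", "branch"])
        out.attrs["skipped_terms"] = skipped
        return out

    rng = np.random.default_rng(seed)
    # one gene-label permutation per iteration, shared by every term
    perm_pos = np.argsort(rng.random((n_perm, N)), axis=1)

    rows = []
    null_nes_all = []
    obs_nes = []
    for term, idx in zip(terms, hit_idx):
        hits = np.zeros(N, dtype=bool)
        hits[idx] = True
        es_obs, _ = _es_batch(scores, hits[None, :], weight)
        es_obs = float(es_obs[0])
        ph = np.zeros((n_perm, N), dtype=bool)
        np.put_along_axis(ph, perm_pos[:, idx], True, axis=1)
        es_null, _ = _es_batch(scores, ph, weight)
        pos_null = es_null[es_null >= 0]
        neg_null = es_null[es_null < 0]
        if es_obs >= 0:
            same = pos_null
            p = (1 + int((same >= es_obs).sum())) / (1 + len(same)) if len(same) else 1.0
            denom = same.mean() if len(same) else np.nan
        else:
            same = neg_null
            p = (1 + int((same <= es_obs).sum())) / (1 + len(same)) if len(same) else 1.0
            denom = np.abs(same).mean() if len(same) else np.nan
        nes = es_obs / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        # normalize the whole null by the sign-matched means for FDR pooling
        mp = pos_null.mean() if len(pos_null) else np.nan
        mn = np.abs(neg_null).mean() if len(neg_null) else np.nan
        nn = np.where(es_null >= 0, es_null / mp, es_null / mn)
        null_nes_all.append(nn[np.isfinite(nn)])
        obs_nes.append(nes)
        rows.append({"go_id": term,
                     "go_name": (term_names or {}).get(term, term),
                     "size": len(idx), "es": es_obs, "nes": nes, "pval": p})

    out = pd.DataFrame(rows)
    out["fdr_q"] = _fdr_q(np.asarray(obs_nes, dtype=float),
                          np.concatenate(null_nes_all))
    out["branch"] = branch
    out = out.sort_values(["nes"], ascending=False, ignore_index=True)
    out.attrs["skipped_terms"] = skipped
    return out


def _fdr_q(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Sign-stratified FDR q over NES values.

    For a positive NES* the q-value is the ratio of the fraction of
    positive null NES >= NES* to the fraction of positive observed
    NES >= NES* (symmetrically for negative), clipped to [0, 1] and made
    monotone in |NES| within each sign.
    """
    q = np.full(len(obs_nes), np.nan)
    for sign in (1, -1):
        if sign > 0:
            o_idx = np.flatnonzero(obs_nes >= 0)
            nulls = null_nes[null_nes >= 0]
            o = obs_nes[o_idx]
        else:
            o_idx = np.flatnonzero(obs_nes < 0)
            nulls = -null_nes[null_nes < 0]
            o = -obs_nes[o_idx]
        if len(o_idx) == 0:
            continue
        for j, val in zip(o_idx, o):
            if not np.isfinite(val):
                q[j] = np.nan
                continue
            frac_null = (nulls >= val).mean() if len(nulls) else np.nan
            frac_obs = (o >= val).mean()
            q[j] = min(1.0, frac_null / frac_obs) if frac_obs > 0 else np.nan
        # monotone: a term may claim the smallest estimated FDR among all
        # thresholds at or below its own NES (cumulative min from the
        # least-extreme end), so a more extreme NES never has a larger q
        order = np.argsort(-o)
        qq = q[o_idx[order]]
        q[o_idx[order]] = np.minimum.accumulate(qq[::-1])[::-1]
    return q
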