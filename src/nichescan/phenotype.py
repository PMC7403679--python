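"""Phenotype metrics: egg volume, carcass-use efficiency, reaction norms.

Reaction norms are summarized per split-brood dyad as an elevation (the
cross-treatment mean of the trait) and a slope (large-carcass value minus
small-carcass value); population contrasts on either component use
permutation inference over dyad labels, exact by exhaustive enumeration
whenever the number of distinct label assignments is small enough.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .popgen import DataError
from .simulate import BroodArm, BroodDyad

__all__ = [
    "egg_volume",
    "carcass_efficiency",
    "reaction_norms",
    "ContrastResult",
    "permutation_contrast",
    "relative_abundance",
]

TRAITS = ("clutch_size", "brood_size", "egg_volume", "efficiency")


def egg_volume(length, width):
    """Egg volume in mm^3 for a prolate spheroid: ``V = pi/6 * w^2 * L``.

    Length and width in mm, with ``L >= w >= 0`` (a sphere when L == w).
    """
    L = np.asarray(length, dtype=float)
    w = np.asarray(width, dtype=float)
    if np.any(w < 0) or np.any(L < w):
        raise DataError("need L >= w >= 0")
    return np.pi / 6.0 * w ** 2 * L


def carcass_efficiency(total_brood_mass, carcass_mass, n_obs: int = 1):
    """Carcass-use efficiency E = brood mass / carcass mass, with its logit.

    At the boundaries E in {0, 1} (and for E > 1, which a very productive
    brood can technically reach) the empirical-logit shrinkage
    ``eps = 1/(2 n_obs)`` is applied before the log-odds; such values are
    flagged in the third return element.
    """
    brood = np.asarray(total_brood_mass, dtype=float)
    carcass = np.asarray(carcass_mass, dtype=float)
    if np.any(carcass <= 0):
        raise DataError("carcass mass must be positive")
    if np.any(brood < 0):
        raise DataError("brood mass cannot be negative")
    eff = brood / carcass
    eps = 1.0 / (2.0 * max(int(n_obs), 1))
    boundary = (eff <= 0.0) | (eff >= 1.0)
    shrunk = np.where(boundary, np.clip(eff, eps, 1.0 - eps), eff)
    logit = np.log(shrunk / (1.0 - shrunk))
    return eff, logit, boundary


def _arm_value(arm: BroodArm, trait: str) -> float | None:
    if trait == "clutch_size":
        return float(arm.clutch_size)
    if trait == "brood_size":
        return float(arm.brood_size)
    if trait == "efficiency":
        if arm.carcass_mass <= 0:
            return None
        return float(arm.brood_mass / arm.carcass_mass)
    if trait == "egg_volume":
        if not arm.egg_lengths:
            return None
        return float(np.mean(egg_volume(arm.egg_lengths, arm.egg_widths)))
    raise DataError(f"unknown trait {trait!r}; choose one of {TRAITS}")


def reaction_norms(dyads: list[BroodDyad], trait: str) -> pd.DataFrame:
    """Elevation/slope summaries, one row per complete dyad.

    Elevation is the mean of the small- and large-carcass values, slope the
    large minus small difference; the decomposition is invertible
    (small = elevation - slope/2, large = elevation + slope/2).  Dyads with
    a missing arm or an unmeasurable trait (breeding failures) are excluded;
    their count lands in ``attrs['n_excluded']``.
    """
    rows = []
    n_excluded = 0
    for d in dyads:
        if not d.complete:
            n_excluded += 1
            continue
        small = _arm_value(d.small, trait)
        large = _arm_value(d.large, trait)
        if small is None or large is None:
            n_excluded += 1
            continue
        rows.append({
            "dyad_id": d.dyad_id,
            "population": d.population,
            "block": d.block,
            "trait": trait,
            "small": small,
            "large": large,
            "elevation": (small + large) / 2.0,
            "slope": large - small,
        })
    out = pd.DataFrame(rows, columns=["dyad_id", "population", "block", "trait",
                                      "small", "large", "elevation", "slope"])
    out.attrs["n_excluded"] = n_excluded
    return out


@dataclass
class ContrastResult:
    component: str
    group_a: str
    group_b: str
    observed: float          # mean(A) - mean(B)
    pvalue: float
    n_perm: int
    exhaustive: bool


def permutation_contrast(summaries: pd.DataFrame, component: str,
                         n_perm: int = 10_000, seed: int = 0,
                         group_col: str = "population") -> ContrastResult:
    """Two-sided permutation test of a group difference in elevation or slope.

    The observed statistic is the difference of group means.  When the
    number of distinct label assignments C(n, n_A) is at most ``n_perm``
    the p-value is exact (all assignments enumerated); otherwise it is the
    add-one Monte-Carlo estimate over ``n_perm`` seeded shuffles.
    """
    if component not in summaries.columns:
        raise DataError(f"no component column {component!r}")
    groups = sorted(summaries[group_col].unique())
    if len(groups) != 2:
        raise DataError(f"need exactly two groups, found {groups}")
    ga, gb = groups
    vals = summaries[component].to_numpy(dtype=float)
    is_a = (summaries[group_col] == ga).to_numpy()
    na, n = int(is_a.sum()), len(vals)
    obs = vals[is_a].mean() - vals[~is_a].mean()
    tol = 1e-12 * max(1.0, abs(obs))
    n_comb = math.comb(n, na)
    if n_comb <= n_perm:
        count = 0
        idx = np.arange(n)
        for combo in combinations(idx, na):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            delta = vals[mask].mean() - vals[~mask].mean()
            if abs(delta) >= abs(obs) - tol:
                count += 1
        return ContrastResult(component, ga, gb, float(obs),
                              count / n_comb, n_comb, True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=na, replace=False)] = True
        delta = vals[mask].mean() - vals[~mask].mean()
        if abs(delta) >= abs(obs) - tol:
            count += 1
    return ContrastResult(component, ga, gb, float(obs),
                          (1 + count) / (1 + n_perm), n_perm, False)


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-woodland species proportions from trap counts.

    Input columns: woodland, species, count (non-negative integers; rows
    for the same woodland/species are summed).  Adds ``proportion`` (exact)
    and ``pct`` (rounded to one decimal for reporting).
    """
    required = {"woodland", "species", "count"}
    if not required.issubset(table.columns):
        raise DataError(f"trap table needs columns {sorted(required)}")
    if (table["count"] < 0).any():
        raise DataError("counts must be non-negative")
    agg = table.groupby(["woodland", "species"], as_index=False)["count"].sum()
    totals = agg.groupby("woodland")["count"].transform("sum")
    agg["proportion"] = agg["count"] / totals
    agg["pct"] = (agg["proportion"] * 100).round(1)
    return agg
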