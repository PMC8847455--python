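"""Rarity indices and the dual-quartile rare-species rule.

Three per-species indices, each min-max scaled to [0, 1] over the species
pool of one analysis system:

* restrictedness  Res_i = 1 - GE_i / TOT  — taxonomic rarity, the complement
  of the fraction of the system's grid cells a species occupies;
* distinctiveness Dis_i = mean_{j != i} d_ij — how dissimilar a species'
  trait combination is from the rest of the pool;
* uniqueness      U_i   = min_{j != i} d_ij — trait-space isolation, the
  distance to the functional nearest neighbour.

A species is *rare* when it lies in the top quartile of restrictedness and
of the chosen functional index (distinctiveness or uniqueness) — both
facets of rarity at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .occupancy import AssemblageMatrix

FUNCTIONAL_INDICES = ("distinctiveness", "uniqueness")

__all__ = [
    "RarityScores",
    "restrictedness",
    "distinctiveness_global",
    "uniqueness",
    "select_rare",
    "rare_counts",
    "compute_rarity",
    "minmax_scale",
]


def minmax_scale(x: pd.Series) -> pd.Series:
    """Scale to [0, 1]; a constant column maps to all zeros (with warning)."""
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        warnings.warn(f"constant score column {x.name!r}: scaled to zeros")
        return pd.Series(np.zeros(len(x)), index=x.index, name=x.name)
    return (x - lo) / (hi - lo)


def restrictedness(assemblage: AssemblageMatrix) -> pd.DataFrame:
    """Geographic restrictedness per species: raw and [0, 1]-scaled.

    raw = 1 - GE/TOT, so a species occupying every cell scores 0 and
    narrowly distributed species score high; min-max rescaling then pins the
    pool's most restricted species at 1 (and its most widespread at 0).
    """
    ge = assemblage.ge
    if (ge == 0).any():
        empty = ge.index[ge == 0].tolist()
        raise ValueError(f"species with zero occupied cells: {empty}")
    raw = 1.0 - ge / assemblage.tot
    raw.name = "restrictedness_raw"
    scaled = minmax_scale(raw)
    return pd.DataFrame({"raw": raw, "scaled": scaled})


def _check_dist(dist: pd.DataFrame) -> None:
    if len(dist) < 2:
        raise ValueError("need at least 2 species")
    if not dist.index.equals(dist.columns):
        raise ValueError("distance matrix must be square with matching labels")


def distinctiveness_global(dist: pd.DataFrame) -> pd.DataFrame:
    """Mean functional distance of each species to all others in the pool."""
    _check_dist(dist)
    n = len(dist)
    raw = (dist.sum(axis=1)) / (n - 1)
    raw.name = "distinctiveness_raw"
    return pd.DataFrame({"raw": raw, "scaled": minmax_scale(raw)})


def uniqueness(dist: pd.DataFrame) -> pd.DataFrame:
    """Functional distance of each species to its nearest neighbour."""
    _check_dist(dist)
    arr = dist.to_numpy(dtype=float).copy()
    np.fill_diagonal(arr, np.inf)
    raw = pd.Series(arr.min(axis=1), index=dist.index, name="uniqueness_raw")
    return pd.DataFrame({"raw": raw, "scaled": minmax_scale(raw)})


@dataclass
class RarityScores:
    """Per-species rarity indices plus dual-quartile rare flags.

    ``table`` columns: ge, res_raw, res, dis_raw, dis, uniq_raw, uniq,
    rare_distinctiveness, rare_uniqueness.
    """

    table: pd.DataFrame
    quartile: float = 0.75

    @property
    def species(self) -> pd.Index:
        return self.table.index

    def rare(self, functional_index: str = "distinctiveness") -> pd.Index:
        flag = self.table[f"rare_{_check_index(functional_index)}"]
        return self.table.index[flag]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="species")


def _check_index(functional_index: str) -> str:
    if functional_index not in FUNCTIONAL_INDICES:
        raise ValueError(
            f"functional_index must be one of {FUNCTIONAL_INDICES}, "
            f"got {functional_index!r}"
        )
    return functional_index


def select_rare(
    scores: pd.DataFrame | RarityScores,
    functional_index: str = "distinctiveness",
    quartile: float = 0.75,
) -> pd.Index:
    """Species in the top quartile of both restrictedness and the chosen
    functional index.

    Quartiles are computed with linear interpolation between order
    statistics (R's default ``quantile`` type); the cutoff is inclusive
    (score >= Q3 qualifies), so ties at the cutoff are counted as rare. A
    constant score column makes everyone qualify on that axis — degenerate,
    warned, and reported rather than hidden.
    """
    _check_index(functional_index)
    table = scores.table if isinstance(scores, RarityScores) else scores
    res = table["res"].to_numpy(dtype=float)
    fun = table["dis" if functional_index == "distinctiveness" else "uniq"].to_numpy(dtype=float)
    out = np.ones(len(table), dtype=bool)
    for vals, name in ((res, "restrictedness"), (fun, functional_index)):
        if np.ptp(vals) == 0:
            warnings.warn(
                f"constant {name} scores: every species ties at the quartile cutoff"
            )
            continue
        q3 = np.quantile(vals, quartile, method="linear")
        out &= vals >= q3
    if out.all():
        warnings.warn("degenerate selection: every species flagged rare")
    return table.index[out]


def compute_rarity(
    assemblage: AssemblageMatrix,
    dist: pd.DataFrame,
    quartile: float = 0.75,
) -> RarityScores:
    """Assemble the full per-species rarity table for one system."""
    if not assemblage.species.equals(dist.index):
        dist = dist.loc[assemblage.species, assemblage.species]
    res = restrictedness(assemblage)
    dis = distinctiveness_global(dist)
    uni = uniqueness(dist)
    table = pd.DataFrame(
        {
            "ge": assemblage.ge,
            "res_raw": res["raw"],
            "res": res["scaled"],
            "dis_raw": dis["raw"],
            "dis": dis["scaled"],
            "uniq_raw": uni["raw"],
            "uniq": uni["scaled"],
        }
    )
    for fi in FUNCTIONAL_INDICES:
        rare = select_rare(table, fi, quartile)
        table[f"rare_{fi}"] = table.index.isin(rare)
    return RarityScores(table, quartile)


def rare_counts(assemblage: AssemblageMatrix, rare: "pd.Index | set") -> pd.Series:
    """Observed number of rare species in each cell (X)."""
    rare = pd.Index(rare)
    missing = rare.difference(assemblage.species)
    if len(missing):
        raise ValueError(f"rare species absent from assemblage: {missing.tolist()}")
    x = assemblage.data.loc[rare].sum(axis=0) if len(rare) else pd.Series(
        np.zeros(assemblage.tot, dtype=int), index=assemblage.cells
    )
    x.name = "X"
    return x
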