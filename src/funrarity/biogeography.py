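"""Downstream biogeographic analyses of rarity hotspots.

Given per-cell SES summaries these routines profile rarity against
latitude, test whether rare and non-rare species use habitat differently
(G-test + Cramér's V on the water-column categories), measure congruence
between SES > 2 hotspot cells and marine protected areas, quantify the
sensitivity of the functional indices to removing individual traits, and
provide a distance-decay diagnostic for spatial autocorrelation.

All geographic distances are planar Euclidean in decimal degrees — a
deliberate, documented simplification (no great-circle correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rarity import distinctiveness_global, uniqueness
from .traits import TraitTable, gower_distance, cramers_v

__all__ = [
    "latitudinal_profile",
    "habitat_test",
    "HabitatTestResult",
    "mpa_congruence",
    "CongruenceResult",
    "sensitivity_trait_removal",
    "distance_decay",
]

HABITAT_LEVELS = (
    "bathydemersal",
    "bathypelagic",
    "benthopelagic",
    "demersal",
    "pelagic_neritic",
    "pelagic_oceanic",
    "reef_associated",
)


def latitudinal_profile(
    summaries: pd.DataFrame,
    ses_threshold: float = 2.0,
    n_grid: int = 181,
) -> dict:
    """Latitudes of high-SES cells and their density along latitude.

    Returns the centroid latitudes of cells with SES >= ``ses_threshold``
    (degenerate cells excluded), a Gaussian-kernel density over latitude,
    and the mean-richness-per-latitude profile for comparison with the
    classic equatorial richness peak.
    """
    if "lat" not in summaries.columns:
        raise ValueError("summaries need a 'lat' column (cell centroid latitude)")
    ok = ~summaries["degenerate"].astype(bool)
    qual = summaries.loc[ok & (summaries["SES"] >= ses_threshold)]
    lats = qual["lat"].to_numpy(dtype=float)
    rich_prof = (
        summaries.groupby("lat")["richness"].mean().rename("mean_richness")
        if "richness" in summaries.columns else None
    )
    if len(lats) == 0:
        warnings.warn("no cells reach the SES threshold: empty profile")
        return {"latitudes": lats, "density": None, "grid": None,
                "richness_profile": rich_prof}
    grid = np.linspace(-90.0, 90.0, n_grid)
    if len(lats) < 2 or np.ptp(lats) == 0:
        # all mass at one latitude: report a point mass instead of a KDE
        dens = np.zeros_like(grid)
        dens[np.argmin(np.abs(grid - lats[0]))] = 1.0
    else:
        dens = stats.gaussian_kde(lats)(grid)
    return {"latitudes": lats, "density": dens, "grid": grid,
            "richness_profile": rich_prof}


@dataclass
class HabitatTestResult:
    table: pd.DataFrame  # 2 x k contingency (rows: rare, non_rare)
    g: float
    df: int
    pvalue: float
    cramers_v: float

    def __str__(self) -> str:
        return (
            f"G = {self.g:.4f}, df = {self.df}, p = {self.pvalue:.4g}, "
            f"Cramér's V = {self.cramers_v:.4f}"
        )


def habitat_test(rare_habitats, nonrare_habitats) -> HabitatTestResult:
    """G-test and Cramér's V for habitat-use differences, rare vs non-rare.

    Builds the 2 x k contingency table of habitat categories (the
    water-column specialization classes), computes the likelihood-ratio
    statistic G = 2 * sum O * ln(O/E) (zero cells contribute 0), its
    chi-square p-value on (2-1)(k-1) degrees of freedom, and Cramér's V
    from the Pearson chi-square. Categories absent from both groups are
    dropped with a warning.
    """
    rare = pd.Series(list(rare_habitats)).dropna().astype(str)
    nonrare = pd.Series(list(nonrare_habitats)).dropna().astype(str)
    if len(rare) == 0 or len(nonrare) == 0:
        raise ValueError("both groups need at least one species")
    cats = sorted(set(rare) | set(nonrare))
    table = pd.DataFrame(
        [rare.value_counts().reindex(cats, fill_value=0),
         nonrare.value_counts().reindex(cats, fill_value=0)],
        index=["rare", "non_rare"],
    )
    zero = table.columns[(table.sum(axis=0) == 0)]
    if len(zero):
        warnings.warn(f"dropping habitat categories with zero total: {list(zero)}")
        table = table.drop(columns=zero)
    obs = table.to_numpy(dtype=float)
    g, p, df, _ = stats.chi2_contingency(obs, correction=False,
                                         lambda_="log-likelihood")
    v = cramers_v(obs)
    return HabitatTestResult(table, float(g), int(df), float(p), v)


@dataclass
class CongruenceResult:
    """Overlap between SES hotspot cells and protected-area points."""

    hotspots: pd.Index
    matched: pd.Index
    percent_hotspots_matched: float | None
    percent_mpas_in_hotspots: float | None
    assignments: pd.DataFrame  # per-MPA: nearest cell, distance, kept flag

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"matched": [c in set(self.matched) for c in self.hotspots]},
            index=self.hotspots,
        )


def _nearest_centroid(mpas: pd.DataFrame, centroids: pd.DataFrame) -> pd.DataFrame:
    """Nearest cell centroid per MPA, planar decimal-degree distance.

    Ties broken deterministically by the lexically lowest cell id.
    """
    order = np.argsort(centroids.index.to_numpy())
    cent = centroids.iloc[order]
    clat = cent["lat"].to_numpy()
    clon = cent["lon"].to_numpy()
    d = np.sqrt(
        (mpas["lat"].to_numpy()[:, None] - clat[None, :]) ** 2
        + (mpas["lon"].to_numpy()[:, None] - clon[None, :]) ** 2
    )
    best = d.argmin(axis=1)  # argmin takes the first minimum -> lowest cell id
    return pd.DataFrame(
        {
            "mpa_id": mpas["id"].to_numpy() if "id" in mpas.columns else mpas.index,
            "cell_id": cent.index.to_numpy()[best],
            "distance": d[np.arange(len(mpas)), best],
        }
    )


def mpa_congruence(
    summaries: pd.DataFrame,
    mpas: pd.DataFrame,
    cutoff: float = 0.75,
    ses_threshold: float = 2.0,
) -> CongruenceResult:
    """Congruence between rarity hotspots (SES > threshold) and MPAs.

    Each protected-area point is assigned to its nearest grid-cell
    centroid and kept only if that distance is strictly below ``cutoff``
    decimal degrees. A hotspot counts as matched when at least one MPA is
    assigned to it. The primary output is the percentage of hotspot cells
    matched; the percentage of assigned MPAs that land in hotspot cells is
    reported as a secondary view of the same overlap.
    """
    if not {"lat", "lon"}.issubset(summaries.columns):
        raise ValueError("summaries need 'lat'/'lon' centroid columns")
    mpas = mpas.drop_duplicates(subset=[c for c in ("lat", "lon") if c in mpas.columns])
    ok = ~summaries["degenerate"].astype(bool)
    hotspots = summaries.index[ok & (summaries["SES"] > ses_threshold)]
    assign = _nearest_centroid(mpas, summaries[["lat", "lon"]])
    assign["kept"] = assign["distance"] < cutoff
    kept = assign.loc[assign["kept"]]
    cells_with_mpa = set(kept["cell_id"])
    matched = pd.Index([c for c in hotspots if c in cells_with_mpa])
    if len(hotspots) == 0:
        warnings.warn("no hotspot cells (SES above threshold); percent undefined")
        pct_cells = None
    else:
        pct_cells = 100.0 * len(matched) / len(hotspots)
    pct_mpas = (
        100.0 * float(kept["cell_id"].isin(set(hotspots)).mean())
        if len(kept) else None
    )
    return CongruenceResult(hotspots, matched, pct_cells, pct_mpas, assign)


def sensitivity_trait_removal(
    table: TraitTable,
    removal_sets: list[list[str]],
) -> pd.DataFrame:
    """Correlation of reduced-trait vs full-trait functional indices.

    For each removal set, the Gower distance matrix and both functional
    indices are recomputed without those traits, and Pearson/Spearman
    correlations with the full-table scores reported. High correlations
    mean no single trait drives the rarity patterns.
    """
    full_dist = gower_distance(table)
    full_dis = distinctiveness_global(full_dist)["raw"]
    full_uni = uniqueness(full_dist)["raw"]
    rows = []
    for removal in removal_sets:
        missing = set(removal) - set(table.data.columns)
        if missing:
            raise KeyError(f"unknown trait(s): {sorted(missing)}")
        sub = table.drop_traits(removal) if removal else table
        dist = gower_distance(sub)
        dis = distinctiveness_global(dist)["raw"]
        uni = uniqueness(dist)["raw"]
        rows.append(
            {
                "removed": ",".join(removal) if removal else "(none)",
                "dis_pearson": _safe_corr(full_dis, dis, "pearson"),
                "dis_spearman": _safe_corr(full_dis, dis, "spearman"),
                "uniq_pearson": _safe_corr(full_uni, uni, "pearson"),
                "uniq_spearman": _safe_corr(full_uni, uni, "spearman"),
            }
        )
    return pd.DataFrame(rows).set_index("removed")


def _safe_corr(a: pd.Series, b: pd.Series, method: str) -> float:
    if np.ptp(a.to_numpy()) == 0 or np.ptp(b.to_numpy()) == 0:
        # identical-up-to-constant score vectors: report perfect agreement
        return 1.0 if np.allclose(a - a.mean(), b - b.mean()) else 0.0
    return float(a.corr(b, method=method))


def distance_decay(
    summaries: pd.DataFrame,
    reference_cell: str,
    taus: tuple[float, ...] = (0.5, 0.9),
) -> dict:
    """Distance-decay diagnostic: |SES difference| vs geographic distance.

    Pairs the reference cell with every other cell (planar decimal-degree
    distance between centroids against absolute SES difference) and fits
    linear quantile-regression lines at the requested quantiles by pinball
    loss minimization. Used to check that spatial autocorrelation is not
    driving hotspot patterns; no particular slope is asserted.
    """
    import statsmodels.api as sm

    if reference_cell not in summaries.index:
        raise KeyError(f"unknown reference cell {reference_cell!r}")
    ok = ~summaries["degenerate"].astype(bool)
    s = summaries.loc[ok]
    if len(s) < 10:
        raise ValueError("need at least 10 cells with finite SES")
    ref = s.loc[reference_cell]
    others = s.drop(index=reference_cell)
    dist = np.sqrt(
        (others["lat"] - ref["lat"]) ** 2 + (others["lon"] - ref["lon"]) ** 2
    ).to_numpy()
    dses = np.abs(others["SES"] - ref["SES"]).to_numpy()
    pairs = pd.DataFrame({"distance": dist, "abs_ses_diff": dses})
    fits = {}
    if np.ptp(dses) == 0:
        warnings.warn("all SES differences equal: quantile slopes are 0")
        for tau in taus:
            fits[tau] = {"intercept": float(dses[0]), "slope": 0.0}
    else:
        X = sm.add_constant(dist)
        for tau in taus:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.QuantReg(dses, X).fit(q=tau)
            fits[tau] = {"intercept": float(res.params[0]),
                         "slope": float(res.params[1])}
    return {"pairs": pairs, "fits": fits}
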