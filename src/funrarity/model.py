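"""Model/Results front-end tying the pipeline together.

``FunctionalRarityModel`` is built from occurrence records and a trait
table (plus optional system partition and grid); ``fit`` runs the full
analysis for one system — thresholding, assemblage construction, trait
filtering and imputation, Gower distances, the three rarity indices, the
dual-quartile rare set, the curveball null model and per-cell SES — and
returns a ``FunctionalRarityResults`` carrying the estimates, their null
uncertainties and the downstream analyses as methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import biogeography, nullmodel, rarity
from .occupancy import (AssemblageMatrix, GridSpec, SystemPartition,
                        build_assemblage, threshold_occurrences)
from .traits import TraitTable, filter_traits, gower_distance, impute_traits

__all__ = ["FunctionalRarityModel", "FunctionalRarityResults"]


class FunctionalRarityModel:
    """Functional-rarity null-model analysis of one gridded assemblage.

    Parameters
    ----------
    occurrences : DataFrame with columns species, lat, lon, probability.
    traits : TraitTable of the species pool (mixed continuous/categorical).
    grid : GridSpec, defaults to the 2-degree global grid.
    partition, system : optional system partition and the system to
        analyse; when omitted the whole grid is treated as one system.
    threshold : occurrence-probability cutoff (strict >), default 0.9.
    functional_index : "distinctiveness" (default) or "uniqueness" — which
        functional facet pairs with restrictedness in the rare-species rule.
    """

    def __init__(
        self,
        occurrences: pd.DataFrame,
        traits: TraitTable,
        grid: GridSpec | None = None,
        partition: SystemPartition | None = None,
        system: str | None = None,
        threshold: float = 0.9,
        functional_index: str = "distinctiveness",
        quartile: float = 0.75,
        max_missing: float = 0.30,
    ):
        rarity._check_index(functional_index)
        self.occurrences = occurrences
        self.traits = traits
        self.grid = grid or GridSpec()
        self.partition = partition
        self.system = system
        self.threshold = threshold
        self.functional_index = functional_index
        self.quartile = quartile
        self.max_missing = max_missing

    @classmethod
    def from_csv(
        cls,
        occurrences_csv,
        traits_csv,
        traits_schema,
        partition_csv=None,
        system: str | None = None,
        **kwargs,
    ) -> "FunctionalRarityModel":
        occ = pd.read_csv(occurrences_csv)
        traits = TraitTable.from_csv(traits_csv, traits_schema)
        part = SystemPartition.from_csv(partition_csv) if partition_csv else None
        return cls(occ, traits, partition=part, system=system, **kwargs)

    def build_assemblage(self) -> AssemblageMatrix:
        kept = threshold_occurrences(self.occurrences, self.threshold)
        asm = build_assemblage(kept, self.grid, self.partition, self.system)
        pool = asm.species.intersection(self.traits.species)
        if len(pool) < len(asm.species):
            asm = AssemblageMatrix(
                asm.data.loc[pool], asm.grid, asm.system
            )
        return asm

    def fit(
        self,
        n_iterations: int = 2000,
        seed: int | None = None,
        trades_per_iteration: int | None = None,
        burn_in: int | None = None,
    ) -> "FunctionalRarityResults":
        """Run the full pipeline and return the results object."""
        asm = self.build_assemblage()
        tr = self.traits.subset_species(asm.species)
        tr = filter_traits(tr, self.max_missing)
        tr = impute_traits(tr, seed=0 if seed is None else seed)
        dist = gower_distance(tr)
        scores = rarity.compute_rarity(asm, dist, self.quartile)
        rare = scores.rare(self.functional_index)
        x = rarity.rare_counts(asm, rare)
        ens = nullmodel.null_distribution(
            asm, rare, n_iterations=n_iterations,
            trades_per_iteration=trades_per_iteration,
            burn_in=burn_in, seed=seed,
        )
        summary = nullmodel.compute_ses(x, ens, richness=asm.richness(),
                                        grid=self.grid)
        return FunctionalRarityResults(self, asm, tr, dist, scores, rare, ens,
                                       summary)


@dataclass
class FunctionalRarityResults:
    """Fitted functional-rarity analysis for one system."""

    model: FunctionalRarityModel
    assemblage: AssemblageMatrix
    traits: TraitTable
    distance_matrix: pd.DataFrame
    rarity_scores: rarity.RarityScores
    rare_species: pd.Index
    ensemble: nullmodel.NullEnsemble
    cell_summary: pd.DataFrame

    # -- headline accessors -------------------------------------------------
    @property
    def ses(self) -> pd.Series:
        return self.cell_summary["SES"]

    def hotspots(self, ses_threshold: float = 2.0) -> pd.Index:
        """Cells with SES strictly above the hotspot threshold."""
        s = self.cell_summary
        return s.index[(~s["degenerate"]) & (s["SES"] > ses_threshold)]

    def summary(self) -> str:
        s = self.cell_summary
        finite = s.loc[~s["degenerate"], "SES"]
        lines = [
            "Functional rarity null-model analysis",
            "=" * 46,
            f"system:            {self.assemblage.system}",
            f"prob. threshold:   >{self.model.threshold}",
            f"functional index:  {self.model.functional_index}",
            f"species (pool):    {len(self.assemblage.species)}",
            f"grid cells (TOT):  {self.assemblage.tot}",
            f"rare species:      {len(self.rare_species)} "
            f"({100 * len(self.rare_species) / len(self.assemblage.species):.1f}% of pool)",
            f"null iterations:   {self.ensemble.n_iterations}",
            f"SES mean (sd):     {finite.mean():.3f} ({finite.std():.3f})",
            f"hotspot cells:     {len(self.hotspots())} with SES > 2",
            f"degenerate cells:  {int(s['degenerate'].sum())}",
        ]
        return "\n".join(lines)

    # -- downstream analyses ------------------------------------------------
    def latitudinal_profile(self, ses_threshold: float = 2.0) -> dict:
        return biogeography.latitudinal_profile(self.cell_summary, ses_threshold)

    def mpa_congruence(self, mpas: pd.DataFrame, cutoff: float = 0.75,
                       ses_threshold: float = 2.0) -> biogeography.CongruenceResult:
        return biogeography.mpa_congruence(self.cell_summary, mpas, cutoff,
                                           ses_threshold)

    def habitat_test(self, habitat_trait: str = "habitat") -> biogeography.HabitatTestResult:
        hab = self.traits.data[habitat_trait]
        rare_mask = hab.index.isin(self.rare_species)
        return biogeography.habitat_test(hab[rare_mask], hab[~rare_mask])

    def sensitivity(self, removal_sets: list[list[str]]) -> pd.DataFrame:
        return biogeography.sensitivity_trait_removal(self.traits, removal_sets)

    def distance_decay(self, reference_cell: str, **kwargs) -> dict:
        return biogeography.distance_decay(self.cell_summary, reference_cell,
                                           **kwargs)

    def planted_recovery(self, truth) -> dict:
        """Score recovery of a synthetic world's planted structure."""
        planted = set(truth.planted_rare_ids) & set(self.assemblage.species)
        rare = set(self.rare_species)
        recall = len(planted & rare) / len(planted) if planted else float("nan")
        hot = set(self.hotspots(2.0))
        cells = set(truth.hotspot_cells) & set(self.assemblage.cells)
        # hotspot detection uses SES >= 2, the figure-level definition
        s = self.cell_summary
        ge2 = set(s.index[(~s["degenerate"]) & (s["SES"] >= 2.0)])
        det = len(cells & ge2) / len(cells) if cells else float("nan")
        return {"planted_recall": recall, "hotspot_detection": det,
                "n_planted_in_pool": len(planted), "hotspots_found": len(hot)}

    # -- output -------------------------------------------------------------
    def to_csv(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "rarity": outdir / "rarity.csv",
            "cell_summary": outdir / "cell_summary.csv",
            "assemblage": outdir / "assemblage.csv",
        }
        self.rarity_scores.to_csv(paths["rarity"])
        self.cell_summary.to_csv(paths["cell_summary"])
        self.assemblage.to_csv(paths["assemblage"])
        return paths

    def plot_latitude(self, ax=None, ses_threshold: float = 2.0):
        """Density of high-SES cells along latitude (requires matplotlib)."""
        import matplotlib.pyplot as plt

        prof = self.latitudinal_profile(ses_threshold)
        if ax is None:
            _, ax = plt.subplots()
        if prof["density"] is not None:
            ax.plot(prof["grid"], prof["density"], label=f"SES >= {ses_threshold}")
            ax.fill_between(prof["grid"], prof["density"], alpha=0.3)
        ax.set_xlabel("latitude (deg)")
        ax.set_ylabel("density of high-SES cells")
        ax.legend()
        return ax
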