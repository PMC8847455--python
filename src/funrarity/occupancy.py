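"""Gridded occupancy: probabilistic occurrence records -> binary assemblage matrices.

Occurrence records (one row per species sighting with an occurrence
probability, as produced by environmental-envelope distribution models) are
thresholded, snapped onto a regular latitude/longitude grid, and turned into
a binary species x grid-cell presence/absence matrix for one analysis
system (e.g. a coastal or high-seas region).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "SystemPartition",
    "AssemblageMatrix",
    "threshold_occurrences",
    "build_assemblage",
    "species_richness",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid tiling [-180, 180) x [-90, 90).

    Cells are half-open squares ``[edge, edge + cell_size)`` so every finite
    coordinate maps to exactly one cell; the north-pole edge (lat = 90) is
    clamped into the top row and longitudes are normalized to [-180, 180)
    before gridding.
    """

    cell_size_deg: float = 2.0
    lon_origin: float = field(default=-180.0, init=False)
    lat_origin: float = field(default=-90.0, init=False)

    @property
    def n_rows(self) -> int:
        return int(round(180.0 / self.cell_size_deg))

    @property
    def n_cols(self) -> int:
        return int(round(360.0 / self.cell_size_deg))

    def cell_index(self, lat, lon):
        """Map coordinates to (row, col) indices. Vectorized.

        Raises ValueError for latitudes outside [-90, 90]; longitudes are
        wrapped onto [-180, 180).
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        bad = ~np.isfinite(lat) | ~np.isfinite(lon) | (lat < -90) | (lat > 90)
        if np.any(bad):
            idx = np.nonzero(np.atleast_1d(bad))[0]
            raise ValueError(
                f"invalid coordinates at record position(s) {idx.tolist()[:10]}"
                f" (lat must be in [-90, 90] and finite)"
            )
        lon = np.mod(lon - self.lon_origin, 360.0) + self.lon_origin
        row = np.floor((lat - self.lat_origin) / self.cell_size_deg).astype(int)
        row = np.clip(row, 0, self.n_rows - 1)  # lat == +90 -> top row
        col = np.floor((lon - self.lon_origin) / self.cell_size_deg).astype(int)
        col = np.clip(col, 0, self.n_cols - 1)
        return row, col

    def cell_id(self, row, col):
        """String id "r<row>c<col>" for a cell; vectorized over arrays."""
        if np.isscalar(row):
            return f"r{int(row)}c{int(col)}"
        row = np.asarray(row)
        col = np.asarray(col)
        return np.array([f"r{r}c{c}" for r, c in zip(row, col)])

    def parse_cell_id(self, cell_id: str) -> tuple[int, int]:
        r, c = cell_id[1:].split("c")
        return int(r), int(c)

    def centroid(self, cell_id: str) -> tuple[float, float]:
        """(lat, lon) centre of a cell."""
        row, col = self.parse_cell_id(cell_id)
        lat = self.lat_origin + (row + 0.5) * self.cell_size_deg
        lon = self.lon_origin + (col + 0.5) * self.cell_size_deg
        return lat, lon

    def centroids(self, cell_ids) -> pd.DataFrame:
        vals = [self.centroid(c) for c in cell_ids]
        return pd.DataFrame(vals, index=pd.Index(cell_ids, name="cell_id"),
                            columns=["lat", "lon"])


class SystemPartition:
    """Assignment of grid cells to analysis systems.

    A system is an (oceanic region, class) pair where class is ``coastal``
    or ``high_seas``; seven regions give at most fourteen systems. Each
    system is analysed independently downstream.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"cell_id", "region", "system_class"}
        if not required.issubset(table.columns):
            raise ValueError(f"partition table must have columns {sorted(required)}")
        bad = set(table["system_class"]) - {"coastal", "high_seas"}
        if bad:
            raise ValueError(f"unknown system_class values: {sorted(bad)}")
        t = table.drop_duplicates("cell_id").set_index("cell_id")
        self.table = t
        self._system = t["region"].astype(str) + ":" + t["system_class"].astype(str)

    @classmethod
    def from_csv(cls, path) -> "SystemPartition":
        return cls(pd.read_csv(path))

    @property
    def systems(self) -> list[str]:
        return sorted(self._system.unique())

    def cells_of(self, system: str) -> pd.Index:
        if system not in set(self._system):
            raise KeyError(f"unknown system {system!r}; available: {self.systems}")
        return self._system.index[self._system == system]

    def __contains__(self, system: str) -> bool:
        return system in set(self._system)


@dataclass
class AssemblageMatrix:
    """Binary species x cell presence/absence matrix for one system.

    ``data`` has unique species labels as rows and cell ids as columns.
    GE (a species' geographic extent) is its row sum; TOT is the number of
    columns.
    """

    data: pd.DataFrame
    grid: GridSpec = field(default_factory=GridSpec)
    system: str = "global"

    def __post_init__(self):
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("assemblage entries must be 0/1")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("species and cell labels must be unique")
        if self.data.shape[1] < 2:
            raise ValueError("assemblage needs at least 2 cells (TOT >= 2)")

    @property
    def species(self) -> pd.Index:
        return self.data.index

    @property
    def cells(self) -> pd.Index:
        return self.data.columns

    @property
    def tot(self) -> int:
        return self.data.shape[1]

    @property
    def ge(self) -> pd.Series:
        """Geographic extent: number of occupied cells per species."""
        return self.data.sum(axis=1)

    def richness(self) -> pd.Series:
        return species_richness(self)

    def centroids(self) -> pd.DataFrame:
        return self.grid.centroids(self.cells)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path, grid: GridSpec | None = None,
                 system: str = "global") -> "AssemblageMatrix":
        df = pd.read_csv(path, index_col="species")
        return cls(df.astype(np.int8), grid or GridSpec(), system)


def threshold_occurrences(records: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Keep records whose occurrence probability is strictly above threshold.

    The strict inequality mirrors the convention of reporting assemblages at
    probability-of-occurrence ">0.9" (and the ">0.7" / ">0.5" robustness
    variants).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    prob = records["probability"].to_numpy(dtype=float)
    invalid = (prob < 0) | (prob > 1) | ~np.isfinite(prob)
    if invalid.any():
        rejected = records.index[invalid].tolist()
        raise ValueError(
            f"{invalid.sum()} record(s) with probability outside [0, 1]; "
            f"rejected indices (first 10): {rejected[:10]}"
        )
    return records.loc[prob > threshold]


def build_assemblage(
    records: pd.DataFrame,
    grid: GridSpec | None = None,
    partition: SystemPartition | None = None,
    system: str | None = None,
) -> AssemblageMatrix:
    """Build a binary assemblage matrix from (already thresholded) records.

    A species is present in a cell iff at least one record falls in it;
    duplicate records collapse idempotently. When a partition and system are
    given, only that system's cells are kept and species with no presence in
    the system are dropped. Columns are the occupied cells of the system.
    """
    grid = grid or GridSpec()
    if records.empty:
        raise ValueError("no occurrence records supplied")
    row, col = grid.cell_index(records["lat"].to_numpy(), records["lon"].to_numpy())
    cell = grid.cell_id(row, col)
    pres = pd.DataFrame({"species": records["species"].to_numpy(), "cell_id": cell})
    if partition is not None and system is not None:
        keep = pres["cell_id"].isin(set(partition.cells_of(system)))
        pres = pres.loc[keep]
        if pres.empty:
            raise ValueError(f"no records fall inside system {system!r}")
    pres = pres.drop_duplicates()
    mat = (
        pd.crosstab(pres["species"], pres["cell_id"])
        .astype(np.int8)
        .clip(upper=1)
    )
    mat = mat.sort_index(axis=0).sort_index(axis=1)
    mat.index.name = "species"
    mat.columns.name = "cell_id"
    return AssemblageMatrix(mat, grid, system or "global")


def species_richness(assemblage: AssemblageMatrix) -> pd.Series:
    """Number of species present in each cell (column sums)."""
    rich = assemblage.data.sum(axis=0)
    rich.name = "richness"
    return rich
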