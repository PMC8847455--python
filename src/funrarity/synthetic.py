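"""Synthetic world generator with planted, recoverable structure.

Emulates the statistical shape of the real inputs — probabilistic
half-degree occurrence records over a 2-degree analysis grid, a mixed-type
trait table with missing data, protected-area points and a coastal /
high-seas system partition — while planting known structure: a handful of
range-restricted species carrying outlier trait combinations, concentrated
on a small set of hotspot cells. The returned truth object lists the
planted species and hotspot cells so downstream recovery (quartile
selection, SES hotspots) can be scored against ground truth.

Background species get contiguous rectangular ranges whose centroids are
biased toward the equator (a latitudinal richness gradient); in-range cells
draw occurrence probabilities from Uniform(0.92, 1), out-of-range noise
records from Uniform(0, 0.5), so the 0.9 / 0.7 / 0.5 thresholds all recover
the intended ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .occupancy import GridSpec
from .traits import TraitTable, CONTINUOUS, CATEGORICAL
from .biogeography import HABITAT_LEVELS

__all__ = ["SimConfig", "SyntheticTruth", "SimWorld", "simulate_world", "write_world"]

REGION_NAMES = (
    "arctic", "north_atlantic", "south_atlantic", "indian",
    "north_pacific", "south_pacific", "southern",
)

# background continuous-trait model: names, correlated blocks, affine units
CONT_TRAITS = (
    "max_depth_m", "temp_pref_c", "growth_k", "qb_ratio",
    "trophic_level", "generation_time_y", "length_maturity_mm",
)
_UNIT_SHIFT = np.array([800.0, 15.0, 0.4, 6.0, 3.4, 5.0, 300.0])
_UNIT_SCALE = np.array([600.0, 8.0, 0.15, 2.5, 0.5, 2.0, 150.0])

CAT_TRAITS = {
    "habitat": {
        "levels": list(HABITAT_LEVELS),
        # bathydemersal is kept scarce in the background and assigned to
        # planted species (their "rare level" within the declared 7-class set)
        "probs": [0.02, 0.08, 0.15, 0.25, 0.15, 0.10, 0.25],
        "rare_level": "bathydemersal",
    },
    "body_shape": {
        "levels": ["fusiform", "compressed", "elongated", "flat", "short_deep",
                   "globiform"],
        "probs": [0.40, 0.25, 0.20, 0.10, 0.05, 0.0],
        "rare_level": "globiform",
    },
    "swimming_mode": {
        "levels": ["subcarangiform", "carangiform", "anguilliform", "labriform",
                   "balistiform"],
        "probs": [0.35, 0.30, 0.20, 0.15, 0.0],
        "rare_level": "balistiform",
    },
    "reproductive_guild": {
        "levels": ["nonguarder_open", "nonguarder_brood_hider", "guarder_nester",
                   "bearer_internal", "bearer_external"],
        "probs": [0.40, 0.25, 0.20, 0.15, 0.0],
        "rare_level": "bearer_external",
    },
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic world.

    The grid is a contiguous window of 2-degree cells centred on
    (lat 0, lon 0); ``richness_gradient_strength`` controls how strongly
    background range centroids pile up at low latitude (0 = uniform);
    ``trait_outlier_shift`` is the distance, in background standard
    deviations, between each planted species' continuous traits and the
    bulk; ``planted_range_size`` must sit below the background
    first-quartile range size so planted species land in the top
    restrictedness quartile by construction.
    """

    n_species: int = 300
    n_lat_cells: int = 20
    n_lon_cells: int = 20
    richness_gradient_strength: float = 1.5
    n_planted_rare: int = 20
    planted_range_size: int = 3
    n_hotspot_cells: int = 5
    trait_outlier_shift: float = 4.0
    missingness_fraction: float = 0.2
    n_mpas: int = 60
    seed: int = 0
    cell_size_deg: float = 2.0
    hotspot_latitude_range: tuple[float, float] | None = None
    noise_cell_fraction: float = 0.08

    def validate(self) -> None:
        if self.n_species <= 0:
            raise ValueError("n_species must be positive")
        if self.n_planted_rare < 0 or self.n_planted_rare > self.n_species:
            raise ValueError("need 0 <= n_planted_rare <= n_species")
        if self.n_hotspot_cells > self.n_lat_cells * self.n_lon_cells:
            raise ValueError("n_hotspot_cells exceeds total cells")
        if self.n_planted_rare > 0 and self.planted_range_size > self.n_hotspot_cells:
            raise ValueError("planted_range_size cannot exceed n_hotspot_cells")
        if self.n_planted_rare > 0 and self.planted_range_size < 1:
            raise ValueError("planted_range_size must be >= 1")
        if not 0 <= self.missingness_fraction <= 0.3:
            raise ValueError("missingness_fraction must lie in [0, 0.3]")
        if self.richness_gradient_strength < 0:
            raise ValueError("richness_gradient_strength must be >= 0")
        if self.n_planted_rare > 0 and self.trait_outlier_shift <= 0:
            raise ValueError("trait_outlier_shift must be positive")
        if min(self.n_lat_cells, self.n_lon_cells) < 2:
            raise ValueError("grid must be at least 2x2")


@dataclass
class SyntheticTruth:
    """What a simulation run buried in its outputs."""

    planted_rare_ids: set[str]
    hotspot_cells: set[str]
    config: SimConfig

    def to_json(self, path) -> None:
        payload = {
            "planted_rare_ids": sorted(self.planted_rare_ids),
            "hotspot_cells": sorted(self.hotspot_cells),
            "config": asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = payload["config"]
        if cfg.get("hotspot_latitude_range") is not None:
            cfg["hotspot_latitude_range"] = tuple(cfg["hotspot_latitude_range"])
        return cls(set(payload["planted_rare_ids"]), set(payload["hotspot_cells"]),
                   SimConfig(**cfg))


@dataclass
class SimWorld:
    occurrences: pd.DataFrame
    traits: TraitTable
    mpas: pd.DataFrame
    partition: pd.DataFrame
    truth: SyntheticTruth
    grid: GridSpec = field(default_factory=GridSpec)


def _window(config: SimConfig, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Global (row, col) index ranges of the simulated window."""
    r0 = grid.n_rows // 2 - config.n_lat_cells // 2
    c0 = grid.n_cols // 2 - config.n_lon_cells // 2
    return (np.arange(r0, r0 + config.n_lat_cells),
            np.arange(c0, c0 + config.n_lon_cells))


def _row_weights(rows: np.ndarray, grid: GridSpec, strength: float) -> np.ndarray:
    lat = grid.lat_origin + (rows + 0.5) * grid.cell_size_deg
    scale = max(np.abs(lat).max(), 1.0)
    w = np.exp(-strength * np.abs(lat) / scale)
    return w / w.sum()


def _background_ranges(config: SimConfig, grid: GridSpec,
                       rng: np.random.Generator) -> list[list[tuple[int, int]]]:
    rows, cols = _window(config, grid)
    weights = _row_weights(rows, grid, config.richness_gradient_strength)
    n_back = config.n_species - config.n_planted_rare
    ranges = []
    for _ in range(n_back):
        h = int(rng.integers(2, min(7, config.n_lat_cells + 1)))
        w = int(rng.integers(2, min(7, config.n_lon_cells + 1)))
        # centroid row drawn from the gradient-weighted distribution, then
        # the rectangle anchored so it stays inside the window
        centre = int(rng.choice(len(rows), p=weights))
        r0 = int(np.clip(centre - h // 2, 0, config.n_lat_cells - h))
        c0 = int(rng.integers(0, config.n_lon_cells - w + 1))
        cells = [(int(rows[r0 + i]), int(cols[c0 + j]))
                 for i in range(h) for j in range(w)]
        ranges.append(cells)
    return ranges


def _hotspot_cells(config: SimConfig, grid: GridSpec,
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    rows, cols = _window(config, grid)
    if config.hotspot_latitude_range is not None:
        lo, hi = config.hotspot_latitude_range
        lat = grid.lat_origin + (rows + 0.5) * grid.cell_size_deg
        rows = rows[(lat >= lo) & (lat <= hi)]
        if len(rows) == 0:
            raise ValueError("hotspot_latitude_range excludes every grid row")
    side = int(np.ceil(np.sqrt(config.n_hotspot_cells)))
    side_r = min(side, len(rows))
    side_c = int(np.ceil(config.n_hotspot_cells / side_r))
    if side_c > len(cols):
        raise ValueError("hotspot block does not fit in the grid window")
    r0 = int(rng.integers(0, len(rows) - side_r + 1))
    c0 = int(rng.integers(0, len(cols) - side_c + 1))
    block = [(int(rows[r0 + i]), int(cols[c0 + j]))
             for i in range(side_r) for j in range(side_c)]
    return block[: config.n_hotspot_cells]


def _emit_records(species: str, cells, in_range: bool,
                  rng: np.random.Generator, grid: GridSpec, out: list) -> None:
    """Half-degree records inside the given 2-degree cells."""
    half = grid.cell_size_deg / 4.0  # half-degree sub-cell size for 2° cells
    for (r, c) in cells:
        lat0 = grid.lat_origin + r * grid.cell_size_deg
        lon0 = grid.lon_origin + c * grid.cell_size_deg
        k = int(rng.integers(1, 4)) if in_range else 1
        subs = rng.choice(16, size=k, replace=False)
        for s in subs:
            si, sj = divmod(int(s), 4)
            lat = lat0 + (si + 0.5) * half
            lon = lon0 + (sj + 0.5) * half
            p = rng.uniform(0.92, 1.0) if in_range else rng.uniform(0.0, 0.5)
            out.append((species, lat, lon, p))


def _make_traits(config: SimConfig, names_bg: list[str], names_pl: list[str],
                 rng: np.random.Generator) -> TraitTable:
    n_bg, n_pl = len(names_bg), len(names_pl)
    corr = np.eye(7)
    # life-history covariation: fast growers mature early and small
    corr[2, 5] = corr[5, 2] = -0.6   # growth_k ~ generation_time_y
    corr[2, 6] = corr[6, 2] = -0.5   # growth_k ~ length_maturity_mm
    corr[5, 6] = corr[6, 5] = 0.6    # generation_time_y ~ length_maturity_mm
    corr[0, 1] = corr[1, 0] = -0.5   # deeper species prefer colder water
    corr[3, 4] = corr[4, 3] = 0.4    # consumption ratio ~ trophic level
    L = np.linalg.cholesky(corr)
    z_bg = rng.standard_normal((n_bg, 7)) @ L.T
    # each planted species is offset `shift` background SDs on every
    # continuous trait, with its own distinct random sign pattern: planted
    # species are then outliers relative to the bulk AND mutually distant
    # (any two patterns differ by >= 2*shift on some trait), which keeps
    # both distinctiveness and uniqueness high
    if n_pl:
        if n_pl > 2 ** 7:
            raise ValueError("cannot plant more than 128 trait-outlier species")
        codes = rng.choice(2 ** 7, size=n_pl, replace=False)
        signs = 2.0 * ((codes[:, None] >> np.arange(7)[None, :]) & 1) - 1.0
        z_pl = (config.trait_outlier_shift * signs
                + 0.3 * rng.standard_normal((n_pl, 7)))
    else:
        z_pl = np.empty((0, 7))
    z = np.vstack([z_bg, z_pl])
    cont = pd.DataFrame(_UNIT_SHIFT + _UNIT_SCALE * z,
                        index=names_bg + names_pl, columns=list(CONT_TRAITS))
    data = cont
    kinds = {t: CONTINUOUS for t in CONT_TRAITS}
    levels = {}
    for trait, spec_ in CAT_TRAITS.items():
        lv = np.array(spec_["levels"], dtype=object)
        p = np.array(spec_["probs"], dtype=float)
        p = p / p.sum()
        vals_bg = rng.choice(lv, size=n_bg, p=p)
        # planted species are strongly enriched for the reserved rare level
        # but not identical on it, so they stay mutually distinct in trait
        # space (otherwise every planted species' nearest neighbour would be
        # another planted species and uniqueness would collapse)
        p_pl = 0.5 * p + 0.5 * (lv == spec_["rare_level"])
        vals_pl = rng.choice(lv, size=n_pl, p=p_pl / p_pl.sum())
        data[trait] = np.concatenate([vals_bg, vals_pl])
        kinds[trait] = CATEGORICAL
        levels[trait] = list(spec_["levels"])
    data.index.name = "species"
    return TraitTable(data, kinds, levels)


def _apply_missingness(table: TraitTable, frac: float,
                       rng: np.random.Generator) -> TraitTable:
    """MCAR mask of exactly round(frac * n) entries per trait.

    Exact counts (rather than Bernoulli draws) keep the realized
    missingness within rounding of the configured fraction on every run.
    No species is left with all traits missing.
    """
    if frac == 0:
        return table
    df = table.data.copy()
    n = len(df)
    m = int(round(frac * n))
    for t in df.columns:
        idx = rng.choice(n, size=m, replace=False)
        df.iloc[idx, df.columns.get_loc(t)] = np.nan
    lost = df.isna().all(axis=1)
    for i in np.nonzero(lost.to_numpy())[0]:
        t = int(rng.integers(0, df.shape[1]))
        df.iloc[i, t] = table.data.iloc[i, t]
    return TraitTable(df, dict(table.kinds),
                      {k: list(v) for k, v in table.levels.items()})


def _partition(config: SimConfig, grid: GridSpec) -> pd.DataFrame:
    """7 longitude-band regions, outer band columns coastal, interior high seas."""
    rows, cols = _window(config, grid)
    bounds = np.linspace(0, len(cols), 8).astype(int)
    records = []
    for k in range(7):
        band = cols[bounds[k]:bounds[k + 1]]
        for j, c in enumerate(band):
            cls = "coastal" if (j == 0 or j == len(band) - 1) else "high_seas"
            for r in rows:
                records.append((grid.cell_id(r, c), REGION_NAMES[k], cls))
    return pd.DataFrame(records, columns=["cell_id", "region", "system_class"])


def simulate_world(config: SimConfig) -> SimWorld:
    """Generate one synthetic world; fully reproducible under config.seed."""
    config.validate()
    grid = GridSpec(config.cell_size_deg)
    rng = np.random.default_rng(config.seed)

    bg_ranges = _background_ranges(config, grid, rng)
    sizes = np.array([len(r) for r in bg_ranges])
    if config.n_planted_rare > 0:
        q1 = np.quantile(sizes, 0.25)
        if config.planted_range_size >= q1:
            raise ValueError(
                f"inconsistent config: planted_range_size={config.planted_range_size} "
                f"is not below the background first-quartile range size ({q1:g}); "
                "planted species would not be restricted by construction"
            )
        hotspots = _hotspot_cells(config, grid, rng)
    else:
        hotspots = []

    n_bg = config.n_species - config.n_planted_rare
    width = len(str(config.n_species))
    names_bg = [f"sp{str(i + 1).zfill(width)}" for i in range(n_bg)]
    names_pl = [f"sp{str(n_bg + i + 1).zfill(width)}" for i in range(config.n_planted_rare)]

    pl_ranges = []
    for _ in names_pl:
        picks = rng.choice(len(hotspots), size=config.planted_range_size,
                           replace=False)
        pl_ranges.append([hotspots[i] for i in picks])

    rows, cols = _window(config, grid)
    all_cells = [(int(r), int(c)) for r in rows for c in cols]
    n_noise = max(1, int(round(config.noise_cell_fraction * len(all_cells))))
    recs: list = []
    for name, cells in zip(names_bg + names_pl, bg_ranges + pl_ranges):
        _emit_records(name, cells, True, rng, grid, recs)
        in_range = set(cells)
        candidates = [c for c in all_cells if c not in in_range]
        noise_idx = rng.choice(len(candidates), size=min(n_noise, len(candidates)),
                               replace=False)
        _emit_records(name, [candidates[i] for i in noise_idx], False, rng, grid, recs)
    occurrences = pd.DataFrame(recs, columns=["species", "lat", "lon", "probability"])

    traits = _make_traits(config, names_bg, names_pl, rng)
    traits = _apply_missingness(traits, config.missingness_fraction, rng)

    centroid = lambda rc: (grid.lat_origin + (rc[0] + 0.5) * grid.cell_size_deg,
                           grid.lon_origin + (rc[1] + 0.5) * grid.cell_size_deg)
    mpa_cells = rng.choice(len(all_cells), size=config.n_mpas, replace=True)
    mpa_rows = []
    for k, ci in enumerate(mpa_cells):
        lat, lon = centroid(all_cells[int(ci)])
        mpa_rows.append((f"mpa{k + 1:03d}",
                         lat + rng.uniform(-0.5, 0.5),
                         lon + rng.uniform(-0.5, 0.5)))
    mpas = pd.DataFrame(mpa_rows, columns=["id", "lat", "lon"])

    partition = _partition(config, grid)
    truth = SyntheticTruth(
        set(names_pl),
        {grid.cell_id(r, c) for r, c in hotspots},
        config,
    )
    return SimWorld(occurrences, traits, mpas, partition, truth, grid)


def write_world(world: SimWorld, outdir) -> dict[str, Path]:
    """Write the four CSV inputs plus the truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrences": outdir / "occurrences.csv",
        "traits": outdir / "traits.csv",
        "traits_schema": outdir / "traits_schema.json",
        "mpas": outdir / "mpas.csv",
        "partition": outdir / "partition.csv",
        "truth": outdir / "truth.json",
    }
    world.occurrences.to_csv(paths["occurrences"], index=False)
    world.traits.to_csv(paths["traits"], paths["traits_schema"])
    world.mpas.to_csv(paths["mpas"], index=False)
    world.partition.to_csv(paths["partition"], index=False)
    world.truth.to_json(paths["truth"])
    return paths
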