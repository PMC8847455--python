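"""Mixed-type trait tables: missingness filtering, imputation, Gower distances.

A trait table holds continuous and categorical traits per species (in a
marine-fish setting: depth and temperature preferences, growth coefficient,
consumption/biomass ratio, trophic level, generation time, length at first
maturity, plus categorical habitat, body shape, swimming mode and
reproductive guild). Traits with excessive missingness are dropped, the
remainder imputed with random-forest models, and the species x species
functional distance matrix computed with Gower's coefficient, the standard
dissimilarity for mixed continuous/categorical data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

__all__ = [
    "TraitTable",
    "filter_traits",
    "impute_traits",
    "gower_distance",
    "trait_correlation",
    "cramers_v",
]


@dataclass
class TraitTable:
    """Species x trait table with declared trait kinds.

    ``kinds`` maps each trait name to ``"continuous"`` or ``"categorical"``;
    ``levels`` optionally declares the admissible level set of each
    categorical trait (inferred from the data when absent). Missing entries
    are NaN (continuous) or NaN/None (categorical).
    """

    data: pd.DataFrame
    kinds: dict[str, str]
    levels: dict[str, list] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.data.columns) - set(self.kinds)
        if unknown:
            raise ValueError(f"traits without a declared kind: {sorted(unknown)}")
        bad = {k: v for k, v in self.kinds.items() if v not in (CONTINUOUS, CATEGORICAL)}
        if bad:
            raise ValueError(f"invalid trait kinds: {bad}")
        self.kinds = {c: self.kinds[c] for c in self.data.columns}
        for t in self.categorical:
            if t not in self.levels:
                vals = self.data[t].dropna().unique().tolist()
                self.levels[t] = sorted(map(str, vals))

    @property
    def species(self) -> pd.Index:
        return self.data.index

    @property
    def continuous(self) -> list[str]:
        return [t for t, k in self.kinds.items() if k == CONTINUOUS]

    @property
    def categorical(self) -> list[str]:
        return [t for t, k in self.kinds.items() if k == CATEGORICAL]

    def missing_fraction(self) -> pd.Series:
        return self.data.isna().mean(axis=0)

    def subset_species(self, species) -> "TraitTable":
        return TraitTable(self.data.loc[species].copy(), dict(self.kinds),
                          {k: list(v) for k, v in self.levels.items()})

    def drop_traits(self, names) -> "TraitTable":
        names = list(names)
        keep = [c for c in self.data.columns if c not in names]
        if len(keep) < 2:
            raise ValueError("removal would leave fewer than 2 traits")
        return TraitTable(
            self.data[keep].copy(),
            {k: v for k, v in self.kinds.items() if k in keep},
            {k: list(v) for k, v in self.levels.items() if k in keep},
        )

    def to_csv(self, path, schema_path=None) -> None:
        self.data.to_csv(path, index_label="species")
        if schema_path is not None:
            import json

            with open(schema_path, "w") as fh:
                json.dump({"kinds": self.kinds, "levels": self.levels}, fh, indent=1)

    @classmethod
    def from_csv(cls, path, schema_path) -> "TraitTable":
        import json

        with open(schema_path) as fh:
            schema = json.load(fh)
        df = pd.read_csv(path, index_col="species")
        for t, k in schema["kinds"].items():
            if k == CATEGORICAL:
                df[t] = df[t].astype(object)
        return cls(df, schema["kinds"], schema.get("levels", {}))


def filter_traits(table: TraitTable, max_missing: float = 0.30) -> TraitTable:
    """Drop traits whose missing fraction exceeds ``max_missing``.

    The boundary is inclusive: a trait with exactly ``max_missing`` missing
    data is retained. Names of dropped traits are reported in a warning.
    """
    frac = table.missing_fraction()
    dropped = frac.index[frac > max_missing].tolist()
    kept = [c for c in table.data.columns if c not in dropped]
    if not kept:
        raise ValueError("all traits exceed the missingness threshold")
    if dropped:
        warnings.warn(f"dropping traits over {max_missing:.0%} missing: {dropped}")
    return TraitTable(
        table.data[kept].copy(),
        {k: table.kinds[k] for k in kept},
        {k: list(v) for k, v in table.levels.items() if k in kept},
    )


def _simple_fill(table: TraitTable) -> pd.DataFrame:
    """Median/mode fill used to seed the iterative forest imputer."""
    df = table.data.copy()
    for t in table.continuous:
        df[t] = df[t].fillna(df[t].median())
    for t in table.categorical:
        mode = df[t].mode(dropna=True)
        if mode.empty:
            raise ValueError(f"trait {t!r} has no observed values")
        df[t] = df[t].fillna(mode.iloc[0])
    return df


def _encode(df: pd.DataFrame, table: TraitTable) -> np.ndarray:
    """One-hot categorical + raw continuous feature matrix for the forests."""
    parts = [df[table.continuous].to_numpy(dtype=float)] if table.continuous else []
    for t in table.categorical:
        lv = table.levels[t]
        onehot = (df[t].astype(str).to_numpy()[:, None] == np.array(lv)[None, :])
        parts.append(onehot.astype(float))
    return np.hstack(parts)


def impute_traits(table: TraitTable, seed: int = 0, n_estimators: int = 50,
                  max_iter: int = 3) -> TraitTable:
    """Fill missing trait values with iterative random-forest imputation.

    Missing entries are seeded with the trait median/mode and then refined:
    in each sweep, every trait with missing data is regressed (continuous,
    ``RandomForestRegressor``) or classified (categorical,
    ``RandomForestClassifier``) on all other traits, and its missing cells
    replaced by the model's predictions — the missForest scheme. Observed
    values are never altered; runs are deterministic under a fixed seed.
    """
    df = table.data
    all_missing = df.isna().all(axis=1)
    if all_missing.any():
        raise ValueError(
            f"species missing every trait: {df.index[all_missing].tolist()}"
        )
    if not df.isna().any().any():
        return table
    mask = df.isna()
    filled = _simple_fill(table)
    rng = np.random.default_rng(seed)
    traits_with_missing = [t for t in df.columns if mask[t].any()]
    for _ in range(max_iter):
        for t in traits_with_missing:
            miss = mask[t].to_numpy()
            others = table.drop_traits([t]) if len(df.columns) > 2 else None
            if others is None:
                break
            X = _encode(filled[others.data.columns], others)
            state = int(rng.integers(2**31 - 1))
            if table.kinds[t] == CONTINUOUS:
                est = RandomForestRegressor(
                    n_estimators=n_estimators, max_features="sqrt",
                    min_samples_leaf=5, random_state=state, n_jobs=1
                )
                est.fit(X[~miss], filled.loc[~miss, t].to_numpy(dtype=float))
                filled.loc[miss, t] = est.predict(X[miss])
            else:
                est = RandomForestClassifier(
                    n_estimators=n_estimators, max_features="sqrt",
                    min_samples_leaf=3, random_state=state, n_jobs=1
                )
                y = filled.loc[~miss, t].astype(str).to_numpy()
                if len(np.unique(y)) < 2:
                    continue  # nothing to learn; keep the mode fill
                est.fit(X[~miss], y)
                filled.loc[miss, t] = est.predict(X[miss])
    out = df.copy()
    for t in df.columns:
        out.loc[mask[t], t] = filled.loc[mask[t], t]
    return TraitTable(out, dict(table.kinds), {k: list(v) for k, v in table.levels.items()})


def gower_distance(table: TraitTable) -> pd.DataFrame:
    """Species x species Gower distance matrix.

    Each continuous trait contributes |x_i - x_j| / range(trait) (zero-range
    traits contribute 0); each categorical trait contributes the mismatch
    indicator. The distance is the unweighted mean over traits, so
    0 <= d_ij <= 1 with d_ii = 0. Ranges are taken over the species pool of
    the table, consistent with per-system analyses.
    """
    df = table.data
    n = len(df)
    if n < 2:
        raise ValueError("need at least 2 species for pairwise distances")
    if df.isna().any().any():
        raise ValueError("impute traits before computing distances")
    acc = np.zeros((n, n))
    for t in table.continuous:
        x = df[t].to_numpy(dtype=float)
        rng_ = np.ptp(x)
        if rng_ > 0:
            acc += np.abs(x[:, None] - x[None, :]) / rng_
    for t in table.categorical:
        x = df[t].astype(str).to_numpy()
        acc += (x[:, None] != x[None, :]).astype(float)
    acc /= len(df.columns)
    np.fill_diagonal(acc, 0.0)
    return pd.DataFrame(acc, index=df.index, columns=df.index)


def cramers_v(table: np.ndarray) -> float:
    """Cramér's V from the Pearson chi-square of a contingency table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0 or min(table.shape) < 2:
        return 0.0
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    return float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))


def _quartile_bin(x: np.ndarray) -> np.ndarray:
    edges = np.quantile(x, [0.25, 0.5, 0.75])
    return np.searchsorted(edges, x, side="left")


def trait_correlation(table: TraitTable) -> pd.DataFrame:
    """Pairwise trait association matrix (diagnostic for redundant traits).

    Continuous-continuous pairs use Pearson's r; any pair involving a
    categorical trait uses Cramér's V, with continuous traits discretized
    into quartile bins. Diagonal is 1. Constant traits associate 0 with
    everything (warned).
    """
    cols = list(table.data.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    df = table.data
    const = [
        t for t in cols
        if df[t].dropna().nunique() <= 1
    ]
    if const:
        warnings.warn(f"constant trait(s) {const}: associations reported as 0")
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if a in const or b in const:
                val = 0.0
            elif table.kinds[a] == CONTINUOUS and table.kinds[b] == CONTINUOUS:
                pair = df[[a, b]].dropna()
                val = float(stats.pearsonr(pair[a], pair[b])[0])
            else:
                pair = df[[a, b]].dropna()
                xa = (_quartile_bin(pair[a].to_numpy(dtype=float))
                      if table.kinds[a] == CONTINUOUS else pair[a].astype(str))
                xb = (_quartile_bin(pair[b].to_numpy(dtype=float))
                      if table.kinds[b] == CONTINUOUS else pair[b].astype(str))
                val = cramers_v(pd.crosstab(xa, xb).to_numpy())
            out.loc[a, b] = out.loc[b, a] = val
    return out
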