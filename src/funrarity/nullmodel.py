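"""Curveball fixed-margins randomization and standardized effect sizes.

The curveball algorithm randomizes a binary species x cell matrix while
keeping every row sum (each species' geographic extent) and every column
sum (each cell's richness) fixed: two species are drawn at random and the
cells held by exactly one of them are re-dealt between the pair. A long
chain of such trades samples (uniformly, in the limit) from the set of
binary matrices with the observed margins.

Observed per-cell rare-species counts X are compared with the null
distribution of the same count across randomized matrices via the
standardized effect size SES = (X - Y) / Z, with Y the null mean and Z the
null (sample) standard deviation; SES > 2 marks a rarity hotspot.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .occupancy import AssemblageMatrix, GridSpec

__all__ = [
    "curveball_trade",
    "randomize",
    "null_distribution",
    "compute_ses",
    "NullEnsemble",
]


def _rows_to_sets(matrix: np.ndarray) -> list[set[int]]:
    return [set(np.nonzero(row)[0].tolist()) for row in matrix]


def _sets_to_matrix(rows: list[set[int]], n_cols: int) -> np.ndarray:
    out = np.zeros((len(rows), n_cols), dtype=np.int8)
    for i, s in enumerate(rows):
        out[i, list(s)] = 1
    return out


def _trade(rows: list[set[int]], i: int, j: int, shuffle) -> None:
    """One curveball trade between rows i and j, in place.

    The columns held by exactly one of the two rows are pooled, shuffled,
    and re-dealt so each row keeps its count. Margins are untouched; a
    trade between identical rows is a no-op.
    """
    a, b = rows[i], rows[j]
    a_only = list(a - b)
    b_only = list(b - a)
    if not a_only or not b_only:
        return  # nothing exchangeable: nested rows leave no degrees of freedom
    pool = a_only + b_only
    shuffle(pool)
    na = len(a_only)
    rows[i] = (a - set(a_only)) | set(pool[:na])
    rows[j] = (b - set(b_only)) | set(pool[na:])


def _as_python_rng(rng) -> random.Random:
    """Derive a fast stdlib RNG from a numpy Generator (or pass one through)."""
    if isinstance(rng, random.Random):
        return rng
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return random.Random(int(rng.integers(2**63)))


def curveball_trade(matrix: np.ndarray, rng) -> np.ndarray:
    """Apply a single curveball trade to a copy of ``matrix``.

    ``rng`` is a numpy Generator (or seed). Row and column sums are exactly
    preserved.
    """
    matrix = np.asarray(matrix)
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to trade")
    pyrng = _as_python_rng(rng)
    rows = _rows_to_sets(matrix)
    i, j = pyrng.sample(range(len(rows)), 2)
    _trade(rows, i, j, pyrng.shuffle)
    return _sets_to_matrix(rows, matrix.shape[1])


def randomize(matrix: np.ndarray, n_trades: int, rng) -> np.ndarray:
    """Apply ``n_trades`` sequential curveball trades to a copy of ``matrix``."""
    matrix = np.asarray(matrix)
    if n_trades == 0:
        return matrix.copy()
    if n_trades < 0:
        raise ValueError("n_trades must be >= 0")
    pyrng = _as_python_rng(rng)
    rows = _rows_to_sets(matrix)
    _run_chain(rows, n_trades, pyrng)
    return _sets_to_matrix(rows, matrix.shape[1])


def _run_chain(rows: list[set[int]], n_trades: int, pyrng: random.Random) -> None:
    n = len(rows)
    randrange = pyrng.randrange
    shuffle = pyrng.shuffle
    for _ in range(n_trades):
        i = randrange(n)
        j = randrange(n - 1)
        if j >= i:
            j += 1
        _trade(rows, i, j, shuffle)


@dataclass
class NullEnsemble:
    """Per-cell rare-species counts across null-model iterations.

    ``counts`` has one row per iteration, one column per cell (in
    ``cells`` order). Every underlying randomized matrix shares the
    observed matrix's row and column sums.
    """

    counts: np.ndarray
    cells: pd.Index
    n_iterations: int
    trades_per_iteration: int
    burn_in: int
    seed: int | None = None

    def mean(self) -> pd.Series:
        return pd.Series(self.counts.mean(axis=0), index=self.cells, name="Y")

    def std(self) -> pd.Series:
        ddof = 1 if self.n_iterations > 1 else 0
        return pd.Series(self.counts.std(axis=0, ddof=ddof), index=self.cells, name="Z")


def null_distribution(
    assemblage: AssemblageMatrix,
    rare,
    n_iterations: int = 2000,
    trades_per_iteration: int | None = None,
    burn_in: int | None = None,
    seed: int | None = None,
) -> NullEnsemble:
    """Null distribution of per-cell rare counts under fixed margins.

    One sequential chain is run over the *full* system matrix (rare and
    non-rare species together, so richness constraints carry over): after a
    burn-in of ``5 * max(n_species, n_cells)`` trades, one sample is taken
    every ``n_species`` trades (both overridable). Rare identity is fixed to
    species labels; only occurrences move.
    """
    rare = pd.Index(rare)
    missing = rare.difference(assemblage.species)
    if len(missing):
        raise ValueError(f"rare species absent from assemblage: {missing.tolist()}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    mat = assemblage.data.to_numpy()
    n_rows, n_cols = mat.shape
    if trades_per_iteration is None:
        trades_per_iteration = n_rows
    if burn_in is None:
        burn_in = 5 * max(n_rows, n_cols)
    counts = np.zeros((n_iterations, n_cols), dtype=np.int32)
    if len(rare) == 0:
        warnings.warn("empty rare set: null ensemble is identically zero")
        return NullEnsemble(counts, assemblage.cells, n_iterations,
                            trades_per_iteration, burn_in, seed)
    rare_pos = [assemblage.species.get_loc(s) for s in rare]
    pyrng = _as_python_rng(np.random.default_rng(seed))
    rows = _rows_to_sets(mat)
    _run_chain(rows, burn_in, pyrng)
    buf = np.zeros(n_cols, dtype=np.int32)
    for it in range(n_iterations):
        _run_chain(rows, trades_per_iteration, pyrng)
        buf[:] = 0
        for r in rare_pos:
            buf[list(rows[r])] += 1
        counts[it] = buf
    return NullEnsemble(counts, assemblage.cells, n_iterations,
                        trades_per_iteration, burn_in, seed)


def compute_ses(
    observed: pd.Series,
    ensemble: NullEnsemble,
    richness: pd.Series | None = None,
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """Per-cell summary: X, null mean Y, null sd Z, SES and degeneracy flag.

    SES = (X - Y)/Z with Z the sample standard deviation of the null
    counts. Cells with Z = 0 are flagged degenerate: SES is 0 when X = Y
    and signed infinity otherwise (such cells are excluded from SES maps).
    """
    if not observed.index.equals(ensemble.cells):
        if set(observed.index) != set(ensemble.cells):
            raise ValueError("observed counts and ensemble cover different cells")
        observed = observed.loc[ensemble.cells]
    x = observed.to_numpy(dtype=float)
    y = ensemble.mean().to_numpy()
    z = ensemble.std().to_numpy()
    degenerate = z == 0
    ses = np.zeros(len(x))
    ok = ~degenerate
    ses[ok] = (x[ok] - y[ok]) / z[ok]
    ses[degenerate & (x != y)] = np.sign((x - y)[degenerate & (x != y)]) * np.inf
    out = pd.DataFrame(
        {"X": observed.to_numpy(), "Y": y, "Z": z, "SES": ses,
         "degenerate": degenerate},
        index=ensemble.cells,
    )
    if richness is not None:
        out.insert(0, "richness", richness.loc[ensemble.cells].to_numpy())
    if grid is not None:
        cent = grid.centroids(ensemble.cells)
        out.insert(0, "lon", cent["lon"].to_numpy())
        out.insert(0, "lat", cent["lat"].to_numpy())
    out.index.name = "cell_id"
    return out
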