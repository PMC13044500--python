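"""Barber bipartite modularity, fixed-margin null models, and z-scores.

Barber's modularity for a bipartite weighted matrix A (rows = habitats,
columns = species) with row sums k, column sums d and total weight m is

    Q = (1/m) * sum_ij (A_ij - k_i d_j / m) * delta(g_i, h_j),

maximized over joint assignments g (rows) and h (columns) to modules. Only
row-column pairs contribute, so for a fixed partition of the rows each
column's optimal module can be chosen independently; this makes exhaustive
search over row set-partitions exact and fast for the small row counts of
habitat networks (<= 7 habitats). Larger matrices fall back to a seeded
label-propagation optimizer with agglomerative merging and random restarts
(in the style of DIRT-LPA-wb+).

Null models: Patefield draws (uniform over integer matrices with the
observed margins, via sequential multivariate hypergeometric rows) for
weighted matrices, and curveball trades (degree-preserving) for binary
matrices. Index values over a null ensemble are summarized as z-scores
(observed - null mean) / null sd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import HabitatNetwork
from .survey import SurveyDataError

#: Largest row count for which the exact set-partition search is used.
EXACT_MAX_ROWS = 7


@dataclass
class ModularityResult:
    """Optimized Barber modularity with the attaining partition."""

    q: float
    row_labels: np.ndarray
    col_labels: np.ndarray
    n_modules: int
    weighted: bool
    degenerate: bool = False  # single row/column: no between-module structure


@dataclass
class NullEnsemble:
    """Replicate statistics from null matrices with derived mean, sd, z."""

    statistic: str
    observed: float
    values: np.ndarray = field(repr=False)

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.values, ddof=1))

    @property
    def z(self) -> float:
        sd = self.null_sd
        if sd == 0:
            return float("nan")
        return (self.observed - self.null_mean) / sd


def barber_q(matrix: np.ndarray, row_labels, col_labels) -> float:
    """Evaluate Barber's Q for a given joint module assignment."""
    a = np.asarray(matrix, dtype=float)
    m = a.sum()
    if m <= 0:
        raise SurveyDataError("modularity of an all-zero matrix is undefined")
    k = a.sum(axis=1)
    d = a.sum(axis=0)
    b = a - np.outer(k, d) / m
    same = np.equal.outer(np.asarray(row_labels), np.asarray(col_labels))
    return float((b * same).sum() / m)


def _set_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, max_label: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0) if n > 1 else iter([labels.copy()])


def _exact_optimum(b: np.ndarray, m: float):
    """Exact maximum of Q by enumerating row set-partitions.

    For each partition, column j joins the row-module with the largest
    summed null-corrected weight, or stays in its own (empty) module when
    every choice is negative.
    """
    n_rows, n_cols = b.shape
    best_q = -np.inf
    best = None
    for part in _set_partitions(n_rows):
        n_mod = part.max() + 1
        group = np.zeros((n_mod, n_cols))
        for mod in range(n_mod):
            group[mod] = b[part == mod].sum(axis=0)
        col_best = group.max(axis=0)
        gains = np.maximum(col_best, 0.0)
        q = gains.sum() / m
        if q > best_q + 1e-15:
            best_q = q
            col_labels = group.argmax(axis=0)
            lone = col_best <= 0
            col_labels = np.where(lone, n_mod + np.arange(n_cols), col_labels)
            best = (part.copy(), col_labels)
    return best_q, best


def _propagation_optimum(b: np.ndarray, m: float, n_starts: int, rng):
    """Label propagation with agglomerative merging, best of n_starts."""
    n_rows, n_cols = b.shape
    best_q, best = -np.inf, None
    for _ in range(max(1, n_starts)):
        rows = rng.permutation(n_rows) % min(n_rows, n_cols)
        for _sweep in range(200):
            # columns adopt their best row-module
            gains = np.zeros((rows.max() + 1, n_cols))
            for mod in range(rows.max() + 1):
                gains[mod] = b[rows == mod].sum(axis=0)
            cols = gains.argmax(axis=0)
            lone = gains.max(axis=0) <= 0
            cols = np.where(lone, rows.max() + 1 + np.arange(n_cols), cols)
            # rows adopt their best column-module
            new_rows = rows.copy()
            for i in range(n_rows):
                cand = {}
                for mod in np.unique(np.concatenate([rows, cols])):
                    cand[mod] = b[i, cols == mod].sum()
                new_rows[i] = max(sorted(cand), key=lambda c: cand[c])
            if np.array_equal(new_rows, rows):
                break
            rows = new_rows
        # relabel contiguously
        uniq = {lab: i for i, lab in enumerate(np.unique(rows))}
        rows = np.array([uniq[r] for r in rows])
        gains = np.zeros((rows.max() + 1, n_cols))
        for mod in range(rows.max() + 1):
            gains[mod] = b[rows == mod].sum(axis=0)
        cols = gains.argmax(axis=0)
        lone = gains.max(axis=0) <= 0
        cols = np.where(lone, rows.max() + 1 + np.arange(n_cols), cols)
        q = np.maximum(gains.max(axis=0), 0).sum() / m

        # agglomerative: merge row-module pairs while Q improves
        improved = True
        while improved and rows.max() > 0:
            improved = False
            mods = np.unique(rows)
            for i_m in range(len(mods)):
                for j_m in range(i_m + 1, len(mods)):
                    trial = rows.copy()
                    trial[trial == mods[j_m]] = mods[i_m]
                    gains = np.zeros((trial.max() + 1, n_cols))
                    for mod in range(trial.max() + 1):
                        gains[mod] = b[trial == mod].sum(axis=0)
                    q_trial = np.maximum(gains.max(axis=0), 0).sum() / m
                    if q_trial > q + 1e-12:
                        rows, q = trial, q_trial
                        cols = gains.argmax(axis=0)
                        lone = gains.max(axis=0) <= 0
                        cols = np.where(lone, trial.max() + 1 + np.arange(n_cols),
                                        cols)
                        improved = True
                        break
                if improved:
                    break
        if q > best_q:
            best_q, best = q, (rows, cols)
    return best_q, best


def barber_modularity(
    matrix,
    weighted: bool = True,
    n_starts: int = 20,
    seed: int = 0,
) -> ModularityResult:
    """Maximize Barber's bipartite modularity.

    Accepts an array or DataFrame (rows = habitats, columns = species).
    ``weighted=False`` binarizes the matrix first. Single-row or
    single-column matrices have no between-module structure: Q = 0 with the
    degenerate flag set.
    """
    a = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    a = a.astype(float)
    if (a < 0).any():
        raise SurveyDataError("matrix entries must be nonnegative")
    if not weighted:
        a = (a > 0).astype(float)
    m = a.sum()
    if m <= 0:
        raise SurveyDataError("modularity of an all-zero matrix is undefined")

    n_rows, n_cols = a.shape
    if n_rows == 1 or n_cols == 1:
        return ModularityResult(
            q=0.0,
            row_labels=np.zeros(n_rows, dtype=int),
            col_labels=np.zeros(n_cols, dtype=int),
            n_modules=1, weighted=weighted, degenerate=True,
        )

    k = a.sum(axis=1)
    d = a.sum(axis=0)
    b = a - np.outer(k, d) / m

    transposed = False
    if min(n_rows, n_cols) <= EXACT_MAX_ROWS:
        bb = b if n_rows <= n_cols else b.T
        transposed = n_rows > n_cols
        q, (r_lab, c_lab) = _exact_optimum(bb, m)
    else:
        rng = np.random.default_rng(seed)
        q, (r_lab, c_lab) = _propagation_optimum(b, m, n_starts, rng)

    if transposed:
        r_lab, c_lab = c_lab, r_lab
    n_modules = len(np.unique(np.concatenate([r_lab, c_lab])))
    return ModularityResult(
        q=float(q), row_labels=np.asarray(r_lab), col_labels=np.asarray(c_lab),
        n_modules=int(n_modules), weighted=weighted,
    )


def patefield_null(matrix, rng) -> np.ndarray:
    """One uniform draw from integer matrices with the observed margins.

    Rows are filled sequentially from the multivariate hypergeometric
    distribution of the remaining column capacities — the exact conditional
    law under the fixed-margins uniform model, as in Patefield's algorithm.
    """
    a = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    if not np.allclose(a, np.round(a)) or (a < 0).any():
        raise SurveyDataError("Patefield nulls need a nonnegative integer matrix")
    a = np.round(a).astype(np.int64)
    if a.sum() <= 0:
        raise SurveyDataError("Patefield nulls need a positive matrix total")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    row_sums = a.sum(axis=1)
    remaining = a.sum(axis=0).copy()
    out = np.zeros_like(a)
    for i, r in enumerate(row_sums[:-1]):
        draw = rng.multivariate_hypergeometric(remaining, int(r))
        out[i] = draw
        remaining -= draw
    out[-1] = remaining
    return out


def curveball_null(matrix, rng, n_sweeps: int = 5) -> np.ndarray:
    """Degree-preserving randomization of a binary matrix by curveball trades.

    Performs ``n_sweeps * n_rows`` random row-pair trades of swappable
    presences. A matrix with no swappable checkerboard (e.g., all ones) is
    returned unchanged with a warning.
    """
    a = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    if not set(np.unique(a)) <= {0, 1}:
        raise SurveyDataError("curveball nulls need a binary matrix")
    a = a.astype(np.int8).copy()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    n_rows = a.shape[0]
    if n_rows < 2:
        return a
    traded = False
    for _ in range(n_sweeps * n_rows * (n_rows - 1) // 2):
        i, j = rng.choice(n_rows, size=2, replace=False)
        only_i = np.flatnonzero(a[i] & ~a[j])
        only_j = np.flatnonzero(a[j] & ~a[i])
        n_trade = min(len(only_i), len(only_j))
        if n_trade == 0:
            continue
        traded = True
        # reshuffle the union of exclusive presences between the two rows
        pool = np.concatenate([only_i, only_j])
        rng.shuffle(pool)
        take_i = pool[: len(only_i)]
        a[i, only_i] = 0
        a[j, only_j] = 0
        a[i, take_i] = 1
        a[j, np.setdiff1d(pool, take_i)] = 1
    if not traded:
        warnings.warn("no swappable checkerboard found; matrix returned unchanged",
                      stacklevel=2)
    return a


def zscore(observed: float, values, statistic: str = "modularity") -> NullEnsemble:
    """Standardize an observed index against a null ensemble."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise SurveyDataError("z-scores need at least two null replicates")
    return NullEnsemble(statistic=statistic, observed=float(observed), values=vals)


def modularity_zscores(
    networks: dict[str, HabitatNetwork],
    n_null: int = 1000,
    seed: int = 0,
    weighted: bool = True,
    n_starts: int = 20,
) -> pd.DataFrame:
    """Observed and null-standardized modularity for every landscape.

    Landscapes whose network has a single habitat row appear with their
    observed (degenerate) modularity but no z-score: a one-row matrix admits
    no between-module structure, so standardization is meaningless there.
    Null replicates use independent child RNG streams per landscape, so
    results do not depend on landscape iteration order.
    """
    root = np.random.SeedSequence(seed)
    lids = sorted(networks)
    children = dict(zip(lids, root.spawn(len(lids))))

    rows = []
    for lid in lids:
        net = networks[lid]
        obs = barber_modularity(net.matrix, weighted=weighted,
                                n_starts=n_starts, seed=seed)
        row = {
            "landscape_id": lid, "q_obs": obs.q, "n_modules": obs.n_modules,
            "mod_z": np.nan, "null_mean": np.nan, "null_sd": np.nan,
            "n_null": n_null, "weighted": weighted, "degenerate": obs.degenerate,
        }
        if not obs.degenerate:
            rng = np.random.default_rng(children[lid])
            mat = net.matrix.to_numpy()
            if not weighted:
                vals = [
                    barber_modularity(
                        curveball_null((mat > 0).astype(int), rng),
                        weighted=False, n_starts=n_starts, seed=seed,
                    ).q
                    for _ in range(n_null)
                ]
            else:
                vals = [
                    barber_modularity(
                        patefield_null(mat, rng), weighted=True,
                        n_starts=n_starts, seed=seed,
                    ).q
                    for _ in range(n_null)
                ]
            ens = zscore(obs.q, vals)
            row.update(mod_z=ens.z, null_mean=ens.null_mean, null_sd=ens.null_sd)
        rows.append(row)
    return pd.DataFrame(rows)
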