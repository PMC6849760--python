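"""Community-composition statistics: rarefaction, Bray-Curtis, PCoA, PERMANOVA.

All four primitives are implemented from first principles on plain
numpy/pandas structures:

* rarefaction — exact without-replacement subsampling (multivariate
  hypergeometric), single seeded draw per sample;
* Bray-Curtis — sum|u-v| / sum(u+v) on count vectors;
* PCoA — Gower double-centring + eigendecomposition, coordinates scaled by
  sqrt(eigenvalue); negative eigenvalues are reported, never dropped
  silently;
* PERMANOVA — sequential (Type-I) sums of squares partitioned directly from
  the distance matrix via projection matrices, pseudo-F per term, p-values
  by seeded label permutation with the +1 correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "filter_and_rarefy",
    "bray_curtis",
    "pcoa",
    "PCoAResult",
    "permanova",
]


def filter_and_rarefy(
    table: pd.DataFrame,
    min_reads: int = 1000,
    depth: Optional[int] = None,
    seed: Optional[int] = 0,
) -> pd.DataFrame:
    """Drop shallow samples and subsample the rest to a common depth.

    Rows with total reads strictly below ``min_reads`` are removed (a row at
    exactly ``min_reads`` is retained); remaining rows are subsampled without
    replacement to ``depth`` (default: the minimum retained row sum).
    """
    counts = table.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise DataError("ASV counts must be integers")
        counts = counts.astype(np.int64)
    if np.any(counts < 0):
        raise DataError("ASV counts must be non-negative")
    row_sums = counts.sum(axis=1)
    keep = row_sums >= min_reads
    if not keep.any():
        raise DataError(f"all {len(table)} samples fall below min_reads={min_reads}")
    counts = counts[keep]
    row_sums = row_sums[keep]
    depth = int(row_sums.min()) if depth is None else int(depth)
    if depth > row_sums.min():
        raise DataError(f"depth {depth} exceeds the smallest retained row sum {row_sums.min()}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return pd.DataFrame(out, index=table.index[keep], columns=table.columns)


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity: sum|u-v| / sum(u+v), in [0, 1]."""
    counts = table.to_numpy(dtype=float)
    sums = counts.sum(axis=1)
    if np.any(sums <= 0):
        empty = table.index[sums <= 0].tolist()
        raise DataError(f"Bray-Curtis undefined for empty samples: {empty}")
    diff = np.abs(counts[:, None, :] - counts[None, :, :]).sum(axis=2)
    tot = sums[:, None] + sums[None, :]
    d = diff / tot
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=table.index, columns=table.index)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def _check_distance_matrix(dm: pd.DataFrame) -> np.ndarray:
    d = dm.to_numpy(dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DataError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise DataError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise DataError("distance matrix must have a zero diagonal")
    return d


def _gower_centre(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(distance_matrix: pd.DataFrame) -> PCoAResult:
    """Principal coordinates of a distance matrix.

    Coordinates are eigenvectors scaled by the square root of their (positive)
    eigenvalues; the proportion explained is over positive eigenvalues only,
    and any negative eigenvalues are returned for inspection.
    """
    d = _check_distance_matrix(distance_matrix)
    g = _gower_centre(d)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-10 * abs(eigvals[0]), 1e-12) if eigvals.size else eigvals > 0
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=distance_matrix.index, columns=axes),
        eigenvalues=eigvals[pos],
        proportion_explained=eigvals[pos] / eigvals[pos].sum(),
        negative_eigenvalues=eigvals[eigvals < 0],
    )


def _hat(X: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(X)
    return q @ q.T


def _dummy(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Drop-first treatment coding; returns the columns and their count."""
    levels = sorted(set(values))
    if len(levels) < 2:
        raise DataError(f"factor needs >= 2 levels, got {levels}")
    cols = [np.asarray(values == lv, dtype=float) for lv in levels[1:]]
    return np.column_stack(cols), len(cols)


def permanova(
    distance_matrix: pd.DataFrame,
    factors: pd.DataFrame,
    n_perm: int = 9999,
    seed: Optional[int] = 0,
    order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Sequential-SS permutational multivariate ANOVA on a distance matrix.

    ``factors`` holds one column per main effect, aligned with the distance
    matrix; terms enter in ``order`` (default: column order). Significance is
    assessed by permuting sample labels, ``p = (1 + #{F* >= F}) / (1 + n_perm)``.
    Returns a table with one row per term plus a residual row (df, SS,
    pseudo-F, partial R2, p).
    """
    d = _check_distance_matrix(distance_matrix)
    n = d.shape[0]
    if len(factors) != n:
        raise DataError("factor table and distance matrix differ in length")
    if not distance_matrix.index.equals(factors.index):
        factors = factors.reindex(distance_matrix.index)
        if factors.isna().any().any():
            raise DataError("factor table is missing samples present in the distance matrix")
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    terms = list(order) if order is not None else list(factors.columns)
    if set(terms) != set(factors.columns):
        raise DataError("order must be a permutation of the factor columns")

    blocks, dfs = [], []
    for term in terms:
        cols, df_term = _dummy(factors[term].to_numpy())
        blocks.append(cols)
        dfs.append(df_term)
    intercept = np.ones((n, 1))
    full = np.column_stack([intercept] + blocks)
    expected_rank = 1 + sum(dfs)
    if np.linalg.matrix_rank(full) < expected_rank:
        raise DataError(f"factors are confounded (aliased design): {terms}")

    g = _gower_centre(d)
    ss_total = float(np.trace(g))

    # incremental projections: H_0 = intercept, then cumulative per term
    hats = [_hat(intercept)]
    for k in range(len(terms)):
        hats.append(_hat(np.column_stack([intercept] + blocks[: k + 1])))
    h_increments = [hats[k + 1] - hats[k] for k in range(len(terms))]
    h_resid = np.eye(n) - hats[-1]
    df_resid = n - expected_rank
    if df_resid <= 0:
        raise DataError("no residual degrees of freedom")

    def term_stats(gmat):
        ss_terms = np.array([float(np.sum(h * gmat)) for h in h_increments])
        ss_res = float(np.sum(h_resid * gmat))
        f = (ss_terms / np.array(dfs)) / (ss_res / df_resid)
        return ss_terms, ss_res, f

    ss_obs, ss_res_obs, f_obs = term_stats(g)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, _, f_perm = term_stats(g[np.ix_(perm, perm)])
        exceed += f_perm >= f_obs - 1e-12
    p_values = (1.0 + exceed) / (1.0 + n_perm)

    rows = [
        {
            "term": term,
            "df": dfs[k],
            "ss": ss_obs[k],
            "pseudo_F": f_obs[k],
            "partial_R2": ss_obs[k] / ss_total,
            "p": p_values[k],
        }
        for k, term in enumerate(terms)
    ]
    rows.append(
        {
            "term": "residual",
            "df": df_resid,
            "ss": ss_res_obs,
            "pseudo_F": np.nan,
            "partial_R2": ss_res_obs / ss_total,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("term")
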