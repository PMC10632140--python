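"""Target-gene (NTRK2) co-expression analysis across malignant cell states.

Per-state detection rate of the target gene, 10-nearest-neighbour smoothing
of its expression on the 2-D lineage/stemness embedding (for visualization),
per-state centred Pearson co-expression with every analysable gene, and
threshold-based gene selection (|r| > 0.25 in at least one state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .expression import STATE_NAMES, UNRESOLVED, ExpressionMatrix

__all__ = [
    "detection_rate",
    "knn_smooth",
    "per_state_correlation",
    "select_correlated_genes",
]

_R_COLUMNS = {s: f"r_{s.split('-')[0]}" for s in STATE_NAMES}


def _target_row(log_matrix: ExpressionMatrix, target_gene: str) -> np.ndarray:
    if target_gene not in log_matrix.gene_ids:
        raise KeyError(f"target gene {target_gene!r} not in matrix")
    return log_matrix.values[log_matrix.gene_ids.get_loc(target_gene)]


def detection_rate(
    log_matrix: ExpressionMatrix,
    target_gene: str,
    assignments: pd.Series,
    state_names: Sequence[str] = STATE_NAMES,
) -> pd.Series:
    """Fraction of cells per state expressing the target gene above zero.

    ``log2(TPM/10 + 1) > 0`` iff ``TPM > 0``, so positivity is the same on
    either scale.  Unresolved cells are excluded; a state with no assigned
    cells yields a missing value (NaN), not zero.
    """
    assignments = assignments.reindex(log_matrix.cell_ids)
    if assignments.isna().any():
        raise ValueError("assignments must cover every cell in the matrix")
    expr = _target_row(log_matrix, target_gene)
    out = {}
    for state in state_names:
        in_state = (assignments == state).to_numpy()
        out[state] = float((expr[in_state] > 0).mean()) if in_state.any() else np.nan
    return pd.Series(out, name=f"{target_gene}_detection_rate")


@dataclass
class SmoothedValues:
    """kNN-smoothed per-cell values on a 2-D embedding."""

    table: pd.DataFrame  # columns: raw, smoothed
    k: int
    coords: np.ndarray


def knn_smooth(
    values: pd.Series | np.ndarray,
    coords: np.ndarray,
    k: int = 10,
    include_self: bool = False,
) -> SmoothedValues:
    """Replace each cell's value by the mean over its k nearest neighbours.

    Neighbours are the k Euclidean-nearest *other* cells in ``coords``
    (typically the lineage/stemness plane); ``include_self`` switches to a
    self-inclusive neighbourhood.  Distance ties are broken by ascending cell
    index, making the result fully deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(values, pd.Series):
        index = values.index
        vals = values.to_numpy(float)
    else:
        vals = np.asarray(values, dtype=float).ravel()
        index = pd.RangeIndex(vals.size)
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != vals.size:
        raise ValueError("coords and values must have matching length")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")
    n = vals.size
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells, got {n}")

    d = cdist(coords, coords)
    if not include_self:
        np.fill_diagonal(d, np.inf)
    # stable argsort => ties broken by ascending cell index
    nbrs = np.argsort(d, axis=1, kind="stable")[:, :k]
    smoothed = vals[nbrs].mean(axis=1)
    table = pd.DataFrame({"raw": vals, "smoothed": smoothed}, index=index)
    table.index.name = "cell_id"
    return SmoothedValues(table=table, k=k, coords=coords)


def per_state_correlation(
    log_matrix: ExpressionMatrix,
    target_gene: str,
    assignments: pd.Series,
    genes: Sequence[str] | None = None,
    abs_threshold: float = 0.25,
    state_names: Sequence[str] = STATE_NAMES,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of every analysable gene with the target, per state.

    The matrix (restricted to ``genes``) is first centred gene-wise across
    the pooled assignable cells; the correlation for a state is then the
    normalized inner product of the centred target row and each centred gene
    row over that state's cells, without re-centring within the state.  A
    state in which the target has zero variance yields missing values and a
    warning.

    Returns a genes x states table with columns ``r_AC, r_OC, r_OPC`` and a
    ``passes_any`` flag (|r| > ``abs_threshold`` in at least one state).
    """
    assignments = assignments.reindex(log_matrix.cell_ids)
    if assignments.isna().any():
        raise ValueError("assignments must cover every cell in the matrix")
    genes = list(log_matrix.gene_ids) if genes is None else list(genes)
    if target_gene not in genes:
        raise ValueError("target gene must be among the analysable genes")
    mat = log_matrix.subset_genes(genes)

    assignable = assignments.isin(state_names).to_numpy()
    if assignable.sum() == 0:
        raise ValueError("no assignable cells")
    values = mat.values[:, assignable]
    labels = assignments.to_numpy()[assignable]
    centred = values - values.mean(axis=1, keepdims=True)
    t = centred[mat.gene_ids.get_loc(target_gene)]

    table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for state in state_names:
        col = _R_COLUMNS[state]
        in_state = labels == state
        if in_state.sum() < min_cells:
            warnings.warn(
                f"state {state!r} has fewer than {min_cells} cells; "
                "correlations set to missing",
                stacklevel=2,
            )
            table[col] = np.nan
            continue
        x = t[in_state]
        xn = float(np.sqrt(np.sum(x * x)))
        # a target constant within the state has no co-variation to correlate
        if xn == 0.0 or np.ptp(x) == 0.0:
            warnings.warn(
                f"target gene has zero variance in state {state!r}; "
                "correlations set to missing",
                stacklevel=2,
            )
            table[col] = np.nan
            continue
        g = centred[:, in_state]
        gn = np.sqrt(np.sum(g * g, axis=1))
        degenerate = (gn == 0.0) | (np.ptp(g, axis=1) == 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (g @ x) / (gn * xn)
        r[degenerate] = np.nan
        table[col] = np.clip(r, -1.0, 1.0)
    rcols = [_R_COLUMNS[s] for s in state_names]
    table["passes_any"] = (table[rcols].abs() > abs_threshold).any(axis=1)
    return table


def select_correlated_genes(
    table: pd.DataFrame,
    abs_threshold: float = 0.25,
    target_gene: str | None = None,
    state_names: Sequence[str] = STATE_NAMES,
) -> dict:
    """Threshold-based gene selection from a per-state correlation table.

    Returns ``{"union": [...], "positive": {state: [...]}}`` where the union
    set holds genes with |r| strictly greater than ``abs_threshold`` in at
    least one state and each per-state positive set holds genes with
    r > ``abs_threshold`` in that state.  Missing correlations never pass;
    the target gene itself is excluded from all reported sets.
    """
    rcols = [_R_COLUMNS[s] for s in state_names]
    sub = table[rcols]
    keep = table.index != target_gene
    union_mask = (sub.abs() > abs_threshold).any(axis=1) & keep
    positive = {
        state: list(table.index[(sub[_R_COLUMNS[state]] > abs_threshold) & keep])
        for state in state_names
    }
    return {"union": list(table.index[union_mask]), "positive": positive}
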