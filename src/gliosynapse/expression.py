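"""Single-cell expression transforms, malignant-programme scoring and state assignment.

The analysis operates on a genes x cells TPM matrix.  Expression is taken to
log2 space as ``log2(TPM/10 + 1)``; genes are kept when their mean log2
expression over the malignant cells exceeds 0.25.  Each malignant cell is then
scored for the three malignant programmes (AC-like, OC-like, OPC-like) with a
bin-matched-control signature score, assigned the argmax state when the maximal
score exceeds 0.5 (otherwise "unresolved"), and placed on a two-dimensional
lineage/stemness hierarchy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATE_NAMES",
    "UNRESOLVED",
    "ExpressionMatrix",
    "Signature",
    "transform_expression",
    "filter_analysable_genes",
    "score_signature",
    "score_signatures",
    "assign_state",
    "hierarchy_coords",
]

#: Canonical malignant cell-state programme names, in fixed order.
STATE_NAMES = ("AC-like", "OC-like", "OPC-like")

#: Label for cells whose maximal state score does not clear the threshold.
UNRESOLVED = "unresolved"


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with per-cell metadata.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_cells)`` array.  Non-negative TPM when
        ``is_log`` is False, ``log2(TPM/10 + 1)`` units otherwise.
    gene_ids, cell_ids
        Unique identifiers for rows and columns.
    cell_meta
        Per-cell metadata indexed by ``cell_ids``; expected columns are
        ``sample`` and ``malignant`` (bool).
    is_log
        Whether ``values`` is already log-transformed.
    """

    values: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame = None
    is_log: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells array")
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValueError("gene_ids/cell_ids lengths do not match values shape")
        if not self.gene_ids.is_unique:
            raise ValueError("gene_ids must be unique")
        if not self.cell_ids.is_unique:
            raise ValueError("cell_ids must be unique")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(
                {"sample": "sample0", "malignant": True}, index=self.cell_ids
            )
        else:
            self.cell_meta = self.cell_meta.loc[self.cell_ids]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def malignant_mask(self) -> np.ndarray:
        if "malignant" in self.cell_meta:
            return self.cell_meta["malignant"].to_numpy(dtype=bool)
        return np.ones(self.n_cells, dtype=bool)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_ids.get_indexer(genes)
        if np.any(idx < 0):
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return replace(
            self,
            values=self.values[idx],
            gene_ids=pd.Index(genes),
            cell_meta=self.cell_meta,
        )

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = np.flatnonzero(mask)
        else:
            cols = mask
        return replace(
            self,
            values=self.values[:, cols],
            cell_ids=self.cell_ids[cols],
            cell_meta=self.cell_meta.iloc[cols],
        )

    def to_anndata(self):
        """Return an :class:`anndata.AnnData` view (cells x genes)."""
        import anndata as ad

        return ad.AnnData(
            X=self.values.T.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=self.gene_ids),
        )


@dataclass(frozen=True)
class Signature:
    """A named gene set, e.g. one of the malignant programmes or SYN/TM."""

    name: str
    genes: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(dict.fromkeys(self.genes)))
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.name!r} is empty")

    def intersect(self, gene_ids: pd.Index) -> tuple:
        present = tuple(g for g in self.genes if g in gene_ids)
        missing = len(self.genes) - len(present)
        if missing:
            warnings.warn(
                f"signature {self.name!r}: {missing} of {len(self.genes)} genes "
                "absent from the matrix",
                stacklevel=3,
            )
        return present


def transform_expression(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return the log-transformed view ``log2(TPM/10 + 1)`` of a TPM matrix.

    Refuses to re-transform an already log-scaled matrix.
    """
    if matrix.is_log:
        raise ValueError("matrix is already log-transformed")
    log_values = np.log2(matrix.values / 10.0 + 1.0)
    return replace(matrix, values=log_values, is_log=True)


def inverse_transform(log_values: np.ndarray) -> np.ndarray:
    """Invert the log transform: ``TPM = 10 * (2**x - 1)``."""
    return 10.0 * (np.exp2(np.asarray(log_values, dtype=float)) - 1.0)


def filter_analysable_genes(
    log_matrix: ExpressionMatrix,
    min_mean: float = 0.25,
    cells: np.ndarray | None = None,
) -> list:
    """Genes whose mean log2 expression is strictly greater than ``min_mean``.

    The mean is taken over the malignant cells (or over an explicit boolean
    ``cells`` mask), matching how the analysable-gene universe is defined.
    Order of ``gene_ids`` is preserved.
    """
    if not log_matrix.is_log:
        raise ValueError("filter_analysable_genes expects a log-transformed matrix")
    mask = log_matrix.malignant_mask() if cells is None else np.asarray(cells, bool)
    if mask.sum() == 0:
        raise ValueError("no cells selected for gene filtering")
    means = log_matrix.values[:, mask].mean(axis=1)
    return [g for g, m in zip(log_matrix.gene_ids, means) if m > min_mean]


def _bin_assignments(gene_means: np.ndarray, n_bins: int) -> list:
    """Partition gene indices into ``n_bins`` equal-frequency bins by mean."""
    order = np.argsort(gene_means, kind="stable")
    return [b for b in np.array_split(order, n_bins) if len(b)]


def _score_group(
    values: np.ndarray,
    gene_ids: pd.Index,
    signatures: Sequence[Signature],
    n_bins: int,
    rng: np.random.Generator | None,
    n_control: int,
) -> np.ndarray:
    """Score one cell group (one tumour sample); returns (n_sigs, n_cells)."""
    gene_means = values.mean(axis=1)
    centred = values - gene_means[:, None]
    bins = _bin_assignments(gene_means, n_bins)
    bin_of = np.empty(len(gene_ids), dtype=int)
    for b, members in enumerate(bins):
        bin_of[members] = b

    out = np.empty((len(signatures), values.shape[1]))
    for s, sig in enumerate(signatures):
        present = sig.intersect(gene_ids)
        if not present:
            raise ValueError(
                f"signature {sig.name!r} has no genes in the scored matrix"
            )
        sig_idx = gene_ids.get_indexer(present)
        sig_set = set(sig_idx.tolist())
        control_means = np.zeros((len(sig_idx), values.shape[1]))
        for j, gi in enumerate(sig_idx):
            members = bins[bin_of[gi]]
            others = members[members != gi]
            if len(others) == 0:
                warnings.warn(
                    f"bin of gene {gene_ids[gi]!r} has a single gene; "
                    "using the gene itself as its control",
                    stacklevel=4,
                )
                others = np.array([gi])
            if rng is not None and len(others) > n_control:
                others = rng.choice(others, size=n_control, replace=False)
            control_means[j] = centred[others].mean(axis=0)
        out[s] = centred[sig_idx].mean(axis=0) - control_means.mean(axis=0)
    return out


def score_signatures(
    log_matrix: ExpressionMatrix,
    signatures: Sequence[Signature],
    n_bins: int = 30,
    per_sample: bool = True,
    genes: Sequence[str] | None = None,
    sampled_controls: bool = False,
    n_control: int = 100,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Bin-matched-control signature scores for every cell.

    For each cell the score of a signature is the mean *relative* (gene-centred
    across cells) log2 expression of the signature genes minus the mean
    relative expression of expression-matched control genes.  Controls come
    from ``n_bins`` equal-frequency bins of genes ranked by mean log2
    expression: each signature gene contributes the other genes of its bin.
    By default the full bin is used (deterministic); ``sampled_controls`` draws
    ``n_control`` genes per bin with the given seed.

    When ``per_sample`` is True (the default), centring and binning are done
    within each tumour sample independently and the per-sample scores are
    concatenated; otherwise the whole cohort is scored at once.

    Returns a cells x signatures DataFrame (signature names as columns).
    """
    if not log_matrix.is_log:
        raise ValueError("score_signatures expects a log-transformed matrix")
    mat = log_matrix if genes is None else log_matrix.subset_genes(list(genes))
    rng = np.random.default_rng(seed) if sampled_controls else None

    names = [s.name for s in signatures]
    scores = pd.DataFrame(
        np.nan, index=mat.cell_ids, columns=names, dtype=float
    )
    if per_sample and "sample" in mat.cell_meta:
        groups = mat.cell_meta.groupby("sample", sort=True).indices
    else:
        groups = {"__all__": np.arange(mat.n_cells)}
    for _, cols in groups.items():
        cols = np.sort(np.asarray(cols))
        block = _score_group(
            mat.values[:, cols], mat.gene_ids, signatures, n_bins, rng, n_control
        )
        scores.iloc[cols] = block.T
    scores.index.name = "cell_id"
    return scores


def score_signature(
    log_matrix: ExpressionMatrix,
    signature: Signature,
    n_bins: int = 30,
    **kwargs,
) -> pd.Series:
    """Score a single signature; see :func:`score_signatures`."""
    return score_signatures(log_matrix, [signature], n_bins=n_bins, **kwargs)[
        signature.name
    ]


def assign_state(
    scores: pd.DataFrame,
    threshold: float = 0.5,
    state_names: Sequence[str] = STATE_NAMES,
) -> pd.Series:
    """Assign each cell the argmax state when its maximal score exceeds ``threshold``.

    Cells whose maximal state score is <= threshold, and exact ties at the
    maximum, are labelled "unresolved".  Missing scores raise.
    """
    missing = [s for s in state_names if s not in scores.columns]
    if missing:
        raise ValueError(f"missing state scores: {missing}")
    sub = scores[list(state_names)]
    if sub.isna().any().any():
        raise ValueError("state scores contain missing values")
    arr = sub.to_numpy(float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("state scores must be finite")
    top = arr.max(axis=1)
    argmax = arr.argmax(axis=1)
    tie = (arr == top[:, None]).sum(axis=1) > 1
    labels = np.array(list(state_names), object)[argmax]
    labels[(top <= threshold) | tie] = UNRESOLVED
    return pd.Series(labels, index=scores.index, name="state")


def hierarchy_coords(
    scores: pd.DataFrame, state_names: Sequence[str] = STATE_NAMES
) -> pd.DataFrame:
    """Two-axis hierarchy placement from the three state scores.

    ``stemness = OPC - max(AC, OC)`` (positive toward the progenitor-like
    apex) and ``lineage = AC - OC`` (positive toward the astrocytic branch).
    This two-axis summary is this package's documented stand-in for the
    hierarchy plot coordinates; see docs/methods.md.
    """
    ac, oc, opc = (scores[s].to_numpy(float) for s in state_names)
    return pd.DataFrame(
        {"lineage": ac - oc, "stemness": opc - np.maximum(ac, oc)},
        index=scores.index,
    )
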