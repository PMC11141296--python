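"""Cell-by-template scoring with six similarity/distance statistics.

Similarities (cosine, Pearson, Spearman) are computed on log-normalized
expression; distances (Euclidean, Manhattan, Chebyshev) on per-gene
z-scored expression, because raw expression and {-1, 0, +1} template
weights are not on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .templates import PipetError, TemplateMatrix

__all__ = [
    "CellMatrix",
    "ScoreTable",
    "METRICS",
    "SIMILARITY_METRICS",
    "DISTANCE_METRICS",
    "filter_genes",
    "lognormalize",
    "score",
]

SIMILARITY_METRICS = ("cosine", "pearson", "spearman")
DISTANCE_METRICS = ("euclidean", "manhattan", "chebyshev")
METRICS = SIMILARITY_METRICS + DISTANCE_METRICS

_CDIST_NAME = {"euclidean": "euclidean", "manhattan": "cityblock", "chebyshev": "chebyshev"}


@dataclass
class CellMatrix:
    """Single-cell expression matrix, genes in rows, cells in columns."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer_tag: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.cell_ids = [str(c).strip() for c in self.cell_ids]
        n, c = self.values.shape
        if len(self.gene_ids) != n:
            raise PipetError("gene_ids length does not match matrix rows")
        if len(self.cell_ids) != c:
            raise PipetError("cell_ids length does not match matrix columns")
        if len(set(self.gene_ids)) != n:
            raise PipetError("duplicate gene ids in cell matrix")
        if len(set(self.cell_ids)) != c:
            raise PipetError("duplicate cell ids in cell matrix")
        if self.layer_tag not in ("raw_counts", "lognorm"):
            raise PipetError(f"unknown layer tag {self.layer_tag!r}")
        if self.layer_tag == "raw_counts":
            if np.any(self.values < 0):
                raise PipetError("raw counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class ScoreTable:
    """Per-cell, per-class statistic with its polarity."""

    stat: np.ndarray  # (cells x classes)
    metric_name: str
    polarity: str  # "higher_is_closer" | "lower_is_closer"
    cell_ids: list[str]
    class_names: list[str]
    degenerate: np.ndarray = field(default=None)  # bool per cell

    def __post_init__(self) -> None:
        self.stat = np.asarray(self.stat, dtype=float)
        if self.stat.shape != (len(self.cell_ids), len(self.class_names)):
            raise PipetError("score table shape mismatch")
        if self.polarity not in ("higher_is_closer", "lower_is_closer"):
            raise PipetError(f"unknown polarity {self.polarity!r}")
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.cell_ids), dtype=bool)
        else:
            self.degenerate = np.asarray(self.degenerate, dtype=bool)


def filter_genes(cells: CellMatrix, min_cell_fraction: float = 0.0) -> CellMatrix:
    """Drop genes expressed (nonzero) in fewer than a fraction of cells.

    ``min_cell_fraction = 0`` keeps every gene (the include-all option).
    """
    if not 0 <= min_cell_fraction < 1:
        raise PipetError("min_cell_fraction must be in [0, 1)")
    if min_cell_fraction == 0:
        return cells
    frac = np.count_nonzero(cells.values, axis=1) / cells.n_cells
    keep = frac >= min_cell_fraction
    if not keep.any():
        raise PipetError("gene filtering removed every gene")
    return CellMatrix(
        values=cells.values[keep],
        gene_ids=[g for g, k in zip(cells.gene_ids, keep) if k],
        cell_ids=list(cells.cell_ids),
        layer_tag=cells.layer_tag,
    )


def lognormalize(cells: CellMatrix, scale_factor: float = 1e4) -> CellMatrix:
    """Library-size normalize and log-transform raw counts.

    value <- ln(1 + scale_factor * count / library_size), per cell.  Cells
    with zero library size stay all-zero.
    """
    if cells.layer_tag != "raw_counts":
        raise PipetError("lognormalize expects raw counts")
    if scale_factor <= 0:
        raise PipetError("scale_factor must be positive")
    lib = cells.values.sum(axis=0, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    vals = np.log1p(scale_factor * cells.values / lib)
    return CellMatrix(
        values=vals,
        gene_ids=list(cells.gene_ids),
        cell_ids=list(cells.cell_ids),
        layer_tag="lognorm",
    )


def _align(cells: CellMatrix, templates: TemplateMatrix) -> np.ndarray:
    """Row indices of the template genes inside the cell matrix (id join)."""
    pos = {g: i for i, g in enumerate(cells.gene_ids)}
    missing = [g for g in templates.gene_ids if g not in pos]
    if missing:
        raise PipetError(
            "template genes missing from cell matrix (intersect first): "
            + ", ".join(missing[:10])
        )
    return np.fromiter((pos[g] for g in templates.gene_ids), dtype=np.intp)


def zscore_genes(values: np.ndarray) -> np.ndarray:
    """Per-gene z-score across cells; constant genes map to zero."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def pairwise_stat(S: np.ndarray, W: np.ndarray, metric: str) -> tuple[np.ndarray, np.ndarray]:
    """Statistic between every cell column of ``S`` (genes x cells) and every
    template column of ``W`` (genes x classes).

    Returns ``(stat, degenerate)`` where ``stat`` is (cells x classes) and
    ``degenerate`` flags cells whose vector is constant over the template
    genes (their similarity entries are set to 0).  For distance metrics the
    caller must pass z-scored expression.
    """
    S = np.asarray(S, dtype=float)
    W = np.asarray(W, dtype=float)
    if metric in DISTANCE_METRICS:
        stat = cdist(S.T, W.T, metric=_CDIST_NAME[metric])
        return stat, np.zeros(S.shape[1], dtype=bool)
    if metric == "spearman":
        S = rankdata(S, axis=0)
        W = rankdata(W, axis=0)
        metric = "pearson"
    if metric == "pearson":
        S = S - S.mean(axis=0, keepdims=True)
        W = W - W.mean(axis=0, keepdims=True)
    elif metric != "cosine":
        raise PipetError(f"unknown metric {metric!r}; choose one of {METRICS}")
    s_norm = np.sqrt((S * S).sum(axis=0))
    w_norm = np.sqrt((W * W).sum(axis=0))
    degen = s_norm == 0
    s_norm = np.where(degen, 1.0, s_norm)
    if np.any(w_norm == 0):
        raise PipetError("template column has zero norm under this metric")
    stat = (S.T @ W) / np.outer(s_norm, w_norm)
    stat[degen] = 0.0
    np.clip(stat, -1.0, 1.0, out=stat)
    return stat, degen


def score(cells: CellMatrix, templates: TemplateMatrix, metric: str = "cosine") -> ScoreTable:
    """Score every cell against every class template.

    The cell vector is its expression restricted to the template genes,
    aligned by gene id.  Degenerate cells (constant over the template
    genes) receive similarity 0 and are flagged instead of producing NaN.
    """
    if metric not in METRICS:
        raise PipetError(f"unknown metric {metric!r}; choose one of {METRICS}")
    idx = _align(cells, templates)
    sub = cells.values[idx]
    if metric in DISTANCE_METRICS:
        stat, _ = pairwise_stat(zscore_genes(sub), templates.weights, metric)
        degen = np.all(sub == sub[:1, :], axis=0)
    else:
        stat, degen = pairwise_stat(sub, templates.weights, metric)
    polarity = "lower_is_closer" if metric in DISTANCE_METRICS else "higher_is_closer"
    return ScoreTable(
        stat=stat,
        metric_name=metric,
        polarity=polarity,
        cell_ids=list(cells.cell_ids),
        class_names=list(templates.class_names),
        degenerate=degen,
    )
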