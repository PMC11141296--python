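"""Permutation-based confidence and final per-cell class assignment.

The null distribution is built by re-applying the template weight vector
(in its original gene order) to randomly resampled gene subsets of the
filtered single-cell matrix; the same resampled index sets are shared by
all cells and classes so per-cell nulls stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .similarity import (
    DISTANCE_METRICS,
    METRICS,
    CellMatrix,
    ScoreTable,
    pairwise_stat,
    score,
    zscore_genes,
)
from .templates import PipetError, TemplateMatrix

__all__ = [
    "NullModel",
    "PredictionRecord",
    "permutation_null",
    "empirical_pvalues",
    "adjust_bh",
    "assign_labels",
    "predict",
]


@dataclass
class NullModel:
    """Permutation statistics, shape (nPerm, cells, classes)."""

    permuted_stats: np.ndarray
    metric_name: str
    polarity: str
    n_perm: int
    seed: int


@dataclass
class PredictionRecord:
    cell_id: str
    best_class: str
    best_stat: float
    p_value: float
    fdr: float
    label: str
    degenerate: bool = False
    tie: bool = False


def permutation_null(
    cells: CellMatrix,
    templates: TemplateMatrix,
    metric: str = "cosine",
    n_perm: int = 1000,
    seed: int = 0,
) -> NullModel:
    """Build the permutation null by resampling gene subsets.

    Each of the ``n_perm`` iterations draws ``m`` gene indices (m = total
    template genes) uniformly without replacement from the ``n`` filtered
    genes and scores every cell against every template on that subset.
    """
    if metric not in METRICS:
        raise PipetError(f"unknown metric {metric!r}")
    if n_perm < 1:
        raise PipetError("n_perm must be >= 1")
    m = templates.n_genes
    n = cells.n_genes
    if n < m:
        raise PipetError(
            f"filtered single-cell matrix has {n} genes, fewer than the "
            f"{m} template genes; cannot resample the null"
        )
    rng = np.random.default_rng(seed)
    vals = cells.values
    if metric in DISTANCE_METRICS:
        vals = zscore_genes(np.asarray(vals, dtype=float))
    c, k = cells.n_cells, len(templates.class_names)
    out = np.empty((n_perm, c, k), dtype=float)
    W = templates.weights
    for r in range(n_perm):
        idx = rng.choice(n, size=m, replace=False)
        out[r], _ = pairwise_stat(vals[idx], W, metric)
    polarity = "lower_is_closer" if metric in DISTANCE_METRICS else "higher_is_closer"
    return NullModel(
        permuted_stats=out, metric_name=metric, polarity=polarity,
        n_perm=n_perm, seed=seed,
    )


def empirical_pvalues(observed: ScoreTable, null: NullModel) -> np.ndarray:
    """One-sided empirical p-values with a +1 pseudo-count.

    p = (1 + #{permutation stats as or more extreme}) / (n_perm + 1);
    "more extreme" means >= for similarities and <= for distances.
    """
    if observed.polarity != null.polarity or observed.metric_name != null.metric_name:
        raise PipetError("observed scores and null model disagree on metric/polarity")
    obs = observed.stat[None, :, :]
    if null.polarity == "higher_is_closer":
        extreme = null.permuted_stats >= obs
    else:
        extreme = null.permuted_stats <= obs
    return (1.0 + extreme.sum(axis=0)) / (null.n_perm + 1.0)


def adjust_bh(p: np.ndarray, family: str = "joint") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    ``family="joint"`` adjusts all cell-by-class p-values as one family;
    ``family="per_class"`` adjusts each class column separately.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise PipetError("p-values must lie in (0, 1]")
    if family == "joint":
        flat = multipletests(p.ravel(), method="fdr_bh")[1]
        return flat.reshape(p.shape)
    if family == "per_class":
        if p.ndim != 2:
            raise PipetError("per_class family needs a 2-D p-value matrix")
        return np.column_stack(
            [multipletests(p[:, j], method="fdr_bh")[1] for j in range(p.shape[1])]
        )
    raise PipetError(f"unknown BH family {family!r}")


def assign_labels(
    observed: ScoreTable,
    p: np.ndarray,
    fdr: np.ndarray,
    alpha: float = 0.05,
    gate: str = "p",
) -> list[PredictionRecord]:
    """Pick each cell's nearest template and apply the significance gate.

    Best class is the argmax of similarities (argmin of distances), ties
    broken toward the first class in declared order.  The label is the
    best class only when the gated quantity (p or fdr) at (cell, best)
    is below ``alpha``; otherwise "Unassigned".  Degenerate cells are
    always "Unassigned" with p = 1.
    """
    if gate not in ("p", "fdr", "none"):
        raise PipetError(f"unknown gate {gate!r}")
    if not 0 < alpha < 1:
        raise PipetError("alpha must be in (0, 1)")
    p = np.asarray(p, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    if p.shape != observed.stat.shape or fdr.shape != observed.stat.shape:
        raise PipetError("p/fdr matrices do not match the score table")
    stat = observed.stat
    if observed.polarity == "higher_is_closer":
        best = stat.argmax(axis=1)
        best_stat = stat.max(axis=1)
    else:
        best = stat.argmin(axis=1)
        best_stat = stat.min(axis=1)
    ties = (stat == best_stat[:, None]).sum(axis=1) > 1
    records: list[PredictionRecord] = []
    for i, cell in enumerate(observed.cell_ids):
        j = int(best[i])
        cls = observed.class_names[j]
        degen = bool(observed.degenerate[i])
        pv, fv = float(p[i, j]), float(fdr[i, j])
        if degen:
            pv, fv = 1.0, 1.0
            label = "Unassigned"
        elif gate == "none":
            label = cls
        else:
            gated = pv if gate == "p" else fv
            label = cls if gated < alpha else "Unassigned"
        records.append(
            PredictionRecord(
                cell_id=cell, best_class=cls, best_stat=float(best_stat[i]),
                p_value=pv, fdr=fv, label=label,
                degenerate=degen, tie=bool(ties[i]),
            )
        )
    return records


def predict(
    cells: CellMatrix,
    templates: TemplateMatrix,
    metric: str = "cosine",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    gate: str = "p",
    bh_family: str = "joint",
) -> tuple[list[PredictionRecord], dict]:
    """End-to-end prediction: score, permutation null, p/FDR, assignment.

    ``templates`` need not be pre-intersected; the intersection with the
    cell matrix genes is taken here.  Returns the records and a run
    manifest.
    """
    from .templates import intersect_with_cells

    templates = intersect_with_cells(templates, cells.gene_ids)
    observed = score(cells, templates, metric)
    null = permutation_null(cells, templates, metric, n_perm=n_perm, seed=seed)
    p = empirical_pvalues(observed, null)
    fdr = adjust_bh(p, family=bh_family)
    records = assign_labels(observed, p, fdr, alpha=alpha, gate=gate)
    manifest = {
        "metric": metric,
        "n_perm": n_perm,
        "seed": seed,
        "alpha": alpha,
        "gate": gate,
        "bh_family": bh_family,
        "n_common_genes": templates.n_common,
        "n_filtered_genes": cells.n_genes,
        "n_cells": cells.n_cells,
        "n_classes": len(templates.class_names),
        "class_names": list(templates.class_names),
        "n_unassigned": sum(r.label == "Unassigned" for r in records),
    }
    return records, manifest
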