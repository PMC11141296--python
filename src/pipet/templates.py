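"""Marker selection from bulk data and template (feature-vector) construction.

A *template* is a per-class weight vector over marker genes.  For two
classes the weights are mirrored signs (+1 on the class's own markers,
-1 on the other class's markers); for three or more classes each column
is one-hot (+1 on the class's markers, 0 elsewhere).  Cells are later
scored against these columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BulkDataset",
    "MarkerSet",
    "TemplateMatrix",
    "select_markers",
    "build_templates",
    "intersect_with_cells",
]


class PipetError(ValueError):
    """Domain error raised for contract violations."""


@dataclass
class BulkDataset:
    """Bulk count matrix (genes x samples) with one phenotype label per sample."""

    counts: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    phenotype: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.phenotype = [str(p) for p in self.phenotype]
        n_genes, n_samples = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise PipetError("gene_ids length does not match count matrix rows")
        if len(self.sample_ids) != n_samples:
            raise PipetError("sample_ids length does not match count matrix columns")
        if len(self.phenotype) != n_samples:
            raise PipetError("phenotype must have one label per sample")
        if len(set(self.gene_ids)) != n_genes:
            raise PipetError("duplicate gene ids in bulk data")
        if len(set(self.sample_ids)) != n_samples:
            raise PipetError("duplicate sample ids in bulk data")
        if np.any(self.counts < 0):
            raise PipetError("bulk counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise PipetError("bulk counts must be integers")
        classes = self.classes
        if len(classes) < 2:
            raise PipetError("bulk data needs at least 2 phenotype classes")
        for cls in classes:
            if self.phenotype.count(cls) < 2:
                raise PipetError(f"class {cls!r} has fewer than 2 samples")

    @property
    def classes(self) -> list[str]:
        """Class names in first-appearance order."""
        return list(dict.fromkeys(self.phenotype))

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass
class MarkerSet:
    """Per-class ordered marker gene lists with effect sizes.

    ``genes[c]`` is ordered by descending log2 fold change; ``log2fc`` and
    ``fdr`` are aligned to it.
    """

    class_names: list[str]
    genes: dict[str, list[str]]
    log2fc: dict[str, np.ndarray] = field(default_factory=dict)
    fdr: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.class_names) < 2:
            raise PipetError("marker set needs at least 2 classes")
        seen: dict[str, str] = {}
        for cls in self.class_names:
            glist = self.genes.get(cls, [])
            if len(glist) < 1:
                raise PipetError(f"class {cls!r} has no marker genes")
            if len(set(glist)) != len(glist):
                raise PipetError(f"duplicate marker genes within class {cls!r}")
            for g in glist:
                if g in seen:
                    raise PipetError(
                        f"gene {g!r} is a marker for both {seen[g]!r} and {cls!r}"
                    )
                seen[g] = cls

    @property
    def sizes(self) -> dict[str, int]:
        return {c: len(self.genes[c]) for c in self.class_names}

    @property
    def total(self) -> int:
        return sum(self.sizes.values())


@dataclass
class TemplateMatrix:
    """Weight matrix (marker genes x classes) with entries in {-1, 0, +1}."""

    gene_ids: list[str]
    weights: np.ndarray
    class_names: list[str]
    scheme: str
    n_common: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.int8)
        if self.weights.shape != (len(self.gene_ids), len(self.class_names)):
            raise PipetError("template weights shape mismatch")
        if self.scheme not in ("binary", "multiclass"):
            raise PipetError(f"unknown template scheme {self.scheme!r}")
        allowed = {-1, 0, 1} if self.scheme == "binary" else {0, 1}
        if not set(np.unique(self.weights)).issubset(allowed):
            raise PipetError("template weights out of range for scheme")
        for j, cls in enumerate(self.class_names):
            if not np.any(self.weights[:, j]):
                raise PipetError(f"template column for class {cls!r} is all zero")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def _log2_cpm(counts: np.ndarray) -> np.ndarray:
    lib = counts.sum(axis=0, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    return np.log2(1.0 + 1e6 * counts / lib)


def select_markers(
    bulk: BulkDataset,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> MarkerSet:
    """Select per-class up-regulated marker genes from bulk counts.

    Stand-in differential-expression test: per gene, a two-sided Welch
    t-test on log2(CPM+1) of the class versus all other samples
    (one-vs-rest), Benjamini-Hochberg adjusted per class.  The log2 fold
    change is the difference of group means of log2(CPM+1).  Genes passing
    ``fdr < fdr_threshold`` and ``log2fc > lfc_threshold`` become markers
    of that class, ordered by descending log2fc.  A gene qualifying for
    several classes is kept only for the class with the largest |log2fc|.
    """
    if not 0 < fdr_threshold < 1:
        raise PipetError("fdr_threshold must be in (0, 1)")
    if lfc_threshold < 0:
        raise PipetError("lfc_threshold must be non-negative")

    expr = _log2_cpm(bulk.counts)
    pheno = np.asarray(bulk.phenotype)
    classes = bulk.classes

    per_class: dict[str, pd.DataFrame] = {}
    for cls in classes:
        in_cls = pheno == cls
        a, b = expr[:, in_cls], expr[:, ~in_cls]
        lfc = a.mean(axis=1) - b.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
        # zero variance in both groups: perfectly separated if means differ
        zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
        pvals = np.where(zero_var, np.where(lfc != 0, 0.0, 1.0), pvals)
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)
        fdr = multipletests(pvals, method="fdr_bh")[1]
        keep = (fdr < fdr_threshold) & (lfc > lfc_threshold)
        df = pd.DataFrame(
            {"gene": np.asarray(bulk.gene_ids)[keep], "log2fc": lfc[keep], "fdr": fdr[keep]}
        ).sort_values("log2fc", ascending=False, kind="stable")
        per_class[cls] = df

    # resolve cross-class duplicates: keep the class with the largest |log2fc|
    best: dict[str, tuple[str, float]] = {}
    for cls in classes:
        for gene, lfc in zip(per_class[cls]["gene"], per_class[cls]["log2fc"]):
            if gene not in best or abs(lfc) > abs(best[gene][1]):
                best[gene] = (cls, lfc)
    dups = [
        g for cls in classes for g in per_class[cls]["gene"] if best[g][0] != cls
    ]
    if dups:
        warnings.warn(
            f"{len(dups)} marker gene(s) shared across classes were assigned "
            "to the class with the largest |log2fc|: "
            + ", ".join(sorted(set(dups))[:10]),
            stacklevel=2,
        )
        for cls in classes:
            df = per_class[cls]
            per_class[cls] = df[[best[g][0] == cls for g in df["gene"]]]

    genes, lfcs, fdrs = {}, {}, {}
    for cls in classes:
        df = per_class[cls]
        if df.empty:
            raise PipetError(
                f"no marker genes found for class {cls!r} at "
                f"fdr<{fdr_threshold}, log2fc>{lfc_threshold}"
            )
        genes[cls] = df["gene"].tolist()
        lfcs[cls] = df["log2fc"].to_numpy()
        fdrs[cls] = df["fdr"].to_numpy()
    return MarkerSet(class_names=classes, genes=genes, log2fc=lfcs, fdr=fdrs)


def build_templates(markers: MarkerSet) -> TemplateMatrix:
    """Build the class template matrix from a marker set.

    Two classes: +1 on own markers, -1 on the other class's markers (the
    second column is the elementwise negation of the first).  More than
    two classes: one-hot columns (+1 on own markers, 0 elsewhere).
    """
    classes = markers.class_names
    gene_ids = [g for cls in classes for g in markers.genes[cls]]
    if len(set(gene_ids)) != len(gene_ids):
        raise PipetError("duplicate gene across classes in marker set")
    k = len(classes)
    weights = np.zeros((len(gene_ids), k), dtype=np.int8)
    offset = 0
    for j, cls in enumerate(classes):
        m = len(markers.genes[cls])
        weights[offset : offset + m, j] = 1
        offset += m
    if k == 2:
        weights = np.where(weights == 1, 1, -1).astype(np.int8)
        scheme = "binary"
    else:
        scheme = "multiclass"
    return TemplateMatrix(
        gene_ids=gene_ids, weights=weights, class_names=classes, scheme=scheme
    )


def intersect_with_cells(
    templates: TemplateMatrix, sc_gene_ids: list[str]
) -> TemplateMatrix:
    """Restrict templates to genes present in the single-cell matrix.

    Records the number of common genes N; raises if no gene survives or if
    any class column becomes all zero.
    """
    if not sc_gene_ids:
        raise PipetError("single-cell gene list is empty")
    sc_set = {str(g).strip() for g in sc_gene_ids}
    keep = [i for i, g in enumerate(templates.gene_ids) if g in sc_set]
    if not keep:
        raise PipetError("no common genes between templates and single-cell data")
    gene_ids = [templates.gene_ids[i] for i in keep]
    weights = templates.weights[keep]
    for j, cls in enumerate(templates.class_names):
        if not np.any(weights[:, j]):
            raise PipetError(
                f"class {cls!r} lost all of its marker genes in the intersection"
            )
    return TemplateMatrix(
        gene_ids=gene_ids,
        weights=weights,
        class_names=list(templates.class_names),
        scheme=templates.scheme,
        n_common=len(gene_ids),
    )
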