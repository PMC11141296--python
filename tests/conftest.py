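import numpy as np
import pytest

from pipet.similarity import CellMatrix
from pipet.templates import BulkDataset, MarkerSet, TemplateMatrix, build_templates


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_bulk(counts, gene_ids=None, phenotype=None):
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    if phenotype is None:
        half = n_samples // 2
        phenotype = ["A"] * half + ["B"] * (n_samples - half)
    return BulkDataset(
        counts=counts,
        gene_ids=gene_ids,
        sample_ids=[f"s{i + 1}" for i in range(n_samples)],
        phenotype=phenotype,
    )


@pytest.fixture
def binary_templates():
    """F_A = (+1, +1, -1), F_B = (-1, -1, +1) over (g1, g2, g3)."""
    markers = MarkerSet(class_names=["A", "B"], genes={"A": ["g1", "g2"], "B": ["g3"]})
    return build_templates(markers)


@pytest.fixture
def multiclass_templates():
    markers = MarkerSet(
        class_names=["A", "B", "C"], genes={"A": ["g1"], "B": ["g2"], "C": ["g3"]}
    )
    return build_templates(markers)


def make_cells(values, gene_ids=None, cell_ids=None, layer_tag="lognorm"):
    values = np.asarray(values, dtype=float)
    n, c = values.shape
    return CellMatrix(
        values=values,
        gene_ids=gene_ids or [f"g{i + 1}" for i in range(n)],
        cell_ids=cell_ids or [f"c{i + 1}" for i in range(c)],
        layer_tag=layer_tag,
    )
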