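"""Readers and writers for matrices, marker lists, predictions and manifests.

Single-cell input is either a 10x-style MTX triplet directory
(matrix.mtx + genes/features + barcodes, genes x cells) or a dense
TSV/CSV with genes in rows.  All outputs are plain text.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .inference import PredictionRecord
from .similarity import CellMatrix, ScoreTable
from .templates import BulkDataset, MarkerSet, PipetError

__all__ = [
    "RunConfig",
    "read_run_config",
    "read_sc_matrix",
    "write_sc_matrix",
    "read_bulk",
    "read_markers",
    "write_markers",
    "write_predictions",
    "read_predictions",
    "write_manifest",
    "read_labels",
]


@dataclasses.dataclass
class RunConfig:
    """Prediction run settings; mirrors the CLI flags of ``pipet predict``."""

    sc: str | None = None
    templates: str | None = None
    bulk: str | None = None
    phenotype: str | None = None
    metric: str = "cosine"
    nperm: int = 1000
    alpha: float = 0.05
    gate: str = "p"
    fdr: float = 0.05
    lfc: float = 1.0
    min_cell_fraction: float = 0.0
    seed: int = 0
    out: str | None = None

    def __post_init__(self) -> None:
        has_markers = self.templates is not None
        has_bulk = self.bulk is not None and self.phenotype is not None
        if has_markers == has_bulk:
            raise PipetError(
                "provide exactly one of templates or (bulk and phenotype)"
            )


def read_run_config(path: str | Path) -> dict:
    """Read a JSON config file; unknown keys are rejected."""
    payload = json.loads(Path(path).read_text())
    if not isinstance(payload, dict):
        raise PipetError("config file must hold a JSON object")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(payload) - known)
    if unknown:
        raise PipetError(f"unknown config keys: {', '.join(unknown)}")
    return payload


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_id_file(path: Path) -> list[str]:
    """First column of a headerless TSV (10x genes/features/barcodes style)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].str.strip().tolist()


def read_sc_matrix(path: str | Path, cells_in_rows: bool = False) -> CellMatrix:
    """Read a single-cell matrix from an MTX triplet directory or dense table.

    Orientation is auto-detected for MTX (matrix dims vs id-file lengths);
    for dense tables genes are assumed in rows unless ``cells_in_rows``.
    """
    path = Path(path)
    if path.is_dir():
        mtx_path = next((p for p in (path / "matrix.mtx", path / "matrix.mtx.gz") if p.exists()), None)
        if mtx_path is None:
            raise PipetError(f"no matrix.mtx found in {path}")
        genes_path = next(
            (p for n in ("genes.tsv", "features.tsv") if (p := path / n).exists()), None
        )
        barcodes_path = path / "barcodes.tsv"
        if genes_path is None or not barcodes_path.exists():
            raise PipetError(f"missing genes/features or barcodes file in {path}")
        mat = spio.mmread(mtx_path)
        genes = _read_id_file(genes_path)
        barcodes = _read_id_file(barcodes_path)
        if mat.shape == (len(genes), len(barcodes)):
            pass
        elif mat.shape == (len(barcodes), len(genes)):
            mat = mat.T
        else:
            raise PipetError(
                f"matrix dims {mat.shape} match neither (genes={len(genes)}, "
                f"cells={len(barcodes)}) nor its transpose"
            )
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        return CellMatrix(values=values, gene_ids=genes, cell_ids=barcodes)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if cells_in_rows:
        df = df.T
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise PipetError(f"duplicate ids in {path}: {dup[:10]}")
    return CellMatrix(
        values=df.to_numpy(),
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
    )


def write_sc_matrix(cells: CellMatrix, outdir: str | Path) -> None:
    """Write an MTX triplet (matrix.mtx, genes.tsv, barcodes.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(cells.values)
    spio.mmwrite(outdir / "matrix.mtx", mat)
    pd.Series(cells.gene_ids).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(cells.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)


def read_bulk(path: str | Path, phenotype_path: str | Path) -> BulkDataset:
    """Read a bulk count table (genes x samples) and join phenotype labels.

    Samples missing from the label file are dropped with a warning; labels
    referencing unknown samples raise.
    """
    path, phenotype_path = Path(path), Path(phenotype_path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    labels = pd.read_csv(phenotype_path, sep=_sep(phenotype_path), header=None, dtype=str)
    if labels.shape[1] < 2:
        raise PipetError("phenotype file must have two columns: sample_id, class")
    if labels.iloc[0, 0].strip().lower() in ("sample", "sample_id", "id"):
        labels = labels.iloc[1:]
    label_map = dict(zip(labels.iloc[:, 0].str.strip(), labels.iloc[:, 1].str.strip()))
    samples = [str(s) for s in df.columns]
    unknown = sorted(set(label_map) - set(samples))
    if unknown:
        raise PipetError(f"phenotype file references unknown samples: {unknown[:10]}")
    unlabeled = [s for s in samples if s not in label_map]
    if unlabeled:
        warnings.warn(f"dropping {len(unlabeled)} unlabeled sample(s): {unlabeled[:10]}")
        df = df.drop(columns=unlabeled)
        samples = [str(s) for s in df.columns]
    return BulkDataset(
        counts=df.to_numpy(),
        gene_ids=[str(g) for g in df.index],
        sample_ids=samples,
        phenotype=[label_map[s] for s in samples],
    )


def read_markers(path: str | Path) -> MarkerSet:
    """Read per-class marker lists.

    Accepts a TSV/CSV with columns (class, gene_id[, log2fc[, fdr]]) with
    or without a header, or a GMT file (class, description, genes...).
    """
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        genes: dict[str, list[str]] = {}
        for line in path.read_text().splitlines():
            parts = [p.strip() for p in line.split("\t") if p.strip()]
            if len(parts) >= 3:
                genes[parts[0]] = parts[2:]
            elif len(parts) == 2:
                genes[parts[0]] = parts[1:]
        if not genes:
            raise PipetError(f"no gene sets parsed from {path}")
        return MarkerSet(class_names=list(genes), genes=genes)
    df = pd.read_csv(path, sep=_sep(path), header=None, dtype=str)
    if df.iloc[0, 0].strip().lower() in ("class", "class_name", "phenotype"):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 2:
        raise PipetError("marker file must have at least (class, gene_id) columns")
    class_names = list(dict.fromkeys(df.iloc[:, 0].str.strip()))
    genes = {c: [] for c in class_names}
    lfc = {c: [] for c in class_names}
    fdr = {c: [] for c in class_names}
    for _, row in df.iterrows():
        cls = row.iloc[0].strip()
        genes[cls].append(row.iloc[1].strip())
        if df.shape[1] > 2 and pd.notna(row.iloc[2]):
            lfc[cls].append(float(row.iloc[2]))
        if df.shape[1] > 3 and pd.notna(row.iloc[3]):
            fdr[cls].append(float(row.iloc[3]))
    return MarkerSet(
        class_names=class_names,
        genes=genes,
        log2fc={c: np.asarray(v) for c, v in lfc.items() if v},
        fdr={c: np.asarray(v) for c, v in fdr.items() if v},
    )


def write_markers(markers: MarkerSet, path: str | Path) -> None:
    rows = []
    for cls in markers.class_names:
        lfc = markers.log2fc.get(cls)
        fdr = markers.fdr.get(cls)
        for i, g in enumerate(markers.genes[cls]):
            rows.append(
                {
                    "class": cls,
                    "gene_id": g,
                    "log2fc": "" if lfc is None else f"{lfc[i]:.6g}",
                    "fdr": "" if fdr is None else f"{fdr[i]:.6g}",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_predictions(
    records: list[PredictionRecord],
    path: str | Path,
    scores: ScoreTable | None = None,
) -> None:
    """Write prediction records as TSV, optionally with per-class statistics."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if df.empty:
        df = pd.DataFrame(
            columns=["cell_id", "best_class", "best_stat", "p_value", "fdr",
                     "label", "degenerate", "tie"]
        )
    if scores is not None and len(records):
        order = {c: i for i, c in enumerate(scores.cell_ids)}
        idx = [order[r.cell_id] for r in records]
        for j, cls in enumerate(scores.class_names):
            df[f"stat_{cls}"] = scores.stat[idx, j]
    df.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def read_labels(path: str | Path, id_col: str = "cell_id", label_col: str = "label"):
    """Read a two-column (id, label) table, with or without a header."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    if id_col in df.columns and label_col in df.columns:
        return df[id_col].str.strip().tolist(), df[label_col].str.strip().tolist()
    df = pd.read_csv(path, sep=_sep(path), header=None, dtype=str)
    return (
        df.iloc[:, 0].str.strip().tolist(),
        df.iloc[:, 1].str.strip().tolist(),
    )
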