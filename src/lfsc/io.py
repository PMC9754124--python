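"""Readers and writers for expression matrices, bulk panels and labels.

Two on-disk dialects are supported: MatrixMarket coordinate files with
``genes.tsv`` / ``barcodes.tsv`` sidecars (the CellRanger-style layout), and
dense TSV/CSV with genes in rows and a header row of cell/sample ids. Bulk
panels carry their per-sample cell-type labels in a ``*.labels.tsv`` sidecar
(sample_id <tab> cell_type).

MatrixMarket indices are 1-based on disk (the format standard) and converted
to 0-based storage on read; writing converts back.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import AnnotationResult, BulkPanel, ClusterResult, ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_bulk",
    "write_bulk",
    "read_labels",
    "write_labels",
    "write_results",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


def _infer_fmt(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("mtx", "tsv"):
            raise FormatError(f"unknown format {fmt!r}; expected 'mtx' or 'tsv'")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix in (".tsv", ".csv", ".txt"):
        return "tsv"
    raise FormatError(f"cannot infer format from suffix {suffix!r}; pass fmt")


def _read_sidecar_ids(path: Path) -> list[str]:
    with open(path) as fh:
        # sidecars may carry extra columns (e.g. gene symbol); first wins
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _sep_for(path: str | Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def _read_dense_table(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.name is None and df.columns.size == 0:
        raise FormatError(f"malformed header in {path}")
    if df.index.hasnans or any(not isinstance(g, str) for g in df.index):
        raise FormatError(f"gene id absent from header in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression entry in {path}: {exc}") from exc
    return values, [str(g) for g in df.index], [str(c) for c in df.columns]


def read_expression(path: str | Path, fmt: str | None = None) -> ExpressionMatrix:
    """Read a raw genes x cells expression matrix.

    Parameters
    ----------
    path
        ``.mtx`` file (with ``genes.tsv`` and ``barcodes.tsv`` alongside) or a
        dense TSV/CSV with gene ids in the first column and cell ids in the
        header.
    fmt
        ``"mtx"`` or ``"tsv"``; inferred from the suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_fmt(path, fmt)
    if fmt == "mtx":
        genes_path = path.parent / "genes.tsv"
        barcodes_path = path.parent / "barcodes.tsv"
        for side in (genes_path, barcodes_path):
            if not side.exists():
                raise FileNotFoundError(f"missing sidecar {side}")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # scipy raises bare ValueError on bad headers
            raise FormatError(f"malformed MatrixMarket header in {path}: {exc}") from exc
        values = np.asarray(
            mat.toarray() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        gene_ids = _read_sidecar_ids(genes_path)
        cell_ids = _read_sidecar_ids(barcodes_path)
        if values.shape != (len(gene_ids), len(cell_ids)):
            raise FormatError(
                f"matrix shape {values.shape} does not match sidecars "
                f"({len(gene_ids)} genes, {len(cell_ids)} barcodes)"
            )
    else:
        values, gene_ids, cell_ids = _read_dense_table(path)
    if np.any(values < 0):
        raise FormatError("negative expression value")
    if len(set(gene_ids)) != len(gene_ids):
        raise FormatError("duplicate gene ids")
    return ExpressionMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids, layer="raw")


def write_expression(x: ExpressionMatrix, path: str | Path, fmt: str | None = None) -> None:
    """Write an expression matrix in either supported dialect."""
    path = Path(path)
    fmt = _infer_fmt(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(x.values))
        (path.parent / "genes.tsv").write_text("".join(f"{g}\n" for g in x.gene_ids))
        (path.parent / "barcodes.tsv").write_text("".join(f"{c}\n" for c in x.cell_ids))
    else:
        df = pd.DataFrame(x.values, index=x.gene_ids, columns=x.cell_ids)
        df.index.name = "gene"
        df.to_csv(path, sep=_sep_for(path))


def _labels_sidecar(path: Path) -> Path:
    return path.with_suffix(".labels.tsv")


def read_bulk(
    path: str | Path, fmt: str | None = None, labels_path: str | Path | None = None
) -> BulkPanel:
    """Read a bulk panel (genes x samples TSV/CSV) plus its label sidecar.

    Labels live in ``<stem>.labels.tsv`` next to the panel unless
    ``labels_path`` points elsewhere; every sample in the panel header must
    appear there. Labels need not be unique across samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_fmt(path, fmt)
    if fmt != "tsv":
        raise FormatError("bulk panels are dense tables; use tsv/csv")
    values, gene_ids, sample_ids = _read_dense_table(path)
    if np.any(values < 0):
        raise FormatError("negative expression value")
    if len(set(gene_ids)) != len(gene_ids):
        raise FormatError("duplicate gene ids")
    lab_path = Path(labels_path) if labels_path is not None else _labels_sidecar(path)
    if not lab_path.exists():
        raise FileNotFoundError(f"missing label sidecar {lab_path}")
    lab_df = pd.read_csv(lab_path, sep="\t", header=None, names=["sample", "cell_type"], dtype=str)
    label_map = dict(zip(lab_df["sample"], lab_df["cell_type"]))
    missing = [s for s in sample_ids if s not in label_map]
    if missing:
        raise FormatError(f"missing label for sample(s): {', '.join(missing)}")
    labels = [label_map[s] for s in sample_ids]
    return BulkPanel(values=values, gene_ids=gene_ids, sample_ids=sample_ids, cell_type_labels=labels)


def write_bulk(r: BulkPanel, path: str | Path) -> None:
    """Write a bulk panel as TSV/CSV plus its label sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(r.values, index=r.gene_ids, columns=r.sample_ids)
    df.index.name = "gene"
    df.to_csv(path, sep=_sep_for(path))
    with open(_labels_sidecar(path), "w") as fh:
        for s, lab in zip(r.sample_ids, r.cell_type_labels):
            fh.write(f"{s}\t{lab}\n")


def read_labels(path: str | Path) -> list[str]:
    """Read per-cell labels: one label per line, or cell_id <tab> label."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            out.append(parts[-1])
    return out


def write_labels(labels: list[str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(f"{lab}\n" for lab in labels))


def write_results(
    clusters: ClusterResult,
    annotation: AnnotationResult | None,
    cell_ids: list[str],
    path: str | Path,
) -> None:
    """Write the per-cell output table: cell_id, cluster, cell_type.

    Rows follow the input cell order, so re-running on identical inputs gives
    a byte-identical file. ``annotation`` may be ``None`` (unannotated run);
    the cell_type column then holds "NA".
    """
    if clusters.n_cells != len(cell_ids):
        raise ValueError(
            f"{clusters.n_cells} cluster labels for {len(cell_ids)} cells"
        )
    if annotation is not None and len(annotation.cell_types) != len(cell_ids):
        raise ValueError("annotation length does not match cell count")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("cell_id\tcluster\tcell_type\n")
        for i, cid in enumerate(cell_ids):
            ct = annotation.cell_types[i] if annotation is not None else "NA"
            fh.write(f"{cid}\t{clusters.labels[i]}\t{ct}\n")
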