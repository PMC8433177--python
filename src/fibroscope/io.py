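"""Readers and writers for the pipeline's tabular and sparse formats.

Conventions: bulk expression is stored genes-as-rows in TSV; sparse matrices
go to MatrixMarket MTX with plain-text row/column name sidecars
(``<path>.rownames.txt`` / ``<path>.colnames.txt``); single-cell references
are cells x genes MTX plus a cell annotation TSV. Floating output is written
at 6 significant digits for cross-platform diffability, and every table is
re-readable by the module's own readers.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_tiles",
    "write_tiles",
    "read_reference",
    "write_reference",
    "write_table",
]

FLOAT_FMT = "%.6g"


def _sidecars(path: Path) -> tuple[Path, Path]:
    return Path(f"{path}.rownames.txt"), Path(f"{path}.colnames.txt")


def _read_names(path: Path) -> list[str]:
    return [line.rstrip("\n") for line in path.read_text().splitlines() if line != ""]


def read_expression(
    path: str | Path,
    fmt: str | None = None,
    orientation: str = "genes_by_samples",
) -> pd.DataFrame:
    """Read an expression matrix as genes x samples.

    ``fmt`` is inferred from the suffix (``.mtx`` vs delimited text) when not
    given. ``orientation`` declares how the stored matrix is laid out
    (``genes_by_samples`` or ``samples_by_genes``); the returned frame is
    always genes x samples. Duplicate identifiers are rejected.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    elif fmt == "mtx":
        rows_f, cols_f = _sidecars(path)
        for f in (rows_f, cols_f):
            if not f.exists():
                raise FileNotFoundError(f"missing MTX name sidecar: {f}")
        mat = spio.mmread(path)
        rows, cols = _read_names(rows_f), _read_names(cols_f)
        if mat.shape != (len(rows), len(cols)):
            raise ValueError(
                f"sidecar lengths ({len(rows)}, {len(cols)}) do not match "
                f"matrix shape {mat.shape} for {path}"
            )
        dense = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        df = pd.DataFrame(dense, index=rows, columns=cols)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if orientation == "samples_by_genes":
        df = df.T
    elif orientation != "genes_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    for axis, name in ((df.index, "gene"), (df.columns, "sample")):
        if axis.duplicated().any():
            dups = list(axis[axis.duplicated()][:5])
            raise ValueError(f"duplicate {name} identifiers: {dups}")
    return df


def write_expression(df: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    """Write a genes x samples matrix as TSV or MTX (+ name sidecars)."""
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")
    elif fmt == "mtx":
        spio.mmwrite(path, sparse.csr_matrix(df.to_numpy()))
        rows_f, cols_f = _sidecars(path)
        rows_f.write_text("\n".join(map(str, df.index)) + "\n")
        cols_f.write_text("\n".join(map(str, df.columns)) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    from .syndata import STAGES

    meta = pd.read_csv(path, sep="\t", index_col=0)
    if "stage" in meta:
        meta["stage"] = pd.Categorical(meta["stage"], categories=list(STAGES), ordered=True)
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="sample_id")


def read_tiles(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tiles(tiles: pd.DataFrame, path: str | Path) -> None:
    tiles.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)


def read_reference(mtx_path: str | Path, annotation_path: str | Path) -> ad.AnnData:
    """Single-cell reference: cells x genes MTX + cell annotation TSV.

    The annotation table needs columns ``cell_type`` and ``subject`` and one
    row per cell, aligned with the MTX rows; gene names come from the column
    sidecar.
    """
    mtx_path = Path(mtx_path)
    X = spio.mmread(mtx_path).tocsr()
    rows_f, cols_f = _sidecars(mtx_path)
    cells = _read_names(rows_f) if rows_f.exists() else [f"cell{i}" for i in range(X.shape[0])]
    if not cols_f.exists():
        raise FileNotFoundError(f"missing gene-name sidecar: {cols_f}")
    genes = _read_names(cols_f)
    if X.shape != (len(cells), len(genes)):
        raise ValueError(
            f"sidecar lengths ({len(cells)}, {len(genes)}) do not match matrix shape {X.shape}"
        )
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    for col in ("cell_type", "subject"):
        if col not in ann.columns:
            raise ValueError(f"annotation table lacks column {col!r}")
    ann = ann.reindex(cells)
    if ann["cell_type"].isna().any():
        raise ValueError("annotation table does not cover every cell in the matrix")
    adata = ad.AnnData(X=X, obs=ann, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.uns["cell_types"] = sorted(ann["cell_type"].unique())
    return adata


def write_reference(reference: ad.AnnData, mtx_path: str | Path, annotation_path: str | Path) -> None:
    mtx_path = Path(mtx_path)
    X = reference.X if sparse.issparse(reference.X) else sparse.csr_matrix(reference.X)
    spio.mmwrite(mtx_path, X)
    rows_f, cols_f = _sidecars(mtx_path)
    rows_f.write_text("\n".join(map(str, reference.obs_names)) + "\n")
    cols_f.write_text("\n".join(map(str, reference.var_names)) + "\n")
    reference.obs.to_csv(annotation_path, sep="\t", index_label="cell_id")
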