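"""Readers and writers for count matrices (TSV/CSV/GCT 1.2) and labels."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CountMatrix

__all__ = ["read_counts", "read_labels", "write_counts"]


def _check_unique(values, what: str) -> None:
    seen, dups = set(), []
    for v in values:
        if v in seen:
            dups.append(v)
        seen.add(v)
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(map(str, dups)))}")


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != "#1.2":
            raise ValueError(f"{path}:1: expected GCT header '#1.2', found {header!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValueError(f"{path}:2: expected '<n_genes> <n_samples>' dims line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t")
    if list(df.columns[:2]) != ["Name", "Description"]:
        raise ValueError(f"{path}:3: expected 'Name' and 'Description' columns")
    found_genes, found_samples = df.shape[0], df.shape[1] - 2
    if (found_genes, found_samples) != (n_genes, n_samples):
        raise ValueError(
            f"{path}:2: dims line says {n_genes} x {n_samples}, "
            f"found {found_genes} x {found_samples}"
        )
    return df.drop(columns=["Description"]).set_index("Name")


def read_counts(
    path: str | Path,
    fmt: str | None = None,
    labels: np.ndarray | None = None,
    gene_lengths: np.ndarray | None = None,
) -> CountMatrix:
    """Load a gene x sample count matrix (genes as rows, first column = id).

    ``fmt`` is one of tsv/csv/gct; when None it is inferred from the file
    suffix.  Labels default to a single placeholder class and gene lengths
    to 1000 bp when not supplied (both are required for downstream TPM and
    DE work, but a bare matrix is still loadable).
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "tsv"
    if fmt == "gct":
        df = _read_gct(path)
    elif fmt in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected tsv, csv or gct")
    _check_unique(df.index.tolist(), "gene ids")
    _check_unique(df.columns.tolist(), "sample ids")
    counts = df.to_numpy()
    if labels is None:
        labels = np.array(["unlabeled"] * df.shape[1], dtype=object)
    if gene_lengths is None:
        gene_lengths = np.full(df.shape[0], 1000, dtype=int)
    return CountMatrix(
        counts=counts,
        gene_ids=np.array(df.index, dtype=object),
        sample_ids=np.array(df.columns, dtype=object),
        gene_lengths=np.asarray(gene_lengths),
        labels=np.asarray(labels, dtype=object),
    )


def read_labels(path: str | Path) -> pd.DataFrame:
    """Two-column TSV: sample_id, class."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["sample_id", "class"]:
        raise ValueError("labels file must have columns: sample_id, class")
    _check_unique(df["sample_id"].tolist(), "sample ids")
    return df


def write_counts(cm: CountMatrix, path: str | Path, fmt: str = "tsv") -> None:
    if fmt == "gct":
        cm.write_gct(path)
    elif fmt == "tsv":
        cm.write_tsv(path)
    elif fmt == "csv":
        df = pd.DataFrame(cm.counts, index=pd.Index(cm.gene_ids, name="gene_id"),
                          columns=list(cm.sample_ids))
        df.to_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
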