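"""Reading and writing count matrices, metadata and tabular results.

Counts travel either as a tab-separated gene × sample table (first column =
gene id, header row = sample ids) or as 1-based MatrixMarket coordinate format
with plain-text one-id-per-line ``.rows`` / ``.cols`` sidecars, genes as rows.
All outputs are TSV, written deterministically so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import CountMatrix, SampleTable, ValidationError

logger = logging.getLogger("canalex")

PathLike = Union[str, Path]


def read_counts(path: PathLike, format: str | None = None) -> CountMatrix:
    """Load a count matrix from TSV or MatrixMarket (+sidecars).

    The format is inferred from the suffix (.mtx → MatrixMarket) unless given
    explicitly.  Cells must be non-negative integers; a violating cell is
    reported with its gene row and sample column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        return _read_counts_tsv(path)
    if fmt == "mtx":
        return _read_counts_mtx(path)
    raise ValueError(f"unknown counts format {fmt!r}")


def _read_counts_tsv(path: Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: malformed header, need gene id + >=1 sample column")
    gene_ids = df.iloc[:, 0].tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | (numeric != np.floor(numeric))
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-integer cell {raw.iloc[g, s]!r} at gene "
            f"{gene_ids[g]!r} (row {g + 2}), sample {sample_ids[s]!r}"
        )
    return CountMatrix(gene_ids, sample_ids, numeric.to_numpy(dtype=np.int64))


def _sidecar(path: Path, kind: str) -> Path:
    return path.with_suffix(path.suffix + f".{kind}")


def _read_counts_mtx(path: Path) -> CountMatrix:
    rows_path, cols_path = _sidecar(path, "rows"), _sidecar(path, "cols")
    for p in (rows_path, cols_path):
        if not p.exists():
            raise FileNotFoundError(f"missing MatrixMarket sidecar {p}")
    gene_ids = rows_path.read_text().splitlines()
    sample_ids = cols_path.read_text().splitlines()
    mat = scipy.io.mmread(path)
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if not np.allclose(dense, np.round(dense)):
        raise ValidationError(f"{path}: non-integer entries in MatrixMarket file")
    return CountMatrix(gene_ids, sample_ids, dense.astype(np.int64))


def write_counts(counts: CountMatrix, path: PathLike, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("mtx" if path.suffix == ".mtx" else "tsv")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        df = counts.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", lineterminator="\n")
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(counts.counts))
        _sidecar(path, "rows").write_text("\n".join(counts.gene_ids) + "\n")
        _sidecar(path, "cols").write_text("\n".join(counts.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def read_metadata(path: PathLike) -> SampleTable:
    """Load the sample design table (TSV or CSV, inferred from suffix)."""
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    return SampleTable(df)


def write_metadata(meta: SampleTable, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["sample_id", "maternal_morph", "paternal_morph", "time_point", "family_id", "batch"]
    meta.frame[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_table(records, path: PathLike) -> None:
    """Write a rectangular result table as deterministic TSV.

    Accepts a DataFrame or a list of dict rows.  Column order is the input
    order; rows are written in input order.  Empty input is an error rather
    than an empty file.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        df = pd.DataFrame.from_records(records)
    if df.empty:
        raise ValidationError("refusing to write an empty table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    index = df.index.name is not None
    df.to_csv(path, sep="\t", index=index, lineterminator="\n", float_format="%.10g")


def digest(path: PathLike) -> str:
    """SHA-256 of a file, for run manifests."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: PathLike, config: dict, seed: int, inputs: dict[str, PathLike]) -> None:
    """Record config, seed and input digests so a run can be reproduced."""
    manifest = {
        "config": config,
        "seed": seed,
        "inputs": {name: {"path": str(p), "sha256": digest(p)} for name, p in inputs.items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    logger.info("wrote manifest %s", path)
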