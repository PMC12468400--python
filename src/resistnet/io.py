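"""Readers and writers for the tabular formats the pipeline consumes.

Expression matrices travel as delimited text (one header row of gene IDs,
first column sample IDs) or as an HDF5 container with datasets ``/X``,
``/obs_names``, ``/var_names``. Gene mappings are two-column TSV
(ensembl, symbol). Drug response and survival tables are plain CSV.
Gene sets use the GMT convention (name, description, members).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_gene_mapping",
    "read_response",
    "read_survival",
    "read_gmt",
]


def _looks_like_gene_ids(ids, namespace: str) -> float:
    ids = [str(i) for i in ids]
    if namespace == "ensembl":
        hits = sum(i.upper().startswith("ENS") for i in ids)
    else:
        # HGNC-like symbols: alnum, mostly upper-case, short
        hits = sum(i.isupper() and i.replace("-", "").isalnum() for i in ids)
    return hits / max(len(ids), 1)


def read_expression(
    path: str | Path,
    orientation_hint: str | None = None,
    namespace: str = "symbol",
) -> ExpressionMatrix:
    """Read an expression table into samples x genes orientation.

    ``orientation_hint`` is one of ``None``, ``"samples_rows"`` or
    ``"genes_rows"``. Without a hint, the table is transposed when >90% of
    the row identifiers look like gene IDs of the declared namespace.
    State starts at ``raw_tpm``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            X = np.asarray(f["X"], dtype=float)
            obs = [s.decode() if isinstance(s, bytes) else str(s) for s in f["obs_names"][:]]
            var = [s.decode() if isinstance(s, bytes) else str(s) for s in f["var_names"][:]]
        df = pd.DataFrame(X, index=obs, columns=var)
    else:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
        if len(bad):
            raise ValueError(f"non-numeric cells in columns: {list(bad)[:5]}")
    if orientation_hint == "genes_rows":
        df = df.T
    elif orientation_hint is None and _looks_like_gene_ids(df.index, namespace) > 0.9 > _looks_like_gene_ids(df.columns, namespace):
        df = df.T
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dups[:5]}")
    return ExpressionMatrix(df.astype(float), namespace=namespace, state="raw_tpm")


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=m.values.to_numpy())
            f.create_dataset("obs_names", data=np.array(m.sample_ids, dtype="S"))
            f.create_dataset("var_names", data=np.array(m.gene_ids, dtype="S"))
        return
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    m.values.to_csv(path, sep=sep)


def read_gene_mapping(path: str | Path) -> pd.DataFrame:
    """Two-column TSV (ensembl, symbol); '#' lines are comments.

    Ensembl version suffixes (".<n>") are stripped so lookups are
    version-agnostic.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["ensembl", "symbol"], dtype=str
    )
    # tolerate an accidental header row
    if df.iloc[0]["ensembl"].lower() in {"ensembl", "ensembl_id", "ensembl_gene_id"}:
        df = df.iloc[1:].reset_index(drop=True)
    df["ensembl"] = df["ensembl"].str.split(".").str[0]
    return df


def read_response(path: str | Path) -> pd.DataFrame:
    """Drug-response CSV with columns sample_id, drug, auc."""
    df = pd.read_csv(path)
    required = {"sample_id", "drug", "auc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    return df


def read_survival(path: str | Path) -> pd.DataFrame:
    """Survival CSV with columns sample_id, time, event (event in {0,1})."""
    df = pd.read_csv(path)
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    if not set(df["event"].unique()) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    return df


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: tab-separated name, description, member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
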