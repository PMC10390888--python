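"""Readers and writers for the package's file conventions.

Canonical dialect: TSV, UTF-8, '.' decimal, empty cell = missing; CSV is
accepted on read (chosen by file extension). Matrices have the feature or
gene id in the first column and sample ids as the header row. GCT 1.2 is
supported read-only. Floats are written at 6 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import (
    ExpressionMatrix,
    FeatureMatrix,
    NehetError,
    SampleAnnotation,
    SignatureTable,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_signature",
    "write_signature",
    "read_annotations",
    "write_provenance",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:
        raise NehetError(f"cannot parse {path}: {exc}") from exc
    return df


def _to_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col].str.strip() if df[col].dtype == object else df[col], errors="coerce")
        raw_missing = df[col].isna() | (df[col].astype(str).str.strip().isin(["", "NA", "NaN", "nan"]))
        bad = converted.isna() & ~raw_missing
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise NehetError(
                f"non-numeric cell in {path.name}, row {row!r}, column {col!r}"
            )
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def _check_ids(df: pd.DataFrame, path: Path):
    idx = pd.Index([str(i).strip() for i in df.index])
    cols = pd.Index([str(c).strip() for c in df.columns])
    for name, ids in (("feature/gene", idx), ("sample", cols)):
        dup = ids[ids.duplicated()].unique().tolist()
        if dup:
            raise NehetError(f"duplicate {name} id(s) in {path.name}: {dup[:5]}")
    df.index, df.columns = idx, cols
    return df


def read_matrix(path, modality: str = "expression") -> FeatureMatrix:
    """Read a features x samples matrix from TSV/CSV or GCT 1.2.

    Ids are whitespace-trimmed but otherwise preserved verbatim; empty or
    NA cells become missing markers. Duplicate ids, ragged rows and
    non-numeric cells raise ``NehetError`` with row/column context.
    """
    path = Path(path)
    if not path.exists():
        raise NehetError(f"no such file: {path}")
    first = path.open().readline()
    if first.startswith("#1.2"):
        df = _read_gct(path)
    else:
        df = _read_table(path, _sep_for(path))
    df = _check_ids(df, path)
    df = _to_numeric(df, path)
    if modality == "expression":
        return ExpressionMatrix(df)
    return FeatureMatrix(df, modality)


def _read_gct(path: Path) -> pd.DataFrame:
    with path.open() as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise NehetError(f"unsupported GCT version line {version!r} in {path.name}")
        dims = fh.readline().split()
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except (IndexError, ValueError):
            raise NehetError(f"malformed GCT dimension line in {path.name}")
        df = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
    if "Description" in df.columns:
        df = df.drop(columns=["Description"])
    elif df.shape[1] == n_cols + 1:
        df = df.drop(columns=[df.columns[0]])
    if df.shape != (n_rows, n_cols):
        raise NehetError(
            f"GCT {path.name} declares {n_rows}x{n_cols} but holds {df.shape}"
        )
    return df


def write_matrix(fm: FeatureMatrix, path) -> None:
    path = Path(path)
    fm.values.to_csv(
        path, sep=_sep_for(path), index_label="id", float_format="%.6g", na_rep=""
    )


def read_signature(path) -> SignatureTable:
    """Read a signature TSV with columns gene, group, ne_ref, non_ne_ref."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"gene", "group", "ne_ref", "non_ne_ref"}
    missing = required - set(df.columns)
    if missing:
        raise NehetError(f"signature {path.name} missing column(s): {sorted(missing)}")
    genes = [str(g).strip() for g in df["gene"]]
    if len(set(genes)) != len(genes):
        dup = sorted({g for g in genes if genes.count(g) > 1})
        raise NehetError(f"signature {path.name} lists gene(s) more than once: {dup}")
    return SignatureTable(
        genes,
        df["ne_ref"].astype(float).to_numpy(),
        df["non_ne_ref"].astype(float).to_numpy(),
        [str(g).strip() for g in df["group"]],
    )


def write_signature(sig: SignatureTable, path) -> None:
    sig.to_frame().to_csv(Path(path), sep="\t", index=False, float_format="%.6g")


def read_annotations(path) -> list[SampleAnnotation]:
    """Read a sample annotation table; ``sample_id`` column is mandatory."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in df.columns:
        raise NehetError(f"annotation file {path.name} lacks a sample_id column")
    known = {"sample_id", "lineage", "study", "amplification", "tf_class"}
    out = []
    for _, row in df.iterrows():
        amp = row.get("amplification")
        amp = None if pd.isna(amp) else int(amp)
        out.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                lineage=str(row.get("lineage", "") or ""),
                study=str(row.get("study", "") or ""),
                amplification=amp,
                tf_class=None if pd.isna(row.get("tf_class")) else str(row["tf_class"]),
                extra={k: row[k] for k in df.columns if k not in known},
            )
        )
    return out


def write_provenance(out_path, params: dict) -> None:
    """Write a reproducibility sidecar next to an output file."""
    from . import __version__

    sidecar = Path(str(out_path) + ".provenance.json")
    payload = {
        "tool": "nehet",
        "version": __version__,
        "multitest_method": "benjamini-hochberg",
        "params": {k: str(v) for k, v in params.items()},
    }
    sidecar.write_text(json.dumps(payload, indent=1, sort_keys=True))
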