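"""Plain-text (TSV) readers and writers for every pipeline table.

All tables are tab-separated with a ``gene_id`` (or ``sample_id``) key column;
writers can prepend ``#``-commented header lines recording the tool version
and the parameters that produced the file, and readers skip such comments.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .quantify import CountMatrix, FpkmMatrix

__all__ = [
    "read_table",
    "write_table",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_fpkm_tsv",
    "write_fpkm_tsv",
    "read_manifest_tsv",
]


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    header: Mapping[str, object] | None = None,
    index: bool = True,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, index_col: str | None = "gene_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if index_col is not None and index_col in df.columns:
        df = df.set_index(index_col)
    return df


def write_counts_tsv(
    counts: CountMatrix, path: str | Path, header: Mapping[str, object] | None = None
) -> None:
    meta = {"region": counts.region, **(header or {})}
    write_table(counts.counts, path, header=meta)


def read_counts_tsv(
    path: str | Path,
    region: str,
    totals: pd.Series | None = None,
) -> CountMatrix:
    df = read_table(path)
    return CountMatrix(region=region, counts=df, totals=totals)


def write_fpkm_tsv(
    fpkm: FpkmMatrix, path: str | Path, header: Mapping[str, object] | None = None
) -> None:
    meta = {"region": fpkm.region, **(header or {})}
    write_table(fpkm.values, path, header=meta)


def read_fpkm_tsv(path: str | Path, region: str) -> FpkmMatrix:
    return FpkmMatrix(region=region, values=read_table(path))


def read_manifest_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "condition", "assay", "timepoint_h", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    if "bait" in df.columns:
        df["bait"] = df["bait"].fillna("")
    return df
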