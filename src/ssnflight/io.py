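"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: TSV matrices and tables, GMT gene sets, and
edge-list TSVs with canonically ordered gene columns.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .enrich import GeneSet

__all__ = [
    "read_counts",
    "write_matrix",
    "read_matrix",
    "read_metadata",
    "write_table",
    "read_table",
    "read_gmt",
    "write_gmt",
]


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene × sample integer count matrix from TSV (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition", "tissue", "dataset", "dose_mGy"}
    missing = required - set(md.columns)
    if missing:
        raise ValueError(f"{path}: metadata lacks columns {sorted(missing)}")
    if md["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    bad = set(md["condition"]) - {"GC", "SF"}
    if bad:
        raise ValueError(f"{path}: unknown conditions {sorted(bad)}")
    return md


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT: one set per line — name, description, then member genes."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: GMT line needs name, description and >= 1 gene")
        sets.append(GeneSet(name=fields[0], genes=frozenset(fields[2:])))
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "synthetic") -> None:
    lines = [
        "\t".join([name, description, *genes])
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
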