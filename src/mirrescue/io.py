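"""Readers and writers for the plain-text formats used across the pipeline.

All tabular artifacts are TSV. Matrices carry the probe id in the first
column and sample ids in the header; sample maps are two columns
(sample, group); detection flags share the matrix layout with values in
{P, A}. Gene sets use the GMT convention (name, description, members...).
Numeric output is written with 6 significant digits so that repeated runs
are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .matrix import ExpressionMatrix

FLOAT_FORMAT = "%.6g"


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_sample_map(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "group"}.issubset(df.columns):
        raise ValueError("sample map must have columns 'sample' and 'group'")
    return df.set_index("sample")["group"]


def write_sample_map(groups: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"sample": groups.index, "group": groups.values})
    df.to_csv(path, sep="\t", index=False)


def read_expression(matrix_path: str | Path, samples_path: str | Path,
                    flags_path: str | Path | None = None) -> ExpressionMatrix:
    values = read_matrix_tsv(matrix_path)
    groups = read_sample_map(samples_path)
    flags = read_matrix_tsv(flags_path) if flags_path is not None else None
    return ExpressionMatrix(values=values, groups=groups, flags=flags)


def write_expression(matrix: ExpressionMatrix, outdir: str | Path,
                     prefix: str) -> dict[str, Path]:
    """Write values / sample map / flags; return the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["matrix"] = outdir / f"{prefix}_matrix.tsv"
    write_matrix_tsv(matrix.values, paths["matrix"])
    paths["samples"] = outdir / f"{prefix}_samples.tsv"
    write_sample_map(matrix.groups, paths["samples"])
    if matrix.flags is not None:
        paths["flags"] = outdir / f"{prefix}_flags.tsv"
        write_matrix_tsv(matrix.flags, paths["flags"])
    return paths


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"mirna", "gene", "source"}.issubset(df.columns):
        raise ValueError("prediction table needs columns mirna, gene, source")
    return df[["mirna", "gene", "source"]]


def write_predictions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name TAB description TAB genes...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "group", "gene", "ct"}
    if not need.issubset(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(need)}")
    return df[["sample", "group", "gene", "ct"]]


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
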