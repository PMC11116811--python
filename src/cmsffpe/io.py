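"""Plain-text file formats for the pipeline.

Everything is tab-delimited UTF-8 with Unix newlines and ``NA`` for missing
values: expression and TIN matrices are gene-by-sample with the row id in the
first column, labels and predictions are one sample per row, gene lists are
one identifier per line with ``#`` comments. All writers round-trip exactly
through the corresponding readers (to 1e-12 for reals).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

CMS_CLASSES = ("CMS1", "CMS2", "CMS3", "CMS4")
NO_LABEL = "NOLBL"

__all__ = [
    "CMS_CLASSES",
    "NO_LABEL",
    "read_matrix",
    "write_matrix",
    "read_expression",
    "read_gene_list",
    "write_gene_list",
    "read_labels",
    "write_labels",
    "read_coverage",
    "write_run_manifest",
]


def read_matrix(path: str | Path, index_name: str = "id") -> pd.DataFrame:
    """Read a row-id-by-sample TSV matrix of reals (``NA`` -> NaN)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype=None)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {path}: {dups[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    df.index = df.index.astype(str)
    df.index.name = index_name
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    out = df.copy()
    out.index.name = out.index.name or index_name
    out.to_csv(path, sep="\t", na_rep="NA", lineterminator="\n", float_format="%.10g")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample expression matrix; missing or negative values are errors."""
    df = read_matrix(path, index_name="gene_id")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing expression values in {path} (samples {bad[:5]})")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative expression values in {path}")
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and ``#`` comments ignored."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_labels(path: str | Path, allow_nolbl: bool = True) -> pd.Series:
    """Read a ``sample_id<TAB>cms`` table into a Series indexed by sample."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"labels file {path} needs columns sample_id, cms")
    labels = pd.Series(
        df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str), name="cms"
    )
    allowed = set(CMS_CLASSES) | ({NO_LABEL} if allow_nolbl else set())
    bad = sorted(set(labels) - allowed)
    if bad:
        raise ValueError(f"unknown labels in {path}: {bad}")
    if labels.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    labels.index.name = "sample_id"
    return labels


def write_labels(labels: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": labels.index, "cms": labels.to_numpy()})
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_coverage(path: str | Path) -> pd.DataFrame:
    """Read per-transcript sampled depth vectors.

    Columns: transcript_id, sample_id, depths (comma-separated integers,
    5'->3'). Returns a tidy frame with the depth vector as a list per row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"transcript_id", "sample_id", "depths"}
    if not required.issubset(df.columns):
        raise ValueError(f"coverage file {path} needs columns {sorted(required)}")
    if df.empty:
        raise ValueError(f"coverage file {path} has no records")
    df = df.copy()
    df["depths"] = df["depths"].map(
        lambda s: [int(x) for x in str(s).split(",") if x != ""]
    )
    return df


def write_run_manifest(
    path: str | Path, inputs: Mapping[str, str | Path], seed: int | None, **extra
) -> None:
    """Record input checksums, the seed and the package version next to an output."""
    import hashlib

    from . import __version__

    checksums = {}
    for name, p in inputs.items():
        p = Path(p)
        checksums[name] = {
            "path": str(p),
            "sha256": hashlib.sha256(p.read_bytes()).hexdigest() if p.is_file() else None,
        }
    manifest = {"version": __version__, "seed": seed, "inputs": checksums, **extra}
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
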