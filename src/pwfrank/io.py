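"""Readers and writers for the pipeline's plain-text formats.

All pwfrank-owned TSV files are UTF-8, tab-delimited, Unix newlines,
and start with a ``# pwfrank <kind> v1`` format-version comment line.
Gene ids are opaque, case-sensitive strings.  GMT files follow the
standard interchange layout (name, description, members; no comment
line, for compatibility with third-party readers).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GeneSetCatalog

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "read_gmt",
    "write_gmt",
    "read_table_tsv",
    "write_table_tsv",
]

FORMAT_VERSION = "v1"


class ParseError(ValueError):
    pass


def _header(kind: str) -> str:
    return f"# pwfrank {kind} {FORMAT_VERSION}\n"


def _open_skipping_header(path: str | Path) -> _io.StringIO:
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines(keepends=True)
    while lines and lines[0].startswith("#"):
        lines.pop(0)
    return _io.StringIO("".join(lines))


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header("expression"))
        expr.to_csv(fh, sep="\t", index_label="gene", lineterminator="\n")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples log2 matrix; first column is the gene id."""
    buf = _open_skipping_header(path)
    try:
        frame = pd.read_csv(buf, sep="\t", index_col=0, dtype={0: str})
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty expression matrix") from None
    if frame.empty or frame.shape[1] == 0:
        raise ParseError(f"{path}: empty expression matrix")
    dupes = frame.index[frame.index.duplicated()].unique()
    if len(dupes):
        raise ParseError(f"{path}: duplicated gene id(s): {list(dupes)}")
    non_numeric = frame.columns[
        [not np.issubdtype(d, np.number) for d in frame.dtypes]
    ]
    if len(non_numeric):
        for col in non_numeric:
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ParseError(
                f"{path}: non-numeric value at gene {row!r}, sample {col!r}"
            )
    return frame


def write_design_tsv(design: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header("design"))
        design.to_csv(fh, sep="\t", index_label="sample", lineterminator="\n")


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(
        _open_skipping_header(path), sep="\t", index_col="sample", dtype=str
    )
    required = {"experiment", "sorted", "treatment"}
    missing = required - set(design.columns)
    if missing:
        raise ParseError(f"{path}: design sheet lacks column(s) {sorted(missing)}")
    return design


def write_gmt(catalog: GeneSetCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in catalog:
            desc = catalog.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path: str | Path) -> GeneSetCatalog:
    """Parse a GMT catalog; duplicate members are dropped with a warning."""
    import warnings

    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">= 1 member (got {len(fields)} fields)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: duplicate members in set {name!r} "
                    "were de-duplicated",
                    stacklevel=2,
                )
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCatalog(sets=sets, descriptions=descriptions)


def write_table_tsv(frame: pd.DataFrame, path: str | Path, kind: str,
                    index: bool = True, index_label: str | None = None) -> None:
    """Write any result table with the standard format-version header."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header(kind))
        frame.to_csv(fh, sep="\t", index=index, index_label=index_label,
                     lineterminator="\n")


def read_table_tsv(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(_open_skipping_header(path), sep="\t", index_col=index_col)
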