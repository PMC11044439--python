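"""Readers and writers for the plain-text formats the package consumes.

Matrices and phenotype tables are TSV/CSV with one header row; gene sets use
the GMT dialect (term, description, members, tab-separated); probe-gene maps
are two-column TSV. All writers prepend a ``#`` comment line carrying the
tool version and, where relevant, the RNG seed, so result files are
self-describing.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import GeneSetCollection, OmicsMatrix, PhenotypeTable, ProbeGeneMap

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_phenotypes",
    "read_gmt",
    "read_probe_gene_map",
    "write_table",
]


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path, rows_are_features: bool = True, omic_label: str = "omic") -> OmicsMatrix:
    """Read a delimited numeric matrix with a header row and leading id column.

    With ``rows_are_features=False`` the file holds samples in rows and is
    transposed on load. Non-numeric cells are rejected with their coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values present; impute or drop first")
    if not rows_are_features:
        df = df.T
    return OmicsMatrix(df.to_numpy(float), list(df.index), list(df.columns), omic_label)


def write_matrix(m: OmicsMatrix, path, seed: int | None = None) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        fh.write(sep.join(["feature"] + m.sample_ids) + "\n")
        for fid, row in zip(m.feature_ids, m.values):
            fh.write(sep.join([fid] + [f"{v:.10g}" for v in row]) + "\n")


def read_phenotypes(path, response: str, confounders: list[str] | None = None) -> PhenotypeTable:
    """Read a sample table; first column = sample ids.

    The response is coerced to a two-level categorical when it has exactly two
    observed levels; a single-level response is an error. Confounders keep
    their native types (categorical when non-numeric or few-valued).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    df.index = df.index.map(str)
    confounders = list(confounders or [])
    if response not in df.columns:
        raise KeyError(f"{path}: response column {response!r} not found")
    n_levels = df[response].nunique()
    if n_levels == 1:
        raise ValueError(f"{path}: response {response!r} has one level")
    if df[response].dtype.kind not in "biufc" and n_levels > 2:
        raise ValueError(
            f"{path}: non-numeric response {response!r} has {n_levels} levels; at most 2 supported"
        )
    return PhenotypeTable(df, response, confounders)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT gene-set file (term, description, members...)."""
    terms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >=3")
            tid, name, members = fields[0], fields[1], [g for g in fields[2:] if g]
            terms.append((tid, name, frozenset(members)))
    return GeneSetCollection(terms)


def write_gmt(gs: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for tid, name, members in gs.terms:
            fh.write("\t".join([tid, name] + sorted(members)) + "\n")


def read_probe_gene_map(path) -> ProbeGeneMap:
    pairs = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter=_sep_for(path))
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty mapping file")
        for row in reader:
            if len(row) < 2:
                continue
            pairs.append((row[0], row[1]))
    return ProbeGeneMap(pairs)


def _header_comment(seed: int | None = None) -> str:
    tail = "" if seed is None else f" seed={seed}"
    return f"# cwgcna v{__version__}{tail}\n"


def write_table(df: pd.DataFrame, path, seed: int | None = None, index: bool = True) -> None:
    """Write a result table as TSV with the version/seed comment header.

    Floats are fixed to 10 significant digits so identical runs produce
    byte-identical files.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g", lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
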