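"""Expression-matrix and clinical-table I/O, probe collapsing, and standardization.

Expression matrices are plain pandas DataFrames with genes in rows (index)
and samples in columns, holding log2-scale values. Clinical tables are
DataFrames indexed by sample identifier. Signature gene lists are small
named collections of gene symbols with optional role tags (e.g. Oncotype
group membership).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


@dataclass
class SignatureGeneList:
    """A named list of gene symbols with optional per-gene role tags.

    Roles are free-form strings (e.g. the Oncotype group a gene belongs
    to); ``None`` when the signature carries no role information.
    """

    name: str
    entries: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        symbols = list(self.entries)
        if len({s.upper() for s in symbols}) != len(symbols):
            raise ValueError(f"duplicate symbols in signature {self.name!r}")

    @property
    def symbols(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_symbols(cls, name: str, symbols: list[str]) -> "SignatureGeneList":
        return cls(name=name, entries={s: None for s in symbols})


def _check_unique(values, what: str) -> None:
    index = pd.Index(values)
    if index.has_duplicates:
        dupes = sorted(index[index.duplicated()].unique().tolist())
        raise FormatError(f"duplicate {what}: {', '.join(map(str, dupes[:10]))}")


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Enforce expression-matrix invariants: unique IDs, finite numeric values."""
    _check_unique(matrix.index, "gene identifiers")
    _check_unique(matrix.columns, "sample identifiers")
    if not all(np.issubdtype(dt, np.number) for dt in matrix.dtypes):
        bad = [c for c, dt in matrix.dtypes.items() if not np.issubdtype(dt, np.number)]
        raise FormatError(f"non-numeric columns: {bad}")
    return matrix


def read_expression(path: str | Path, *, missing: str = "drop") -> pd.DataFrame:
    """Read a genes x samples TSV expression matrix (log2 scale).

    Parameters
    ----------
    path:
        TSV file; first column gene identifiers, header row sample IDs.
    missing:
        Policy for rows containing missing values after parsing:
        ``"drop"`` (default) removes them with a logged count,
        ``"error"`` raises, ``"keep"`` passes NaNs through.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"non-numeric value {raw.loc[row, col]!r} at gene {row!r}, sample {col!r}"
            )
        raw[col] = converted
    validate_expression(raw)
    n_missing_rows = int(raw.isna().any(axis=1).sum())
    if n_missing_rows:
        if missing == "error":
            raise FormatError(f"{n_missing_rows} gene rows contain missing values")
        if missing == "drop":
            logger.info("dropping %d gene rows with missing values", n_missing_rows)
            raw = raw.dropna(axis=0)
    return raw


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples expression matrix as TSV."""
    validate_expression(matrix)
    out = matrix.copy()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a per-sample clinical CSV, indexed by its first column (sample ID)."""
    table = pd.read_csv(path, index_col=0)
    _check_unique(table.index, "sample identifiers")
    return table


def write_clinical(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path)


def read_signature(path: str | Path) -> SignatureGeneList:
    """Read a signature gene list from JSON.

    Accepted forms::

        {"name": "...", "genes": ["A", "B", ...]}
        {"name": "...", "genes": {"A": "proliferation", "B": null, ...}}
    """
    with open(path) as handle:
        payload = json.load(handle)
    genes = payload["genes"]
    if isinstance(genes, list):
        entries = {g: None for g in genes}
    else:
        entries = dict(genes)
    return SignatureGeneList(name=payload.get("name", Path(path).stem), entries=entries)


def write_signature(signature: SignatureGeneList, path: str | Path) -> None:
    payload = {"name": signature.name, "genes": signature.entries}
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=1)


def collapse_probes(
    matrix: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene.

    For genes measured by several probes the probe with the highest mean
    expression across samples is retained (a common convention for
    summarized array data; alternatives such as per-gene averaging are
    easy to apply upstream). Probes without a mapping entry are dropped
    with a logged count.
    """
    mapped = [p for p in matrix.index if p in probe_to_gene]
    n_unmapped = matrix.shape[0] - len(mapped)
    if n_unmapped:
        logger.info("dropping %d unmapped probes", n_unmapped)
    if not mapped:
        raise FormatError("no probes could be mapped to genes")
    sub = matrix.loc[mapped]
    genes = pd.Series([probe_to_gene[p] for p in mapped], index=sub.index)
    means = sub.mean(axis=1)
    # within each gene keep the probe whose mean expression is maximal
    best = means.groupby(genes, sort=True).idxmax()
    out = sub.loc[best.to_numpy()]
    out.index = best.index
    out.index.name = "gene_id"
    return out


def map_signature(
    matrix: pd.DataFrame, signature: SignatureGeneList
) -> tuple[SignatureGeneList, SignatureGeneList]:
    """Partition a signature into genes present in / absent from the matrix.

    Symbol matching is case-insensitive; presence is reported against the
    matrix's gene identifiers. Returns ``(found, missing)``.
    """
    available = {str(g).upper(): g for g in matrix.index}
    found: dict[str, str | None] = {}
    missing: dict[str, str | None] = {}
    for symbol, role in signature.entries.items():
        if symbol.upper() in available:
            found[symbol] = role
        else:
            missing[symbol] = role
    logger.info(
        "signature %s: %d/%d genes found in matrix",
        signature.name,
        len(found),
        len(signature),
    )
    return (
        SignatureGeneList(name=signature.name, entries=found),
        SignatureGeneList(name=f"{signature.name}:missing", entries=missing),
    )


def resolve_symbols(matrix: pd.DataFrame, symbols: list[str]) -> list:
    """Map symbols (case-insensitively) to the matrix's own gene identifiers."""
    available = {str(g).upper(): g for g in matrix.index}
    out = []
    for s in symbols:
        key = s.upper()
        if key not in available:
            raise KeyError(f"gene {s!r} not present in expression matrix")
        out.append(available[key])
    return out


def zscore_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene row to mean 0, SD 1 (population SD, ddof=0).

    Raises if any gene has zero variance across samples; callers should
    drop constant genes first.
    """
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    if np.any(sd == 0):
        bad = matrix.index[sd == 0].tolist()
        raise ValueError(f"zero-variance genes cannot be standardized: {bad[:10]}")
    centred = values - values.mean(axis=1, keepdims=True)
    return pd.DataFrame(centred / sd[:, None], index=matrix.index, columns=matrix.columns)


def read_geo_series_matrix(path: str | Path) -> pd.DataFrame:
    """Minimal reader for a GEO Series Matrix expression table.

    Parses only the rectangular block between ``!series_matrix_table_begin``
    and ``!series_matrix_table_end`` (ID_REF rows x GSM columns); metadata
    lines are ignored. Intended for optional ingest of public GEO series;
    values are returned as-is (no normalization).
    """
    lines: list[str] = []
    with open(path) as handle:
        inside = False
        for line in handle:
            marker = line.strip().lower()
            if marker == "!series_matrix_table_begin":
                inside = True
                continue
            if marker == "!series_matrix_table_end":
                break
            if inside:
                lines.append(line)
    if not lines:
        raise FormatError("no series_matrix_table block found")
    from io import StringIO

    table = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col=0)
    table.index = table.index.map(lambda s: str(s).strip('"'))
    table.columns = [str(c).strip('"') for c in table.columns]
    table.index.name = "gene_id"
    return validate_expression(table)
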