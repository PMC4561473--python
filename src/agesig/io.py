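"""Readers and writers for the pipeline's on-disk artifacts.

All formats are plain tab-delimited text:

* expression matrix — identifiers in the first row/column, numeric body;
* sample table / probe annotation — TSV with mandatory columns;
* signature — TSV ``probe_id  direction  performance``;
* gene sets — GMT (term, description, then members).

Every read/write pair round-trips bit-exactly on valid inputs. Parsing is
locale-independent: decimal points only, scientific notation accepted.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    DIRECTIONS,
    ExpressionMatrix,
    GeneSetCollection,
    ProbeAnnotation,
    SampleTable,
    SignatureModel,
)

logger = logging.getLogger("agesig")

_TRUE_TOKENS = {"true", "1", "t", "yes"}
_FALSE_TOKENS = {"false", "0", "f", "no"}


def _parse_numeric_body(raw: pd.DataFrame, path) -> pd.DataFrame:
    """Convert a string-typed frame to float, pointing at the first bad cell.

    Uses Python's correctly-rounded float conversion so written values
    round-trip bit-exactly (pandas' fast parser can be one ulp off).
    """

    def _cell(value):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return np.nan
        if isinstance(value, str) and value.strip() == "":
            return np.nan
        return float(value)

    out = {}
    for col in raw.columns:
        try:
            out[col] = raw[col].map(_cell)
        except (TypeError, ValueError):
            for row, value in raw[col].items():
                try:
                    _cell(value)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric value {value!r} at row {row!r}, column {col!r}"
                    ) from None
    return pd.DataFrame(out, index=raw.index)


def read_expression_matrix(
    path,
    orientation: str = "probes",
    missing: str = "error",
) -> ExpressionMatrix:
    """Load a tab-delimited expression matrix.

    Parameters
    ----------
    orientation:
        ``"probes"`` if rows are probes (the default), ``"samples"`` if rows
        are samples (the matrix is transposed after reading). Never guessed.
    missing:
        ``"error"`` (default) rejects missing cells; ``"impute_median"``
        replaces them with the per-probe median.
    """
    if orientation not in ("probes", "samples"):
        raise ValueError(f"orientation must be 'probes' or 'samples', got {orientation!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    values = _parse_numeric_body(raw, path)
    if orientation == "samples":
        values = values.T
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    if values.columns.has_duplicates:
        dup = values.columns[values.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    if values.isna().any().any():
        if missing == "impute_median":
            n_missing = int(values.isna().sum().sum())
            med = values.median(axis=1)
            values = values.apply(lambda col: col.fillna(med))
            logger.info("imputed %d missing values with per-probe medians", n_missing)
        else:
            idx = np.argwhere(values.isna().to_numpy())[0]
            raise ValueError(
                f"{path}: missing value at probe {values.index[idx[0]]!r}, "
                f"sample {values.columns[idx[1]]!r} (pass missing='impute_median' to impute)"
            )
    return ExpressionMatrix(values)


def write_expression_matrix(matrix: ExpressionMatrix, path, orientation: str = "probes") -> None:
    """Write a matrix as TSV at full stored precision (read-back is exact)."""
    if orientation not in ("probes", "samples"):
        raise ValueError(f"orientation must be 'probes' or 'samples', got {orientation!r}")
    values = matrix.values if orientation == "probes" else matrix.values.T
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise ValueError("refusing to write a degenerate (empty) expression matrix")
    values.to_csv(path, sep="\t", index_label="id")


def read_signature(path) -> SignatureModel:
    """Read a signature TSV (probe_id, direction, performance)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    for col in ("probe_id", "direction", "performance"):
        if col not in df.columns:
            raise ValueError(f"{path}: signature file lacks column '{col}'")
    dirs = df["direction"].astype(str).str.lower()
    bad = ~dirs.isin(DIRECTIONS)
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise ValueError(
            f"{path}: unknown direction {df['direction'].iloc[i]!r} "
            f"for probe {df['probe_id'].iloc[i]!r} (row {i + 2})"
        )
    entries = pd.DataFrame(
        {"direction": dirs.to_numpy(), "performance": df["performance"].astype(float).to_numpy()},
        index=pd.Index(df["probe_id"], name="probe_id"),
    )
    return SignatureModel(entries)


def write_signature(signature: SignatureModel, path) -> None:
    out = signature.entries.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT dialect: term, description, members (tab-separated)."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term, desc = fields[0], fields[1]
            if term in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term!r}")
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ValueError(f"{path}:{lineno}: term {term!r} has no members")
            terms[term] = (desc, members)
    return GeneSetCollection(terms)


def write_gmt(gmt: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in gmt.terms.items():
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: sample table lacks mandatory column '{col}'")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return SampleTable(df.set_index("sample_id"))


def write_sample_table(table: SampleTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def _parse_bool_column(col: pd.Series, path, name: str) -> pd.Series:
    tokens = col.astype(str).str.strip().str.lower()
    if not tokens.isin(_TRUE_TOKENS | _FALSE_TOKENS).all():
        bad = col[~tokens.isin(_TRUE_TOKENS | _FALSE_TOKENS)].iloc[0]
        raise ValueError(f"{path}: cannot interpret {bad!r} as boolean in column '{name}'")
    return tokens.isin(_TRUE_TOKENS)


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_symbol": str})
    for col in ("probe_id", "gene_symbol", "multi_locus"):
        if col not in df.columns:
            raise ValueError(f"{path}: probe annotation lacks mandatory column '{col}'")
    if df["probe_id"].duplicated().any():
        dup = df["probe_id"][df["probe_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    df["multi_locus"] = _parse_bool_column(df["multi_locus"], path, "multi_locus")
    return ProbeAnnotation(df.set_index("probe_id"))


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    out = annotation.data.copy()
    out["multi_locus"] = np.where(out["multi_locus"], "TRUE", "FALSE")
    out.to_csv(path, sep="\t", index_label="probe_id")
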