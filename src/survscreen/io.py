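"""File I/O: expression matrices, clinical tables, gene sets, IHC counts.

In-memory containers are plain pandas objects:

* expression — DataFrame of z-scores, index = gene symbols, columns = sample
  IDs;
* clinical — DataFrame indexed by sample ID with columns ``time`` (months),
  ``event`` (0/1) and optional covariates (age, gs, t_category, ipsa,
  therapy);
* gene sets — dict mapping set name to a list of member symbols.

All files are UTF-8, tab-delimited; '' and 'NA' mark missing values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "SchemaError",
    "T_CATEGORY_MAP",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_gmt",
    "read_ihc_counts",
    "align_samples",
]

logger = logging.getLogger("survscreen")

NA_VALUES = ("", "NA")

# Pathological T stage -> ordinal coding used as a single Cox covariate.
T_CATEGORY_MAP = {
    "pT2": 2, "pT2a": 2, "pT2b": 2, "pT2c": 2,
    "pT3": 3, "pT3a": 3, "pT3b": 3,
    "pT4": 4,
    "T1c": 1, "T2a": 2, "T2b": 2, "T2c": 2, "T3a": 3, "T3b": 3, "T4": 4,
}


class ParseError(ValueError):
    """Malformed input file."""


class SchemaError(ValueError):
    """Structurally valid file violating the expected schema."""


def read_expression_matrix(path, dialect: str = "cbioportal_zscore",
                           na_values=NA_VALUES) -> pd.DataFrame:
    """Read a gene x sample expression matrix.

    ``cbioportal_zscore`` dialect: first column is the gene symbol, an
    optional second ``Entrez_Gene_Id`` column is dropped, remaining columns
    are samples. ``plain``: first column gene symbol, rest samples.
    Duplicated gene symbols keep the row with the fewest missing values
    (ties: first occurrence), with a warning.
    """
    if dialect not in ("cbioportal_zscore", "plain"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=list(na_values),
                         keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if df.shape[0] == 0:
        raise ParseError(f"{path}: header-only file, no data rows")
    cols = list(df.columns)
    drop = [cols[0]]
    if dialect == "cbioportal_zscore" and len(cols) > 1 and \
            cols[1].lower() in ("entrez_gene_id", "entrez_id"):
        drop.append(cols[1])
    sample_cols = [c for c in cols if c not in drop]
    if not sample_cols:
        raise ParseError(f"{path}: no sample columns")
    symbols = df[cols[0]].astype(str)

    values = pd.DataFrame(index=df.index, columns=sample_cols, dtype=float)
    for c in sample_cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = converted.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: non-numeric value {df[c].iloc[row]!r} "
                f"for gene {symbols.iloc[row]!r}, column {c!r}"
            )
        values[c] = converted
    values.index = pd.Index(symbols, name="gene")

    if symbols.duplicated().any():
        dups = sorted(set(symbols[symbols.duplicated()]))
        logger.warning("duplicate gene symbols %s: keeping row with fewest missing values", dups)
        n_missing = values.isna().sum(axis=1).to_numpy()
        keep_pos = []
        seen = {}
        for pos, sym in enumerate(symbols):
            if sym not in seen:
                seen[sym] = pos
                keep_pos.append(pos)
            elif n_missing[pos] < n_missing[seen[sym]]:
                keep_pos[keep_pos.index(seen[sym])] = pos
                seen[sym] = pos
        values = values.iloc[sorted(keep_pos)]
    return values


def write_expression_matrix(expr: pd.DataFrame, path,
                            dialect: str = "cbioportal_zscore") -> None:
    out = expr.copy()
    out.index.name = "Hugo_Symbol" if dialect == "cbioportal_zscore" else "gene"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_clinical_table(path, t_category_map: dict | None = None,
                        na_values=NA_VALUES) -> pd.DataFrame:
    """Read the per-sample clinical/survival table.

    Requires ``sample_id`` (or ``sample``), ``time`` and ``event`` columns.
    Rows missing time or event are dropped (count logged); event must be
    0/1; textual T categories are mapped to the ordinal coding.
    """
    try:
        df = pd.read_csv(path, sep="\t", na_values=list(na_values),
                         keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    df.columns = [str(c).lower() for c in df.columns]
    if "sample" in df.columns and "sample_id" not in df.columns:
        df = df.rename(columns={"sample": "sample_id"})
    missing_cols = {"sample_id", "time", "event"} - set(df.columns)
    if missing_cols:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing_cols)}")

    n0 = len(df)
    df = df.dropna(subset=["time", "event"])
    if len(df) < n0:
        logger.warning("dropped %d rows without survival data", n0 - len(df))
    if df.empty:
        raise SchemaError(f"{path}: no rows with complete survival data")
    if df["sample_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample IDs")

    df["time"] = pd.to_numeric(df["time"], errors="raise")
    if (df["time"] < 0).any():
        raise SchemaError(f"{path}: negative survival times")
    ev = pd.to_numeric(df["event"], errors="raise")
    if not ev.isin([0, 1]).all():
        raise SchemaError(f"{path}: event column must be 0/1")
    df["event"] = ev.astype(int)

    if "t_category" in df.columns and df["t_category"].dtype == object:
        cmap = T_CATEGORY_MAP if t_category_map is None else t_category_map
        mapped = df["t_category"].map(lambda v: cmap.get(v, v) if isinstance(v, str) else v)
        df["t_category"] = pd.to_numeric(mapped, errors="raise")
    return df.set_index("sample_id")


def write_clinical_table(clin: pd.DataFrame, path) -> None:
    clin.to_csv(path, sep="\t", index=True, index_label="sample_id", na_rep="NA")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, tab-separated members."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name = fields[0]
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    if not sets:
        raise ParseError(f"{path}: no gene sets")
    return sets


def read_ihc_counts(path) -> pd.DataFrame:
    """Read per-field IHC intensity-category counts.

    Columns: patient_id, field_id, n_negative, n_low, n_positive, n_high.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [str(c).lower() for c in df.columns]
    required = {"patient_id", "field_id", "n_negative", "n_low", "n_positive", "n_high"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    counts = df[["n_negative", "n_low", "n_positive", "n_high"]]
    if (counts < 0).to_numpy().any():
        raise SchemaError(f"{path}: negative counts")
    return df


def align_samples(expr: pd.DataFrame, clin: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both tables to their common samples, in expression order."""
    common = [s for s in expr.columns if s in set(clin.index)]
    if not common:
        raise ValueError(
            f"no samples in common ({expr.shape[1]} expression vs {len(clin)} clinical IDs)"
        )
    logger.info("aligned %d common samples", len(common))
    return expr.loc[:, common], clin.loc[common]
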