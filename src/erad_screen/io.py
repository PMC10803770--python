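"""Readers and writers for the pipeline's tab-separated tables.

All tables are UTF-8 TSV with a header row and unquoted identifiers, the
dialect of proteomics supplementary tables. Missing PSM entries mean "not
detected" and are materialized as zero when a table is pivoted.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd

from .errors import IntegrityError, SchemaError

PSM_COLUMNS = ("psm_igg", "psm_sko", "psm_wt", "psm_hko")
PSM_KEY = ("protein_id", "experiment_id")

ANNOT_COLUMNS = (
    "protein_id",
    "gene_symbol",
    "localizations",
    "has_signal_peptide",
    "n_glycosylation_sites",
    "has_disulfide",
    "n_tm_domains",
)

DE_COLUMNS = ("gene_symbol", "contrast", "log2fc", "padj")

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def ensure_dir(path) -> None:
    os.makedirs(path, exist_ok=True)


def _require(df: pd.DataFrame, columns: Iterable[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _to_bool(series: pd.Series, path, name: str) -> pd.Series:
    if series.dtype == bool:
        return series
    try:
        return series.astype(str).str.strip().str.lower().map(_BOOL_MAP).astype(bool)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: column {name} is not boolean-like") from exc


def read_psm_table(path) -> pd.DataFrame:
    """Read a long-format PSM count table.

    One row per (protein, experiment) with non-negative integer counts for
    the four genotype pulldowns. Duplicate keys, negative counts and
    non-integer counts are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "experiment_id": str})
    _require(df, PSM_KEY + PSM_COLUMNS, path)
    for c in PSM_COLUMNS:
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any():
            raise ValueError(f"{path}: non-numeric value in {c}")
        if (col < 0).any():
            raise ValueError(f"{path}: negative PSM count in {c}")
        if (col != col.round()).any():
            raise ValueError(f"{path}: non-integer PSM count in {c}")
        df[c] = col.astype("int64")
    dup = df.duplicated(subset=list(PSM_KEY))
    if dup.any():
        first = df.loc[dup, list(PSM_KEY)].iloc[0].tolist()
        raise IntegrityError(f"{path}: duplicate (protein, experiment) row {first}")
    return df.reset_index(drop=True)


def read_annotation_table(path) -> pd.DataFrame:
    """Read protein annotations; derives the keratin flag when absent.

    ``localizations`` is a semicolon-separated subset of
    {ER, Golgi, lysosome, membrane, nucleus, mitochondrion, secreted,
    cytosol} and must be non-empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ANNOT_COLUMNS, path)
    if (df["localizations"].isna() | (df["localizations"].str.strip() == "")).any():
        raise ValueError(f"{path}: empty localizations entry")
    for c in ("has_signal_peptide", "has_disulfide"):
        df[c] = _to_bool(df[c], path, c)
    for c in ("n_glycosylation_sites", "n_tm_domains"):
        df[c] = pd.to_numeric(df[c]).astype("int64")
        if (df[c] < 0).any():
            raise ValueError(f"{path}: negative count in {c}")
    if "is_keratin_family" in df.columns:
        df["is_keratin_family"] = _to_bool(df["is_keratin_family"], path,
                                           "is_keratin_family")
    else:
        df["is_keratin_family"] = df["gene_symbol"].str.upper().str.match(r"KRT(AP)?\d")
    if "species" not in df.columns:
        df["species"] = "human"
    if df["protein_id"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate protein_id")
    return df.reset_index(drop=True)


def read_de_table(path) -> pd.DataFrame:
    """Read a differential-expression table (gene, contrast, log2fc, padj)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str, "contrast": str})
    _require(df, DE_COLUMNS, path)
    df["log2fc"] = pd.to_numeric(df["log2fc"])
    df["padj"] = pd.to_numeric(df["padj"])
    ok = df["padj"].isna() | ((df["padj"] >= 0) & (df["padj"] <= 1))
    if not ok.all():
        raise ValueError(f"{path}: padj outside [0, 1]")
    return df.reset_index(drop=True)


def read_ortholog_map(path) -> dict[str, str]:
    """Read a mouse→human symbol map (columns mouse_symbol, human_symbol).

    The mapping must be a function: a mouse symbol listed twice with
    different human targets is an error. Lookup is case-normalized.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ("mouse_symbol", "human_symbol"), path)
    mapping: dict[str, str] = {}
    for mouse, human in zip(df["mouse_symbol"], df["human_symbol"]):
        key = mouse.strip().upper()
        val = human.strip().upper()
        if key in mapping and mapping[key] != val:
            raise IntegrityError(f"{path}: mouse symbol {mouse} maps to two targets")
        mapping[key] = val
    return mapping


def read_pathway_table(path) -> pd.DataFrame:
    """Read pathway assignments (gene_symbol, pathway); multi-assignment OK."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ("gene_symbol", "pathway"), path)
    return df.drop_duplicates().reset_index(drop=True)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a TSV deterministically (fixed float format, no index)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def pivot_counts(psm: pd.DataFrame, column: str) -> pd.DataFrame:
    """Protein × experiment matrix of one genotype column, absences as 0."""
    wide = psm.pivot_table(
        index="protein_id", columns="experiment_id", values=column,
        aggfunc="sum", fill_value=0,
    )
    return wide.astype("int64")
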