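"""Reading, validation and writing of the pipeline's tabular formats.

All tables are tab-separated text with a header line.  The count table
is a long (tidy) layout — one row per gene x sample with the read count
of each haplotype — matching the shape of gene-level haplotype
expression output from read-backed phasing tools.  Allelic data are
sparse per sample (only heterozygous genes are measurable), which makes
the long layout the natural one.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .errors import FormatError, StructureError

__all__ = [
    "COUNT_COLUMNS",
    "SHEET_COLUMNS",
    "ANNOTATION_COLUMNS",
    "read_count_table",
    "read_sample_sheet",
    "read_annotation",
    "validate_count_table",
    "validate_sample_sheet",
    "validate_annotation",
    "write_table",
]

COUNT_COLUMNS = ["gene_id", "sample_id", "hapA_count", "hapB_count"]
SHEET_COLUMNS = ["sample_id", "individual_id", "tissue", "twin_pair_id", "zygosity"]
ANNOTATION_COLUMNS = ["gene_id", "prior_status", "par_flag"]

VALID_ZYGOSITY = {"MZ", "DZ", "unknown"}
VALID_PRIOR_STATUS = {"silenced", "escape", "variable", "discordant_unknown"}

PathLike = Union[str, Path]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing column(s) {missing}")


def validate_count_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a count table in memory; returns the table with integer
    count dtypes.  Row order is preserved."""
    _require_columns(df, COUNT_COLUMNS, "count table")
    df = df.copy()
    for col in ("hapA_count", "hapB_count"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            row = int(df.index[bad][0])
            raise FormatError(
                f"count table row {row}: non-integer {col} value "
                f"{df[col].iloc[row]!r} (gene {df['gene_id'].iloc[row]!r}, "
                f"sample {df['sample_id'].iloc[row]!r})"
            )
        if (numeric < 0).any():
            row = int(df.index[numeric < 0][0])
            raise FormatError(
                f"count table row {row}: negative {col} value "
                f"{df[col].iloc[row]!r} (gene {df['gene_id'].iloc[row]!r}, "
                f"sample {df['sample_id'].iloc[row]!r})"
            )
        df[col] = numeric.astype("int64")
    dup = df.duplicated(subset=["gene_id", "sample_id"])
    if dup.any():
        row = int(df.index[dup][0])
        raise FormatError(
            f"count table row {row}: duplicate (gene, sample) key "
            f"({df['gene_id'].iloc[row]!r}, {df['sample_id'].iloc[row]!r})"
        )
    return df


def read_count_table(path: PathLike) -> pd.DataFrame:
    """Read and validate a tab-separated gene-level haplotype count table.

    Columns: ``gene_id``, ``sample_id``, ``hapA_count``, ``hapB_count``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    return validate_count_table(df)


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet in memory.

    Enforces: unique sample ids; a twin pair id maps to exactly two
    distinct individuals; zygosity is present and valid whenever a twin
    pair id is present.
    """
    _require_columns(df, SHEET_COLUMNS[:3], "sample sheet")
    df = df.copy()
    for col in ("twin_pair_id", "zygosity"):
        if col not in df.columns:
            df[col] = pd.NA
    df["twin_pair_id"] = df["twin_pair_id"].replace("", pd.NA)
    df["zygosity"] = df["zygosity"].replace("", pd.NA)

    dup = df.duplicated(subset=["sample_id"])
    if dup.any():
        raise FormatError(
            f"sample sheet: duplicate sample_id {df['sample_id'][dup].iloc[0]!r}"
        )
    paired = df[df["twin_pair_id"].notna()]
    for pair_id, group in paired.groupby("twin_pair_id"):
        individuals = group["individual_id"].unique()
        if len(individuals) != 2:
            raise StructureError(
                f"sample sheet: twin pair {pair_id!r} maps to "
                f"{len(individuals)} individual(s), expected exactly 2"
            )
        if group["zygosity"].isna().any():
            raise StructureError(
                f"sample sheet: twin pair {pair_id!r} has samples with "
                "missing zygosity"
            )
        zygo = set(group["zygosity"].dropna())
        bad = zygo - VALID_ZYGOSITY
        if bad:
            raise FormatError(
                f"sample sheet: unknown zygosity token(s) {sorted(bad)} "
                f"for twin pair {pair_id!r} (expected one of {sorted(VALID_ZYGOSITY)})"
            )
        if len(zygo) != 1:
            raise StructureError(
                f"sample sheet: twin pair {pair_id!r} has conflicting "
                f"zygosity labels {sorted(zygo)}"
            )
    loose = df[df["twin_pair_id"].isna() & df["zygosity"].notna()]
    bad = set(loose["zygosity"]) - VALID_ZYGOSITY
    if bad:
        raise FormatError(
            f"sample sheet: unknown zygosity token(s) {sorted(bad)}"
        )
    return df


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    """Read and validate a tab-separated sample sheet.

    Columns: ``sample_id``, ``individual_id``, ``tissue``, and
    optionally ``twin_pair_id`` and ``zygosity`` (MZ/DZ/unknown).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_sheet(df)


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ANNOTATION_COLUMNS[:2], "annotation")
    df = df.copy()
    if "par_flag" not in df.columns:
        df["par_flag"] = False
    bad = ~df["prior_status"].isin(VALID_PRIOR_STATUS)
    if bad.any():
        raise FormatError(
            f"annotation: unknown prior_status "
            f"{df['prior_status'][bad].iloc[0]!r} "
            f"(expected one of {sorted(VALID_PRIOR_STATUS)})"
        )
    if df["gene_id"].duplicated().any():
        dup_gene = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise FormatError(f"annotation: duplicate gene_id {dup_gene!r}")
    df["par_flag"] = (
        df["par_flag"].astype(str).str.lower().isin(("true", "1", "yes"))
    )
    return df


def read_annotation(path: PathLike) -> pd.DataFrame:
    """Read a reference XCI-status annotation table.

    Columns: ``gene_id``, ``prior_status`` (silenced / escape / variable
    / discordant_unknown) and an optional boolean ``par_flag`` marking
    pseudoautosomal genes.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "prior_status": str})
    return validate_annotation(df)


def write_table(df: pd.DataFrame, path: PathLike, float_format: Optional[str] = "%.10g") -> None:
    """Write any result table as tab-separated text (deterministic
    formatting so identical runs produce byte-identical files)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
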