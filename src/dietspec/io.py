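"""Tabular input/output and packaged reference tables.

All on-disk formats are comma-separated UTF-8 with a header row. Months are
stored as short English names in fixtures and mapped to integers 1-12 on
load; everything downstream works with integers.
"""
from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

MONTHS = {
    "Jan": 1, "Feb": 2, "Mar": 3, "Apr": 4, "May": 5, "June": 6, "Jun": 6,
    "July": 7, "Jul": 7, "Aug": 8, "Sept": 9, "Sep": 9, "Oct": 10,
    "Nov": 11, "Dec": 12,
}
MONTH_NAMES = {1: "Jan", 2: "Feb", 3: "Mar", 4: "Apr", 5: "May", 6: "June",
               7: "July", 8: "Aug", 9: "Sept", 10: "Oct", 11: "Nov", 12: "Dec"}


class TableFormatError(ValueError):
    """A malformed cell, row or header in a delimited input table."""


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("dietspec").joinpath("data", name)))


def month_number(value) -> int:
    """Map a month name or number to 1-12, raising on anything else."""
    if isinstance(value, (int, np.integer)):
        if not 1 <= int(value) <= 12:
            raise TableFormatError(f"month out of range: {value}")
        return int(value)
    v = str(value).strip()
    if v.isdigit():
        return month_number(int(v))
    try:
        return MONTHS[v.capitalize() if v.capitalize() in MONTHS else v]
    except KeyError:
        raise TableFormatError(f"unrecognized month: {value!r}") from None


def read_count_table(path) -> pd.DataFrame:
    """Read a samples x taxa table of sequence read counts.

    First column is the sample identifier; remaining columns are taxa.
    Counts must be non-negative integers; a taxon absent from a sample is
    an explicit 0 (compositional closure), never missing.
    """
    df = pd.read_csv(path, dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = "sample_id"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise TableFormatError(f"duplicate sample_id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise TableFormatError(f"duplicate taxon {dup!r} in {path}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.floor(vals))
        if bad.any():
            row = df.index[bad][0]
            raise TableFormatError(
                f"count at sample {row!r}, taxon {col!r} is not a "
                f"non-negative integer: {df.loc[row, col]!r}")
        df[col] = vals.astype(np.int64)
    if (df.sum(axis=1) == 0).any():
        row = df.index[df.sum(axis=1) == 0][0]
        raise TableFormatError(f"sample {row!r} has no positive counts")
    return df


def write_count_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="sample_id")


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata: sample_id, location, month, year."""
    df = pd.read_csv(path, dtype={"sample_id": str}).set_index("sample_id")
    for col in ("location", "month", "year"):
        if col not in df.columns:
            raise TableFormatError(f"metadata missing column {col!r}")
        if df[col].isna().any():
            row = df.index[df[col].isna()][0]
            raise TableFormatError(f"metadata {col!r} missing for sample {row!r}")
    df["month"] = df["month"].map(month_number)
    df["year"] = df["year"].astype(int)
    return df


def read_qpcr(path) -> pd.DataFrame:
    """Read replicated ZFX/ZFY amplification calls (0/1 per reaction)."""
    df = pd.read_csv(path, dtype={"sample_id": str}).set_index("sample_id")
    cols = ["zfx_1", "zfx_2", "zfy_1", "zfy_2"]
    for col in cols:
        if col not in df.columns:
            raise TableFormatError(f"qPCR table missing column {col!r}")
        if not df[col].isin([0, 1]).all():
            row = df.index[~df[col].isin([0, 1])][0]
            raise TableFormatError(
                f"qPCR call at sample {row!r}, {col} must be 0 or 1")
    return df[cols].astype(bool)


def read_annotation(path) -> pd.DataFrame:
    """Read the taxon annotation: order, habitat class, salmonid flag."""
    df = pd.read_csv(path).set_index("taxon")
    df["is_salmonid"] = df["is_salmonid"].astype(bool)
    allowed = {"benthic", "demersal", "pelagic", "unknown"}
    bad = set(df["habitat"].unique()) - allowed
    if bad:
        raise TableFormatError(f"unknown habitat classes: {sorted(bad)}")
    return df


def read_hard_parts(path) -> pd.DataFrame:
    """Read juvenile/adult salmonid ratios from hard-part analysis.

    Columns: scope (sample|month|season), sample_id, location, year, month,
    season, species, juvenile_fraction. Key columns irrelevant to a scope
    are left empty.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    if ((df["juvenile_fraction"] < 0) | (df["juvenile_fraction"] > 1)).any():
        raise TableFormatError("juvenile_fraction outside [0, 1]")
    bad = set(df["scope"].unique()) - {"sample", "month", "season"}
    if bad:
        raise TableFormatError(f"unknown hard-part scope: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# Packaged reference tables (printed summary tables of the source study)
# ---------------------------------------------------------------------------

def load_group_summaries() -> pd.DataFrame:
    """The printed per-group summary table, verbatim (111 rows).

    Columns: location, month (int), month_name, year, season, sex,
    min_prey_density, theoretical_min, n, mean_psi, use (bool), shannon.

    Note the source table is internally incomplete: its group sizes sum to
    1,099 although the companion sexed-count table totals 1,145; see
    :func:`reconciled_group_sizes`.
    """
    df = pd.read_csv(_data_path("group_summaries.csv"))
    df["month_name"] = df["month"]
    df["month"] = df["month"].map(month_number)
    df["use"] = df["use"].eq("Yes")
    return df


def load_sexed_counts() -> pd.DataFrame:
    """Per (location, year, month) female/male sexed-scat counts."""
    df = pd.read_csv(_data_path("sexed_counts.csv"))
    df["month_name"] = df["month"]
    df["month"] = df["month"].map(month_number)
    return df


def load_sexed_count_totals() -> pd.DataFrame:
    """The printed marginal totals of the sexed-count table."""
    return pd.read_csv(_data_path("sexed_count_totals.csv"))


def load_model_comparison() -> pd.DataFrame:
    """The printed four-model comparison (predictors, r2_fixed, r2, AIC, wi)."""
    return pd.read_csv(_data_path("model_comparison.csv"))


def load_annotation_fixture() -> pd.DataFrame:
    """Illustrative taxon annotation covering the study's 13 prey orders.

    The habitat assignments are plausible for the Salish Sea but are a
    starter table, not the study's (unpublished) exhaustive list.
    """
    return read_annotation(_data_path("taxon_annotation_illustrative.csv"))


def reconciled_group_sizes() -> pd.DataFrame:
    """Group sizes completed by cross-referencing the sexed-count table.

    The printed group-summary table omits three groups whose sexed-scat
    counts appear in the monthly sex-determination table (CB Aug-2012 Male,
    CM Jul-2012 Female, FR Sep-2013 Male; 46 samples in total — exactly the
    difference between the two tables' totals). This returns one row per
    group actually implied by the sexed counts (114 rows) with columns
    location, year, month, sex, n, theoretical_min, retained (n >= 5), and
    in_summary_table (whether the group was printed).
    """
    counts = load_sexed_counts()
    long = counts.melt(
        id_vars=["location", "year", "month"],
        value_vars=["n_female", "n_male"], var_name="sex", value_name="n")
    long["sex"] = long["sex"].map({"n_female": "Female", "n_male": "Male"})
    long = long[long["n"] > 0].reset_index(drop=True)
    printed = load_group_summaries()[["location", "year", "month", "sex"]]
    printed = set(map(tuple, printed.to_numpy()))
    long["in_summary_table"] = [
        (r.location, r.year, r.month, r.sex) in printed
        for r in long.itertuples()]
    long["theoretical_min"] = 1.0 / long["n"]
    long["retained"] = long["n"] >= 5
    return long
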