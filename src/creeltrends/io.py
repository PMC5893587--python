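"""Reading and writing the pipeline's tabular interchange formats.

Catch records and species attributes travel as plain CSV.  The attributes
file may declare the basis of its length-weight coefficients in a leading
comment line (``# lw_basis: mm_kg`` | ``mm_g`` | ``cm_g``); everything is
converted to the mm -> kg basis internally so the classic 10^b unit error
cannot occur downstream.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import CATCH_COLUMNS

ATTRIBUTE_COLUMNS = [
    "species",
    "family",
    "lw_a",
    "lw_b",
    "lw_source_tier",
    "max_length_mm",
    "iconic",
]

LW_BASES = ("mm_kg", "mm_g", "cm_g")


def read_catch_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CATCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catch file {path} missing columns: {missing}")
    df["year"] = df["year"].astype(int)
    df["count"] = df["count"].astype(int)
    return df[CATCH_COLUMNS]


def write_catch_csv(records: pd.DataFrame, path) -> None:
    records[CATCH_COLUMNS].to_csv(path, index=False)


def _basis_factor(basis: str, lw_b: pd.Series) -> pd.Series:
    """Multiplier turning lw_a on ``basis`` into the mm -> kg basis."""
    if basis == "mm_kg":
        return pd.Series(1.0, index=lw_b.index)
    if basis == "mm_g":
        return pd.Series(1e-3, index=lw_b.index)
    if basis == "cm_g":
        # W_g = a (L_mm / 10)^b  =>  W_kg = (a 10^-b / 1000) L_mm^b
        return 10.0 ** (-lw_b) / 1000.0
    raise ValueError(f"unknown lw basis {basis!r}; use one of {LW_BASES}")


def read_attributes_csv(path, basis: str | None = None) -> pd.DataFrame:
    """Load species attributes, resolving duplicates by coefficient provenance.

    When several coefficient rows exist for one species, the row with the
    lowest source tier (1 = local study, 4 = farthest region) is kept.
    ``basis`` overrides any ``# lw_basis:`` declaration in the file.
    """
    declared = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "lw_basis" in first:
        declared = first.split(":", 1)[1].strip()
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ATTRIBUTE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"attributes file {path} missing columns: {missing}")
    use_basis = basis or declared or "mm_kg"
    df = df.copy()
    df["lw_a"] = df["lw_a"] * _basis_factor(use_basis, df["lw_b"])

    bad_tier = ~df["lw_source_tier"].isin([1, 2, 3, 4])
    if bad_tier.any():
        raise ValueError(
            f"lw_source_tier outside 1-4 for: {sorted(df.loc[bad_tier, 'species'])}"
        )
    df = (
        df.sort_values(["species", "lw_source_tier"], kind="stable")
        .drop_duplicates("species", keep="first")
        .reset_index(drop=True)
    )
    df["iconic"] = df["iconic"].astype(bool)
    return df[ATTRIBUTE_COLUMNS]


def write_attributes_csv(attributes: pd.DataFrame, path, basis: str = "mm_kg") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# lw_basis: {basis}\n")
        attributes[ATTRIBUTE_COLUMNS].to_csv(fh, index=False)
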