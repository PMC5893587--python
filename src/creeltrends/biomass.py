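"""Allometric length-to-weight conversion.

Fish mass scales with length as W = a L^b.  Coefficients are species
specific inputs (never estimated here) and are carried on the mm -> kg
basis after loading, so ``to_biomass`` is a pure power law.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def to_biomass(fork_length_mm, lw_a, lw_b):
    """Mass in kg of a fish of the given fork length.

    Accepts scalars or aligned arrays; all inputs must be positive.
    """
    length = np.asarray(fork_length_mm, dtype=float)
    a = np.asarray(lw_a, dtype=float)
    b = np.asarray(lw_b, dtype=float)
    if (length <= 0).any() or (a <= 0).any() or (b <= 0).any():
        raise ValueError("lengths and allometric coefficients must be positive")
    out = a * length**b
    if out.ndim == 0:
        return float(out)
    return out


def add_biomass(records: pd.DataFrame, attributes: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``biomass_kg`` column (per-record mass x count).

    Species present in the records but absent from the attribute table
    raise, since no mass can be assigned; the record filters drop such
    rows first when configured to.
    """
    attrs = attributes.set_index("species")
    unknown = set(records["species"]) - set(attrs.index)
    if unknown:
        raise KeyError(f"no attributes for species: {sorted(unknown)}")
    merged = records.merge(
        attributes[["species", "lw_a", "lw_b"]], on="species", how="left"
    )
    out = records.copy()
    out["biomass_kg"] = (
        to_biomass(
            merged["fork_length_mm"].to_numpy(),
            merged["lw_a"].to_numpy(),
            merged["lw_b"].to_numpy(),
        )
        * merged["count"].to_numpy()
    )
    return out
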