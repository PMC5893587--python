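"""Record exclusion filters and per-fishery analysis timeframes.

A raw creel database mixes trip records from many gears, places and
decades, with occasional measurement errors and long tails of rarely
landed taxa.  Before any trend is fitted the database is reduced to its
main components by four sequential filters:

1. location  — drop records from sectors outside the configured region;
2. validity  — drop records with impossible fork lengths (non-positive,
   missing, or beyond the species maximum by more than a tolerance) and,
   unless running strict, records of species with no attribute row;
3. family    — drop families contributing < 1% of overall retained biomass;
4. species   — drop species contributing < 1% of their family's biomass.

The thresholds are strict inequalities: a family or species at exactly
1% is kept.  The order matters (each percentage is computed on the
records surviving the previous step) and is fixed so the bases are
well-defined; the family step is pooled across fisheries by default with
a per-fishery alternative exposed in the config.

Separately, each fishery is only analyzed over the span of years in
which it was meaningfully reported: the longest contiguous run of years
whose centered 3-year rolling mean of annual landed mass stays at or
above a floor (50 kg/yr by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .biomass import to_biomass
from .trends import moving_average

REASON_LOCATION = "out_of_region"
REASON_INVALID = "invalid_measurement"
REASON_NO_ATTRIBUTES = "no_attributes"
REASON_FAMILY = "family<1%"
REASON_SPECIES = "species<1%"


@dataclass
class FilterConfig:
    family_threshold: float = 0.01  # fraction of overall biomass
    species_threshold: float = 0.01  # fraction of family biomass
    region_sectors: Sequence[str] | None = None  # None = keep every sector
    length_tolerance: float = 1.5  # x max_length before a record is an error
    strict: bool = True  # unknown species abort instead of being dropped
    family_filter_per_fishery: bool = False


@dataclass
class FilterReport:
    """Exact accounting of what the filters removed and why."""

    n_records_in: int = 0
    n_records_out: int = 0
    mass_in_kg: float = 0.0
    mass_out_kg: float = 0.0
    dropped_families: list[dict] = field(default_factory=list)
    dropped_species: list[dict] = field(default_factory=list)
    dropped_records: dict[str, dict] = field(default_factory=dict)

    @property
    def mass_dropped_kg(self) -> float:
        return sum(v["mass_kg"] for v in self.dropped_records.values())

    def to_dict(self) -> dict:
        return {
            "n_records_in": self.n_records_in,
            "n_records_out": self.n_records_out,
            "mass_in_kg": self.mass_in_kg,
            "mass_out_kg": self.mass_out_kg,
            "dropped_families": self.dropped_families,
            "dropped_species": self.dropped_species,
            "dropped_records": self.dropped_records,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def log_lines(self) -> list[str]:
        lines = [
            f"records in: {self.n_records_in} ({self.mass_in_kg:.1f} kg)",
            f"records out: {self.n_records_out} ({self.mass_out_kg:.1f} kg)",
        ]
        for reason, entry in self.dropped_records.items():
            lines.append(
                f"dropped {entry['n_records']} records [{reason}] ({entry['mass_kg']:.1f} kg)"
            )
        for entry in self.dropped_families:
            lines.append(
                f"dropped family {entry['family']} [{entry['reason']}] "
                f"({entry['n_records']} records, {entry['mass_kg']:.1f} kg, "
                f"share {100 * entry['share']:.2f}%)"
            )
        for entry in self.dropped_species:
            lines.append(
                f"dropped species {entry['species']} [{entry['reason']}] "
                f"({entry['n_records']} records, {entry['mass_kg']:.1f} kg, "
                f"family share {100 * entry['share']:.2f}%)"
            )
        return lines


def _below(share: float, threshold: float) -> bool:
    """Strictly below the threshold, with a guard against float rounding:
    a group at exactly the threshold (e.g. exactly 1%) is retained."""
    return share < threshold and not np.isclose(share, threshold, rtol=1e-9, atol=0.0)


def _record_mass(records: pd.DataFrame, attributes: pd.DataFrame) -> pd.Series:
    """Per-record biomass (kg) where computable, else 0.

    Mass needs a positive length and a known species; records failing
    either carry zero mass in the accounting (they are dropped as invalid
    or unmatched before any biomass-based filter sees them).
    """
    merged = records.merge(
        attributes[["species", "lw_a", "lw_b"]], on="species", how="left"
    )
    length = merged["fork_length_mm"].to_numpy(dtype=float)
    a = merged["lw_a"].to_numpy(dtype=float)
    b = merged["lw_b"].to_numpy(dtype=float)
    ok = np.isfinite(length) & (length > 0) & np.isfinite(a)
    mass = np.zeros(len(merged))
    mass[ok] = to_biomass(length[ok], a[ok], b[ok]) * merged["count"].to_numpy()[ok]
    return pd.Series(mass, index=records.index, name="biomass_kg")


def apply_filters(
    records: pd.DataFrame,
    attributes: pd.DataFrame,
    config: FilterConfig | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the four exclusion filters in order; returns records + report.

    The returned frame carries a ``biomass_kg`` column.  Applying the
    filters a second time to their own output changes nothing: removing a
    sub-threshold group can only raise the shares of the remainder.
    """
    if config is None:
        config = FilterConfig()
    if records.empty:
        raise ValueError("no catch records to filter")

    df = records.reset_index(drop=True).copy()
    df["biomass_kg"] = _record_mass(df, attributes)

    report = FilterReport(
        n_records_in=int(df["count"].sum()), mass_in_kg=float(df["biomass_kg"].sum())
    )

    def drop_records(mask: pd.Series, reason: str) -> None:
        nonlocal df
        if not mask.any():
            return
        dropped = df.loc[mask]
        entry = report.dropped_records.setdefault(
            reason, {"n_records": 0, "mass_kg": 0.0}
        )
        entry["n_records"] += int(dropped["count"].sum())
        entry["mass_kg"] += float(dropped["biomass_kg"].sum())
        df = df.loc[~mask]

    # (1) location
    if config.region_sectors is not None:
        drop_records(~df["sector"].isin(list(config.region_sectors)), REASON_LOCATION)

    # (2) validity
    known = set(attributes["species"])
    unknown_mask = ~df["species"].isin(known)
    if unknown_mask.any():
        if config.strict:
            missing = sorted(df.loc[unknown_mask, "species"].unique())
            raise KeyError(f"no attributes for species: {missing}")
        drop_records(unknown_mask, REASON_NO_ATTRIBUTES)
    max_len = df["species"].map(attributes.set_index("species")["max_length_mm"])
    length = df["fork_length_mm"]
    invalid = (~np.isfinite(length)) | (length <= 0) | (
        length > max_len * config.length_tolerance
    )
    drop_records(pd.Series(invalid, index=df.index), REASON_INVALID)

    if df.empty:
        report.n_records_out = 0
        return df, report

    # (3) family share of overall biomass
    if config.family_filter_per_fishery:
        group_mass = df.groupby(["fishery", "family"])["biomass_kg"].sum()
        totals = df.groupby("fishery")["biomass_kg"].sum()
        shares = group_mass / totals
        for (fishery, family), share in shares.items():
            if _below(share, config.family_threshold):
                mask = (df["fishery"] == fishery) & (df["family"] == family)
                sub = df.loc[mask]
                report.dropped_families.append(
                    {
                        "family": family,
                        "fishery": fishery,
                        "reason": REASON_FAMILY,
                        "share": float(share),
                        "n_records": int(sub["count"].sum()),
                        "mass_kg": float(sub["biomass_kg"].sum()),
                    }
                )
                df = df.loc[~mask]
    else:
        shares = df.groupby("family")["biomass_kg"].sum() / df["biomass_kg"].sum()
        for family, share in shares.items():
            if _below(share, config.family_threshold):
                mask = df["family"] == family
                sub = df.loc[mask]
                report.dropped_families.append(
                    {
                        "family": family,
                        "reason": REASON_FAMILY,
                        "share": float(share),
                        "n_records": int(sub["count"].sum()),
                        "mass_kg": float(sub["biomass_kg"].sum()),
                    }
                )
                df = df.loc[~mask]

    # (4) species share within family biomass
    family_mass = df.groupby("family")["biomass_kg"].sum()
    species_mass = df.groupby(["family", "species"])["biomass_kg"].sum()
    for (family, species), mass in species_mass.items():
        share = mass / family_mass[family]
        if _below(share, config.species_threshold):
            mask = (df["family"] == family) & (df["species"] == species)
            sub = df.loc[mask]
            report.dropped_species.append(
                {
                    "species": species,
                    "family": family,
                    "reason": REASON_SPECIES,
                    "share": float(share),
                    "n_records": int(sub["count"].sum()),
                    "mass_kg": float(sub["biomass_kg"].sum()),
                }
            )
            df = df.loc[~mask]

    df = df.reset_index(drop=True)
    report.n_records_out = int(df["count"].sum())
    report.mass_out_kg = float(df["biomass_kg"].sum())
    return df, report


def fishery_timeframe(
    records: pd.DataFrame,
    threshold_kg_per_yr: float = 50.0,
    window: int = 3,
) -> dict[str, tuple[int, int] | None]:
    """Longest run of adequately reported years, per fishery.

    Annual landed mass is smoothed with a centered rolling mean
    (truncated at the ends of the series); a year passes when its
    smoothed mass is at or above ``threshold_kg_per_yr``.  The returned
    range is the longest contiguous run of passing years (ties broken
    toward the earlier run), or None when no year passes.  Years with no
    records inside a fishery's span count as 0 kg.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if "biomass_kg" not in records.columns:
        raise ValueError("records need a biomass_kg column (run apply_filters first)")

    out: dict[str, tuple[int, int] | None] = {}
    for fishery, sub in records.groupby("fishery"):
        annual = sub.groupby("year")["biomass_kg"].sum()
        years = np.arange(annual.index.min(), annual.index.max() + 1)
        kg = annual.reindex(years, fill_value=0.0).to_numpy()
        smoothed = moving_average(kg, window=window)
        passing = smoothed >= threshold_kg_per_yr

        best: tuple[int, int] | None = None
        best_len = 0
        run_start = None
        for i, ok in enumerate(np.append(passing, False)):
            if ok and run_start is None:
                run_start = i
            elif not ok and run_start is not None:
                length = i - run_start
                if length > best_len:
                    best = (int(years[run_start]), int(years[i - 1]))
                    best_len = length
                run_start = None
        out[fishery] = best
    return out
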