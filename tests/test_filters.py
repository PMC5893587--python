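"""Exclusion filters, mass accounting, and the reporting-timeframe rule."""

import numpy as np
import pandas as pd
import pytest

from creeltrends.experiments import planted_filter_dataset
from creeltrends.filters import FilterConfig, apply_filters, fishery_timeframe


def _attrs(species_families, max_length=600):
    species, families = zip(*species_families)
    return pd.DataFrame(
        {
            "species": species,
            "family": families,
            "lw_a": [2.5e-8] * len(species),
            "lw_b": [3.0] * len(species),
            "lw_source_tier": [1] * len(species),
            "max_length_mm": [max_length] * len(species),
            "iconic": [False] * len(species),
        }
    )


def _records(rows):
    """rows: (species, family, fork_length_mm, n_records)"""
    out = []
    for species, family, length, n in rows:
        out += [
            {
                "year": 1990 + i % 5,
                "fishery": "bottom",
                "sector": "north",
                "species": species,
                "family": family,
                "fork_length_mm": length,
                "count": 1,
            }
            for i in range(n)
        ]
    return pd.DataFrame(out)


def test_subpercent_family_dropped_entirely():
    # famB biomass share 0.5% < 1% -> fully dropped
    records = _records([("a", "famA", 400, 199), ("b", "famB", 400, 1)])
    filtered, report = apply_filters(records, _attrs([("a", "famA"), ("b", "famB")]))
    assert set(filtered["family"]) == {"famA"}
    assert [e["family"] for e in report.dropped_families] == ["famB"]
    assert report.dropped_families[0]["reason"] == "family<1%"


def test_subpercent_species_dropped_within_family():
    # shares of family biomass: 98% / 1.5% / 0.5% -> only the 0.5% goes
    records = _records(
        [("big", "famA", 400, 980), ("mid", "famA", 400, 15), ("tiny", "famA", 400, 5)]
    )
    attrs = _attrs([("big", "famA"), ("mid", "famA"), ("tiny", "famA")])
    filtered, report = apply_filters(records, attrs)
    assert set(filtered["species"]) == {"big", "mid"}
    assert [e["species"] for e in report.dropped_species] == ["tiny"]


def test_exactly_one_percent_is_kept():
    """The <1% thresholds are strict: a species at exactly 1.0% stays."""
    records = _records([("big", "famA", 400, 99), ("edge", "famA", 400, 1)])
    filtered, _ = apply_filters(records, _attrs([("big", "famA"), ("edge", "famA")]))
    assert set(filtered["species"]) == {"big", "edge"}


def test_planted_invalid_records_dropped_exactly():
    records, attrs, expected = planted_filter_dataset(seed=0)
    config = FilterConfig(region_sectors=["north"], strict=True)
    filtered, report = apply_filters(records, attrs, config)
    assert (
        report.dropped_records["invalid_measurement"]["n_records"]
        == expected["n_invalid"]
    )
    assert (
        report.dropped_records["out_of_region"]["n_records"]
        == expected["n_out_of_region"]
    )
    assert [e["family"] for e in report.dropped_families] == [
        expected["dropped_family"]
    ]
    assert [e["species"] for e in report.dropped_species] == [
        expected["dropped_species"]
    ]
    assert (filtered["fork_length_mm"] > 0).all()


def test_mass_conservation_and_idempotence():
    records, attrs, _ = planted_filter_dataset(seed=4)
    config = FilterConfig(region_sectors=["north"])
    filtered, report = apply_filters(records, attrs, config)
    dropped = (
        report.mass_dropped_kg
        + sum(e["mass_kg"] for e in report.dropped_families)
        + sum(e["mass_kg"] for e in report.dropped_species)
    )
    assert report.mass_in_kg == pytest.approx(report.mass_out_kg + dropped, abs=1e-9)
    assert report.n_records_out <= report.n_records_in

    twice, second = apply_filters(filtered, attrs, config)
    pd.testing.assert_frame_equal(twice, filtered)
    assert second.n_records_in == second.n_records_out


def test_strict_mode_names_missing_species():
    records = _records([("ghost", "famA", 300, 10)])
    with pytest.raises(KeyError, match="ghost"):
        apply_filters(records, _attrs([("other", "famA")]))
    mixed = pd.concat(
        [records, _records([("other", "famA", 300, 100)])], ignore_index=True
    )
    filtered, report = apply_filters(
        mixed, _attrs([("other", "famA")]), FilterConfig(strict=False)
    )
    assert report.dropped_records["no_attributes"]["n_records"] == 10
    assert set(filtered["species"]) == {"other"}


def _timeframe_records(kg_by_year, start=1990):
    return pd.DataFrame(
        {
            "fishery": "bottom",
            "year": np.arange(start, start + len(kg_by_year)),
            "biomass_kg": kg_by_year,
        }
    )


@pytest.mark.parametrize(
    "kg,expected",
    [
        ([10.0, 10.0, 10.0], None),
        ([60.0, 60.0, 60.0, 60.0], (1990, 1993)),
        # centered means: 45,60,83.3,60,33.3,30,30,40 -> run 1991-1993
        ([10.0, 80.0, 90.0, 80.0, 10.0, 10.0, 70.0, 10.0], (1991, 1993)),
    ],
)
def test_timeframe_rolling_mean_rule(kg, expected):
    result = fishery_timeframe(_timeframe_records(kg), threshold_kg_per_yr=50.0)
    assert result["bottom"] == expected


def test_timeframe_tie_breaks_to_earlier_run():
    kg = [60.0, 60.0, 0.0, 0.0, 60.0, 60.0]
    result = fishery_timeframe(_timeframe_records(kg), threshold_kg_per_yr=50.0)
    assert result["bottom"] == (1990, 1990)  # both runs length 1 after smoothing


def test_timeframe_rejects_even_window():
    with pytest.raises(ValueError):
        fishery_timeframe(_timeframe_records([60.0] * 4), window=2)
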