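import numpy as np
import pandas as pd
import pytest

from creeltrends.simulate import EffortSchedule, PathSpec, SpeciesScenario, generate_catch


def make_scenario(
    species="sp_a",
    family="famA",
    max_length=600.0,
    contribution=None,
    size=None,
    cv=0.1,
    **kwargs,
):
    return SpeciesScenario(
        species_id=species,
        family=family,
        max_length_mm=max_length,
        lw_a=2.5e-8,
        lw_b=3.0,
        contribution_path=contribution or PathSpec("constant", 0.5),
        size_path=size or PathSpec("constant", 300.0),
        length_cv=cv,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_catch():
    """A two-species, 10-year catch table with known generating paths."""
    scenarios = [
        make_scenario("sp_a", contribution=PathSpec("linear", 0.8, -0.6)),
        make_scenario("sp_b", contribution=PathSpec("linear", 0.2, 0.6),
                      size=PathSpec("linear", 350.0, -100.0)),
    ]
    effort = EffortSchedule(1990, 1999, annual_n_fish=400, seed=11)
    return scenarios, effort, generate_catch(scenarios, effort, fishery="bottom")


def records_frame(rows):
    """Build a catch-record frame (with biomass) from compact tuples:
    (year, fishery, species, family, fork_length_mm, biomass_kg)."""
    df = pd.DataFrame(
        rows, columns=["year", "fishery", "species", "family", "fork_length_mm", "biomass_kg"]
    )
    df["sector"] = "north"
    df["count"] = 1
    return df
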