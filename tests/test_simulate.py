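"""Generator contracts: determinism, trajectory fidelity, truth tables."""

import numpy as np
import pandas as pd
import pytest

from creeltrends.simulate import (
    EffortSchedule,
    PathSpec,
    SpeciesScenario,
    attributes_table,
    generate_catch,
    scenario_truth,
    scenarios_from_yaml,
    scenarios_to_yaml,
)

from conftest import make_scenario


def test_degenerate_noise_yields_constant_lengths():
    scen = make_scenario(contribution=PathSpec("constant", 1.0), cv=0.003)
    effort = EffortSchedule(1990, 1999, annual_n_fish=100, seed=3)
    records = generate_catch([scen], effort, "bottom")
    assert records["species"].nunique() == 1
    assert records["fork_length_mm"].between(295, 305).all()
    assert (records["count"] == 1).all()
    # Poisson totals around 100/yr over 10 yr
    assert 800 < len(records) < 1200


def test_same_seed_identical_tables(small_catch):
    scenarios, effort, records = small_catch
    again = generate_catch(scenarios, effort, "bottom")
    pd.testing.assert_frame_equal(records, again)
    assert records.to_csv() == again.to_csv()


def test_crossing_contribution_paths_tracked(small_catch):
    """Realized annual species proportions stay in the binomial envelope
    of the generating multinomial probabilities."""
    scenarios, effort, records = small_catch
    n_years = len(effort.years)
    pa = scenarios[0].contribution_path.values(n_years)
    pb = scenarios[1].contribution_path.values(n_years)
    probs = pa / (pa + pb)
    for i, year in enumerate(effort.years):
        sub = records.loc[records["year"] == year]
        n = len(sub)
        share = (sub["species"] == "sp_a").mean()
        se = np.sqrt(probs[i] * (1 - probs[i]) / n)
        assert abs(share - probs[i]) < 3.5 * se


def test_lengths_follow_size_path(small_catch):
    scenarios, effort, records = small_catch
    means = scenarios[1].size_path.values(len(effort.years))
    for i, year in enumerate(effort.years):
        lengths = records.loc[
            (records["year"] == year) & (records["species"] == "sp_b"),
            "fork_length_mm",
        ]
        if len(lengths) < 10:
            continue
        se = means[i] * scenarios[1].length_cv / np.sqrt(len(lengths))
        assert abs(lengths.mean() - means[i]) < 4 * se


def test_annual_totals_unbiased_over_replicates():
    """Mean realized fish count per year ~ expectation over 200 seeds."""
    scen = make_scenario(contribution=PathSpec("constant", 1.0))
    totals = []
    for seed in range(200):
        effort = EffortSchedule(1990, 1993, annual_n_fish=50, seed=seed)
        totals.append(len(generate_catch([scen], effort, "bottom")))
    mean_per_year = np.mean(totals) / 4
    se = np.std(totals, ddof=1) / np.sqrt(200) / 4
    assert abs(mean_per_year - 50) < 3 * se


def test_lengths_respect_support(small_catch):
    _, _, records = small_catch
    assert (records["fork_length_mm"] > 0).all()
    assert (records["fork_length_mm"] <= 600).all()


@pytest.mark.parametrize(
    "form,start,net,expected_net",
    [
        ("constant", 5.0, 0.0, 0.0),
        ("linear", 350.0, -100.0, -100.0),
        ("exponential", 10.0, -6.0, -6.0),
    ],
)
def test_scenario_truth_net_change(form, start, net, expected_net):
    scen = make_scenario(size=PathSpec(form, start, net))
    effort = EffortSchedule(1990, 1999)
    truth = scenario_truth([scen], effort)
    row = truth.loc[truth["variable"] == "size"].iloc[0]
    assert row["form"] == form
    assert row["net_change"] == pytest.approx(expected_net, abs=1e-12)


def test_humped_truth_is_endpoint_difference():
    """The hump amplitude cancels at the endpoints; net change is the
    linear component of the quadratic path."""
    path = PathSpec("humped", 20.0, 6.0, hump=9.0)
    scen = make_scenario(contribution=PathSpec("constant", 1.0), size=path)
    truth = scenario_truth([scen], EffortSchedule(1990, 1999))
    row = truth.loc[truth["variable"] == "size"].iloc[0]
    vals = path.values(10)
    assert row["net_change"] == pytest.approx(vals[-1] - vals[0])
    assert row["net_change"] == pytest.approx(6.0)
    assert vals.max() > vals[0] + 6.0  # the hump actually rises mid-series


def test_generator_input_validation():
    effort = EffortSchedule(1990, 1999)
    with pytest.raises(ValueError):
        generate_catch([], effort, "bottom")
    with pytest.raises(ValueError, match="4 years"):
        generate_catch([make_scenario()], EffortSchedule(1990, 1991), "bottom")
    bad = make_scenario(contribution=PathSpec("linear", 0.2, -0.9))
    with pytest.raises(ValueError, match="sp_a"):
        generate_catch([bad], effort, "bottom")
    with pytest.raises(ValueError):
        SpeciesScenario(
            species_id="x", family="f", max_length_mm=500, lw_a=1e-8, lw_b=4.0,
            contribution_path=PathSpec("constant", 1.0),
            size_path=PathSpec("constant", 300.0),
        )


def test_scenario_yaml_roundtrip(tmp_path, small_catch):
    scenarios, effort, records = small_catch
    path = tmp_path / "scen.yaml"
    scenarios_to_yaml(scenarios, effort, path)
    loaded, effort2 = scenarios_from_yaml(path)
    assert loaded == scenarios
    assert effort2 == effort
    pd.testing.assert_frame_equal(
        generate_catch(loaded, effort2, "bottom"), records
    )


def test_attributes_table_schema(small_catch):
    scenarios, _, _ = small_catch
    attrs = attributes_table(scenarios)
    assert list(attrs["species"]) == ["sp_a", "sp_b"]
    assert (attrs["lw_source_tier"] == 1).all()
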