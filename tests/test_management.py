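"""The four-criterion management classifier: examples, exhaustiveness,
monotonicity and symmetry."""

import itertools

import pytest

from creeltrends.management import (
    CATEGORY_BOTH,
    CATEGORY_GEAR,
    CATEGORY_NONE,
    CATEGORY_SIZE,
    classify,
    summarize,
)
from creeltrends.trends import ModelFit


def make_fit(
    form="linear",
    net=-1.0,
    deriv=None,
    effect=0.5,
    effect_se=0.05,
):
    """A selected (significant) fit with controllable decline geometry."""
    if deriv is None:
        deriv = -1.0 if net < 0 else 1.0
    return ModelFit(
        form=form, params={}, bse={}, r2=0.6, p_value=0.001, aic=10.0,
        shapiro_p=0.5, dw=2.0, n=20, net_change=net, net_change_pct=net,
        derivative_start=deriv,
        std_slope=-effect if net < 0 else effect, std_slope_se=effect_se,
        selected=True,
    )


def test_lone_size_decline_yields_size_policy():
    a = classify(make_fit("exponential", net=-5.0), None)
    assert a.category == CATEGORY_SIZE and a.rationale == 1


def test_lone_contribution_decline_yields_gear_policy():
    a = classify(None, make_fit("linear", net=-3.0))
    assert a.category == CATEGORY_GEAR and a.rationale == 1


def test_curved_immediate_decline_beats_linear():
    size = make_fit("quadratic", net=-2.0, deriv=-0.8)
    contrib = make_fit("linear", net=-4.0)
    a = classify(size, contrib)
    assert a.category == CATEGORY_SIZE and a.rationale == 1


def test_humped_rising_quadratic_is_not_immediate_decline():
    """A quadratic that rises before falling counts as weak, so a linear
    decline in the other variable ties on strength and goes to effects."""
    size = make_fit("quadratic", net=-2.0, deriv=+0.5, effect=0.9, effect_se=0.02)
    contrib = make_fit("linear", net=-4.0, effect=0.3, effect_se=0.02)
    a = classify(size, contrib)
    assert a.rationale == 2 and a.category == CATEGORY_SIZE


def test_overlapping_effects_mean_both_either():
    size = make_fit(effect=0.50, effect_se=0.05)
    contrib = make_fit(effect=0.48, effect_se=0.06)
    a = classify(size, contrib)
    assert a.category == CATEGORY_BOTH and a.rationale == 3


def test_separated_effects_pick_larger_magnitude():
    size = make_fit(effect=0.30, effect_se=0.02)
    contrib = make_fit(effect=0.80, effect_se=0.02)
    a = classify(size, contrib)
    assert a.category == CATEGORY_GEAR and a.rationale == 2


def test_increases_place_no_species():
    a = classify(make_fit(net=+2.0), make_fit(net=+5.0))
    assert a.category == CATEGORY_NONE and a.rationale == 4
    assert classify(None, None).category == CATEGORY_NONE


def test_increase_does_not_block_the_declining_variable():
    a = classify(make_fit(net=+2.0), make_fit(net=-2.0))
    assert a.category == CATEGORY_GEAR


FIT_KINDS = ("absent", "linear_decline", "curved_decline", "humped_late_decline",
             "increase", "flat")


def _fit_of_kind(kind):
    if kind == "absent":
        return None
    if kind == "linear_decline":
        return make_fit("linear", net=-2.0)
    if kind == "curved_decline":
        return make_fit("exponential", net=-2.0, deriv=-1.0)
    if kind == "humped_late_decline":
        return make_fit("quadratic", net=-2.0, deriv=+0.5)
    if kind == "increase":
        return make_fit("linear", net=+2.0)
    return make_fit("linear", net=0.0, deriv=0.0)  # flat


def test_every_fit_combination_maps_to_exactly_one_category():
    """Exhaustive enumeration: each (size, contribution) state pair lands
    in exactly one category, and 'none' exactly when nothing declines."""
    categories = {CATEGORY_SIZE, CATEGORY_GEAR, CATEGORY_BOTH, CATEGORY_NONE}
    declining_kinds = {"linear_decline", "curved_decline", "humped_late_decline"}
    for s_kind, c_kind in itertools.product(FIT_KINDS, FIT_KINDS):
        a = classify(_fit_of_kind(s_kind), _fit_of_kind(c_kind))
        assert a.category in categories
        any_decline = s_kind in declining_kinds or c_kind in declining_kinds
        assert (a.category == CATEGORY_NONE) == (not any_decline)
        assert (a.rationale == 4) == (a.category == CATEGORY_NONE)


def test_strengthening_size_decline_never_flips_to_gear():
    contrib = make_fit(effect=0.5, effect_se=0.03)
    last_rank = 0
    rank = {CATEGORY_GEAR: 0, CATEGORY_BOTH: 1, CATEGORY_SIZE: 2}
    for effect in (0.2, 0.4, 0.5, 0.6, 0.9):
        a = classify(make_fit(effect=effect, effect_se=0.03), contrib)
        assert rank[a.category] >= last_rank
        last_rank = rank[a.category]


@pytest.mark.parametrize(
    "size_kind,contrib_kind",
    list(itertools.product(FIT_KINDS, FIT_KINDS)),
)
def test_swapping_variables_swaps_categories(size_kind, contrib_kind):
    swap = {CATEGORY_SIZE: CATEGORY_GEAR, CATEGORY_GEAR: CATEGORY_SIZE,
            CATEGORY_BOTH: CATEGORY_BOTH, CATEGORY_NONE: CATEGORY_NONE}
    a = classify(_fit_of_kind(size_kind), _fit_of_kind(contrib_kind))
    b = classify(_fit_of_kind(contrib_kind), _fit_of_kind(size_kind))
    assert b.category == swap[a.category]


def test_summarize_arithmetic():
    assignments = (
        [classify(make_fit(), None, species=f"s{i}", fishery="bottom") for i in range(5)]
        + [classify(None, make_fit(), species=f"g{i}", fishery="bottom") for i in range(3)]
        + [classify(make_fit(effect=0.5, effect_se=0.1),
                    make_fit(effect=0.5, effect_se=0.1),
                    species="b0", fishery="bottom")]
        + [classify(None, None, species="n0", fishery="bottom")]
    )
    summary = summarize(assignments)
    overall = summary["overall"]
    assert overall["n_assessed"] == 10 and overall["n_placed"] == 9
    assert overall["placed_fraction"] == pytest.approx(0.9)
    props = overall["placed_proportions"]
    assert props[CATEGORY_SIZE] == pytest.approx(5 / 9)
    assert props[CATEGORY_GEAR] == pytest.approx(3 / 9)
    assert props[CATEGORY_BOTH] == pytest.approx(1 / 9)


def test_cross_fishery_consistency_reported():
    a = classify(make_fit(), None, species="shared", fishery="bottom")
    b = classify(make_fit(), None, species="shared", fishery="SCUBA")
    summary = summarize([a, b])
    assert summary["cross_fishery"] == [
        {
            "species": "shared",
            "fisheries": ["SCUBA", "bottom"],
            "categories": [CATEGORY_SIZE, CATEGORY_SIZE],
            "consistent": True,
        }
    ]
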