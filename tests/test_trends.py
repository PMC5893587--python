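"""Series construction, smoothing, weighted fits and model selection."""

import numpy as np
import pandas as pd
import pytest

from creeltrends.experiments import _series_from_xy
from creeltrends.trends import (
    ModelFit,
    TrendSeries,
    build_series,
    equation_string,
    fit_candidates,
    moving_average,
    p_stars,
    select_model,
)

from conftest import records_frame


# ---------------------------------------------------------------------------
# moving average


def test_moving_average_truncated_ends():
    np.testing.assert_allclose(moving_average([1, 2, 3, 4]), [1.5, 2, 3, 3.5])


def test_moving_average_identity_and_constant():
    np.testing.assert_allclose(moving_average([5.0, 5.0, 5.0]), [5.0, 5.0, 5.0])
    np.testing.assert_allclose(moving_average([3.0, 1.0, 4.0], window=1), [3.0, 1.0, 4.0])


def test_moving_average_skips_nan():
    out = moving_average([1.0, np.nan, 3.0])
    np.testing.assert_allclose(out, [1.0, 2.0, 3.0])


def test_moving_average_input_validation():
    with pytest.raises(ValueError):
        moving_average([])
    with pytest.raises(ValueError):
        moving_average([1.0, 2.0], window=2)


# ---------------------------------------------------------------------------
# candidate fits


def test_noiseless_linear_recovered_exactly():
    x = np.arange(1, 11, dtype=float)
    fits = {f.form: f for f in fit_candidates(_series_from_xy(2 * x + 1))}
    lin = fits["linear"]
    assert lin.params["slope"] == pytest.approx(2.0, abs=1e-10)
    assert lin.params["intercept"] == pytest.approx(1.0, abs=1e-10)
    assert lin.r2 == pytest.approx(1.0)
    assert lin.net_change == pytest.approx(18.0, abs=1e-9)


def test_equal_weights_match_ols():
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    y = 10 + rng.normal(0, 1, 12)
    x = np.arange(1, 13, dtype=float)
    weighted = fit_candidates(_series_from_xy(y, np.full(12, 9.9)))
    for fit in weighted:
        yy = np.log(y) if fit.form in ("exponential", "power") else y
        X = sm.add_constant(
            np.log(x) if fit.form == "power"
            else np.column_stack([x, x**2]) if fit.form == "quadratic"
            else x
        )
        ols = sm.OLS(yy, X).fit()
        np.testing.assert_allclose(
            list(fit.params.values()), ols.params, atol=1e-10
        )


def test_log_forms_skipped_for_nonpositive_response():
    y = np.array([3.0, 1.0, -0.5, 2.0, 4.0, 3.0])
    forms = {f.form for f in fit_candidates(_series_from_xy(y))}
    assert forms == {"linear", "quadratic"}


def test_short_series_unfittable():
    s = _series_from_xy(np.array([1.0, 2.0, 3.0]))
    assert not s.fittable
    with pytest.raises(ValueError, match="usable years"):
        fit_candidates(s)


def test_weight_monotonicity():
    """Inflating one year's weight pulls the fit toward that point."""
    rng = np.random.default_rng(5)
    y = 10 + 0.5 * np.arange(1, 13) + rng.normal(0, 2, 12)
    base = next(f for f in fit_candidates(_series_from_xy(y)) if f.form == "linear")
    w = np.ones(12)
    w[4] = 50.0
    heavy = next(
        f for f in fit_candidates(_series_from_xy(y, w)) if f.form == "linear"
    )
    x = np.arange(1, 13, dtype=float)
    resid = lambda fit: abs(
        y[4] - (fit.params["intercept"] + fit.params["slope"] * x[4])
    )
    assert resid(heavy) <= resid(base) + 1e-12


def test_aic_prefers_true_scale():
    """Exponential-mean data rank the log family below the linear fit in
    (cross-scale) AIC for nearly all replicates, and vice versa."""
    rng = np.random.default_rng(9)
    x = np.arange(1, 21, dtype=float)
    wins = 0
    n_rep = 50
    for _ in range(n_rep):
        y = np.exp(0.15 * x + rng.normal(0, 0.2, 20))
        fits = {f.form: f for f in fit_candidates(_series_from_xy(y))}
        if fits["exponential"].aic < fits["linear"].aic:
            wins += 1
    assert wins >= 0.9 * n_rep


def test_saturating_curve_selects_log_family():
    from creeltrends.experiments import saturating_selection

    result = saturating_selection(n_reps=200, seed=1)
    assert result["log_family_selection_rate"] >= 0.80


# ---------------------------------------------------------------------------
# selection rule


def _fit(form="linear", p=0.01, shapiro=0.5, aic=10.0, dw=2.0, net=-1.0, deriv=-1.0):
    return ModelFit(
        form=form, params={}, bse={}, r2=0.5, p_value=p, aic=aic,
        shapiro_p=shapiro, dw=dw, n=20, net_change=net, net_change_pct=-10.0,
        derivative_start=deriv, std_slope=-0.5, std_slope_se=0.1,
    )


def test_only_significant_fit_wins():
    fits = [_fit("linear", p=0.01), _fit("quadratic", p=0.4, aic=5.0)]
    assert select_model(fits).form == "linear"


def test_normality_gate_overrides_aic():
    fits = [_fit("linear", aic=12.0), _fit("quadratic", aic=5.0, shapiro=0.01)]
    assert select_model(fits).form == "linear"


def test_no_significant_model_returns_none():
    assert select_model([_fit(p=0.2), _fit("quadratic", p=0.9)]) is None


def test_normality_violation_flagged_when_unavoidable():
    fits = [_fit("linear", shapiro=0.01), _fit("quadratic", shapiro=0.02, aic=20.0)]
    best = select_model(fits)
    assert best.form == "linear"
    assert "normality_violated" in best.flags


def test_autocorrelation_flagged_not_vetoed():
    best = select_model([_fit("linear", dw=0.5)])
    assert best is not None and "autocorrelated" in best.flags


def test_equation_rendering():
    quad = _fit("quadratic")
    quad.params = {"intercept": 24.7, "slope": -1.1, "quad": 0.03}
    assert equation_string(quad) == "y = -1.1x + 0.03x2 + 24.7"
    power = _fit("power")
    power.params = {"intercept": 2.5, "slope": -0.6}
    assert equation_string(power) == "log(y) = -0.6 log(x) + 2.5"
    assert p_stars(0.0004) == "***" and p_stars(0.03) == "*" and p_stars(0.2) == ""


# ---------------------------------------------------------------------------
# series construction


def _multi_family_records():
    rows = []
    for year in range(1990, 1998):
        # famA dominant (~60%), famB dominant (~30%), famC minor (~10%)
        rows += [
            (year, "bottom", "a1", "famA", 400, 6.0),
            (year, "bottom", "b1", "famB", 300, 3.0),
            (year, "bottom", "c1", "famC", 200, 1.0),
        ]
    return records_frame(rows)


def _attrs_for(records, iconic=()):
    species = records[["species", "family"]].drop_duplicates()
    return pd.DataFrame(
        {
            "species": species["species"],
            "family": species["family"],
            "lw_a": 2.5e-8,
            "lw_b": 3.0,
            "lw_source_tier": 1,
            "max_length_mm": 600,
            "iconic": species["species"].isin(iconic),
        }
    ).reset_index(drop=True)


def test_single_family_series_constant_100():
    rows = [(y, "bottom", "a1", "famA", 400, 5.0) for y in range(1990, 1996)]
    records = records_frame(rows)
    series = build_series(records, _attrs_for(records), {})
    fam = next(s for s in series if s.unit == "family_pct")
    np.testing.assert_allclose(fam.raw_values, 100.0)
    np.testing.assert_allclose(fam.smoothed_values, 100.0)


def test_dominant_family_and_weight_assignment():
    records = _multi_family_records()
    series = {(s.unit, s.group): s for s in build_series(records, _attrs_for(records), {})}
    assert ("family_pct", "famA") in series and ("family_pct", "famB") in series
    assert ("family_pct", "famC") not in series  # 10% is not > 10%
    np.testing.assert_allclose(series[("family_pct", "famA")].raw_values, 60.0)
    # percent series weighted by total kg; size series by fish count
    np.testing.assert_allclose(series[("family_pct", "famA")].weights, 10.0)
    other = series[("mean_size_mm", "other fishes")]
    np.testing.assert_allclose(other.raw_values, 200.0)
    np.testing.assert_allclose(other.weights, 1.0)
    # family percentages (dominant + other) sum to 100 before smoothing
    total = sum(
        series[k].raw_values
        for k in [("family_pct", "famA"), ("family_pct", "famB"), ("other_pct", "other fishes")]
    )
    np.testing.assert_allclose(total, 100.0)


def test_seventy_percent_coverage_rule():
    """Species at 40/25/10/9/8/8% of biomass -> the top three reach 70%."""
    shares = {"s1": 40.0, "s2": 25.0, "s3": 10.0, "s4": 9.0, "s5": 8.0, "s6": 8.0}
    rows = []
    for year in range(1990, 1996):
        for sp, share in shares.items():
            rows.append((year, "bottom", sp, "famA", 300, share))
    records = records_frame(rows)
    series = build_series(
        records, _attrs_for(records), {}, min_fish=1
    )
    picked = {s.group for s in series if s.unit == "species_pct"}
    assert picked == {"s1", "s2", "s3"}


def test_min_fish_requirement_drops_sparse_species():
    rows = []
    for year in range(1990, 1996):
        rows += [(year, "bottom", "common", "famA", 300, 5.0)] * 10
        rows.append((year, "bottom", "sparse", "famA", 600, 40.0))
    records = records_frame(rows)
    series = build_series(records, _attrs_for(records), {}, min_fish=50)
    picked = {s.group for s in series if s.unit == "species_pct"}
    assert "sparse" not in picked and "common" in picked


def test_iconic_series_emitted():
    records = _multi_family_records()
    attrs = _attrs_for(records, iconic=("b1",))
    series = {s.unit: s for s in build_series(records, attrs, {})}
    np.testing.assert_allclose(series["iconic_pct"].raw_values, 30.0)


def test_planted_decline_tracked_by_species_series(small_catch):
    """A generated linear contribution decline shows up in the raw series
    within the multinomial sampling envelope."""
    from creeltrends.biomass import add_biomass
    from creeltrends.simulate import attributes_table

    scenarios, effort, records = small_catch
    attrs = attributes_table(scenarios)
    withmass = add_biomass(records, attrs)
    series = build_series(
        withmass, attrs, {}, species_coverage=1.0, min_fish=10
    )
    pct = next(
        s for s in series if s.unit == "species_pct" and s.group == "sp_a"
    )
    fit = select_model(fit_candidates(pct))
    assert fit is not None
    assert fit.net_change < 0  # generating path declines 0.8 -> 0.2
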