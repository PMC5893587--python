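"""Validation experiments for the pipeline, with independent oracles.

Each function here sets up a controlled problem with known truth and
measures how the pipeline behaves on it:

* natural-breaks classification against an exhaustive-search oracle;
* weighted-least-squares degeneracy checks (equal weights = OLS,
  noiseless data recovered exactly);
* coefficient recovery and model-selection consistency for a humped
  (quadratic) contribution trajectory under Gaussian noise;
* false-positive (type-I) rate of the selection rule on trendless series;
* end-to-end management-classification recovery on a synthetic cohort
  with a planted mix of decline scenarios.

All randomness flows through an explicit seed so every experiment is
exactly repeatable.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .filters import FilterConfig, apply_filters, fishery_timeframe
from .management import CATEGORY_BOTH, CATEGORY_GEAR, CATEGORY_NONE, CATEGORY_SIZE, classify
from .simulate import EffortSchedule, PathSpec, SpeciesScenario, generate_catch
from .sizeclass import jenks_breaks
from .trends import FORMS, TrendSeries, fit_candidates, select_model


# ---------------------------------------------------------------------------
# natural-breaks oracle


def brute_force_min_ssd(values: np.ndarray, k: int) -> float:
    """Exhaustive minimum within-class SSD over all ordered partitions.

    Enumerates every placement of k-1 split points between sorted values
    — the oracle the dynamic program must match.  Only viable for small
    n (the enumeration is C(n-1, k-1)).
    """
    vals = np.sort(np.asarray(values, dtype=float))
    n = len(vals)

    def ssd(chunk: np.ndarray) -> float:
        return float(np.sum((chunk - chunk.mean()) ** 2))

    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        total = sum(ssd(vals[bounds[i] : bounds[i + 1]]) for i in range(k))
        best = min(best, total)
    return best


def jenks_vs_bruteforce(
    n_instances: int = 500, seed: int = 0, max_n: int = 12
) -> dict:
    """Compare the DP optimum with exhaustive search on random instances.

    Returns the agreement count and the largest absolute SSD discrepancy
    observed (0 when the DP is exact everywhere).
    """
    rng = np.random.default_rng(seed)
    agree = 0
    worst = 0.0
    for _ in range(n_instances):
        k = int(rng.integers(2, 4))
        n = int(rng.integers(k, max_n + 1))
        values = rng.uniform(50, 2000, size=n)
        _, assignment, _ = jenks_breaks(values, k)
        within = 0.0
        for cls in range(1, k + 1):
            chunk = values[assignment == cls]
            within += float(np.sum((chunk - chunk.mean()) ** 2))
        oracle = brute_force_min_ssd(values, k)
        diff = abs(within - oracle)
        worst = max(worst, diff)
        if diff <= 1e-8 * max(1.0, oracle):
            agree += 1
    return {"n_instances": n_instances, "n_agree": agree, "max_abs_diff": worst}


# ---------------------------------------------------------------------------
# weighted-least-squares sanity


def _series_from_xy(y: np.ndarray, w: np.ndarray | None = None) -> TrendSeries:
    """Wrap plain (x=1..n, y) values as an unsmoothed TrendSeries."""
    n = len(y)
    if w is None:
        w = np.ones(n)
    return TrendSeries.from_raw(
        "synthetic", "value", "series", np.arange(2000, 2000 + n), y, w, window=1
    )


def wls_degeneracy_check(seed: int = 0, n: int = 20) -> dict:
    """Equal-weight WLS must equal OLS; noiseless data must fit exactly.

    Returns the largest coefficient discrepancy between the two routes
    and the largest coefficient error on a noiseless quadratic.
    """
    rng = np.random.default_rng(seed)
    x = np.arange(1, n + 1, dtype=float)
    y = 5.0 + 0.7 * x + rng.normal(0, 2.0, n)

    series = _series_from_xy(y, np.full(n, 3.7))  # any constant weight
    fits = {f.form: f for f in fit_candidates(series)}
    max_diff = 0.0
    for form in FORMS:
        if form not in fits:
            continue
        yfit = np.log(y) if form in ("exponential", "power") else y
        X = sm.add_constant(
            np.log(x) if form == "power"
            else np.column_stack([x, x**2]) if form == "quadratic"
            else x
        )
        ols = sm.OLS(yfit, X).fit()
        ours = np.array(list(fits[form].params.values()))
        max_diff = max(max_diff, float(np.max(np.abs(ours - ols.params))))

    exact = 24.7 - 1.1 * x + 0.03 * x**2
    quad = {f.form: f for f in fit_candidates(_series_from_xy(exact))}["quadratic"]
    est = np.array([quad.params["intercept"], quad.params["slope"], quad.params["quad"]])
    exact_err = float(np.max(np.abs(est - np.array([24.7, -1.1, 0.03]))))
    return {"equal_weight_max_coef_diff": max_diff, "noiseless_quadratic_max_err": exact_err}


# ---------------------------------------------------------------------------
# parameter recovery and selection consistency

#: humped percent-contribution trajectory used for the recovery study:
#: y = 24.7 - 1.1 x + 0.03 x^2 (intercept, slope, curvature on the
#: year-index scale), the kind of early-decline-late-flattening path a
#: heavily targeted snapper group follows.
RECOVERY_TRUTH = {"intercept": 24.7, "slope": -1.1, "quad": 0.03}


def quadratic_recovery(
    n_reps: int = 500, seed: int = 0, n_years: int = 20, sigma: float = 2.0
) -> dict:
    """Coefficient recovery + selection rate for the humped trajectory.

    Each replicate draws y_t = 24.7 - 1.1 t + 0.03 t^2 + N(0, sigma) for
    t = 1..n_years, fits all candidates with equal weights and records
    the quadratic fit's coefficients and which form the selection rule
    chose.
    """
    rng = np.random.default_rng(seed)
    x = np.arange(1, n_years + 1, dtype=float)
    truth_y = (
        RECOVERY_TRUTH["intercept"]
        + RECOVERY_TRUTH["slope"] * x
        + RECOVERY_TRUTH["quad"] * x**2
    )
    estimates = []
    n_quadratic = 0
    for _ in range(n_reps):
        y = truth_y + rng.normal(0, sigma, n_years)
        fits = fit_candidates(_series_from_xy(y))
        quad = next(f for f in fits if f.form == "quadratic")
        estimates.append(
            [quad.params["intercept"], quad.params["slope"], quad.params["quad"]]
        )
        best = select_model(fits)
        if best is not None and best.form == "quadratic":
            n_quadratic += 1
    est = np.array(estimates)
    mean = est.mean(axis=0)
    mc_se = est.std(axis=0, ddof=1) / np.sqrt(n_reps)
    names = ["intercept", "slope", "quad"]
    return {
        "n_reps": n_reps,
        "truth": dict(RECOVERY_TRUTH),
        "mean": dict(zip(names, mean)),
        "mc_se": dict(zip(names, mc_se)),
        "z": dict(
            zip(names, (mean - np.array(list(RECOVERY_TRUTH.values()))) / mc_se)
        ),
        "quadratic_selection_rate": n_quadratic / n_reps,
    }


def saturating_selection(
    n_reps: int = 200, seed: int = 0, n_years: int = 20, sigma_log: float = 0.1
) -> dict:
    """How often a saturating decline is assigned to the log-model family.

    Data follow y = exp(2.5 - 0.6 log x) with multiplicative noise — a
    steep early drop that levels off; the exponential/power family
    should win selection for most replicates.
    """
    rng = np.random.default_rng(seed)
    x = np.arange(1, n_years + 1, dtype=float)
    log_mu = 2.5 - 0.6 * np.log(x)
    n_logfam = 0
    for _ in range(n_reps):
        y = np.exp(log_mu + rng.normal(0, sigma_log, n_years))
        best = select_model(fit_candidates(_series_from_xy(y)))
        if best is not None and best.form in ("exponential", "power"):
            n_logfam += 1
    return {"n_reps": n_reps, "log_family_selection_rate": n_logfam / n_reps}


def type1_rate(
    n_reps: int = 200, seed: int = 0, n_years: int = 20,
    mean: float = 20.0, sigma: float = 2.0, alpha: float = 0.05,
) -> dict:
    """Selected-model rate on trendless noise (the false-positive rate).

    Four correlated candidates are each tested at ``alpha``, so the
    family-wise rate is expected at or slightly above the nominal level.
    """
    rng = np.random.default_rng(seed)
    n_selected = 0
    for _ in range(n_reps):
        y = rng.normal(mean, sigma, n_years)
        if select_model(fit_candidates(_series_from_xy(y)), alpha=alpha) is not None:
            n_selected += 1
    rate = n_selected / n_reps
    return {
        "n_reps": n_reps,
        "alpha": alpha,
        "selected_rate": rate,
        "binomial_se": float(np.sqrt(alpha * (1 - alpha) / n_reps)),
    }


# ---------------------------------------------------------------------------
# end-to-end classification recovery

SCENARIO_MIX = {
    "size_decline": 0.40,
    "contribution_decline": 0.20,
    "both_equal": 0.10,
    "stable": 0.30,
}

#: planted category per scenario kind
EXPECTED_CATEGORY = {
    "size_decline": CATEGORY_SIZE,
    "contribution_decline": CATEGORY_GEAR,
    "both_equal": CATEGORY_BOTH,
    "stable": CATEGORY_NONE,
}


def classification_cohort(
    seed: int = 0,
    n_species: int = 40,
    n_years: int = 20,
    annual_n_fish: float = 4000.0,
    length_cv: float = 0.15,
) -> tuple[list[SpeciesScenario], EffortSchedule, dict[str, str]]:
    """A cohort with a planted mix of decline scenarios.

    40% of species decline only in mean size, 20% only in contribution,
    10% in both with matched effect magnitudes, and 30% are stable.
    Species are spread over four families of similar landings so the
    record filters leave the cohort intact.  Declines are substantial
    (size -20%, contribution -50% over the series) against moderate
    sampling noise: roughly 100 measured fish per species-year with a
    15% length CV.
    """
    kinds = []
    for kind, frac in SCENARIO_MIX.items():
        kinds += [kind] * round(n_species * frac)
    assert len(kinds) == n_species
    families = [f"family_{i}" for i in range(4)]
    scenarios = []
    truth: dict[str, str] = {}
    base_share = 1.0 / n_species
    for i, kind in enumerate(kinds):
        species = f"sp_{i:02d}"
        truth[species] = kind
        size0 = 250.0 + 10.0 * (i % 8)  # spread sizes; exact values immaterial
        if kind == "size_decline":
            cpath = PathSpec("constant", base_share)
            spath = PathSpec("linear", size0, -0.20 * size0)
        elif kind == "contribution_decline":
            cpath = PathSpec("linear", base_share, -0.50 * base_share)
            spath = PathSpec("constant", size0)
        elif kind == "both_equal":
            cpath = PathSpec("linear", base_share, -0.50 * base_share)
            spath = PathSpec("linear", size0, -0.20 * size0)
        else:
            cpath = PathSpec("constant", base_share)
            spath = PathSpec("constant", size0)
        scenarios.append(
            SpeciesScenario(
                species_id=species,
                family=families[i % 4],
                max_length_mm=size0 * 1.8,
                lw_a=2.5e-8,
                lw_b=3.0,
                contribution_path=cpath,
                size_path=spath,
                length_cv=length_cv,
            )
        )
    effort = EffortSchedule(1990, 1990 + n_years - 1, annual_n_fish, seed=seed)
    return scenarios, effort, truth


def classification_recovery(seed: int = 0, **cohort_kwargs) -> dict:
    """Generate the planted cohort, run the full pipeline, score recovery.

    Every species is assessed (coverage 100%), each gets its size and
    contribution trend fitted and selected, and the four-criterion rule
    assigns a category; recovered per-category counts are compared with
    the planted mix.
    """
    from .biomass import add_biomass
    from .simulate import attributes_table
    from .trends import build_series

    scenarios, effort, truth = classification_cohort(seed=seed, **cohort_kwargs)
    records = generate_catch(scenarios, effort, fishery="spear")
    attributes = attributes_table(scenarios)
    records = add_biomass(records, attributes)
    series = build_series(
        records, attributes, classifications={},
        species_coverage=1.0, min_fish=50,
    )
    by_species: dict[str, dict[str, TrendSeries]] = {}
    for s in series:
        if s.unit in ("species_pct", "species_size_mm"):
            by_species.setdefault(s.group, {})[s.unit] = s

    recovered: dict[str, str] = {}
    for species, pair in by_species.items():
        size_fit = contrib_fit = None
        if "species_size_mm" in pair and pair["species_size_mm"].fittable:
            size_fit = select_model(fit_candidates(pair["species_size_mm"]))
        if "species_pct" in pair and pair["species_pct"].fittable:
            contrib_fit = select_model(fit_candidates(pair["species_pct"]))
        recovered[species] = classify(size_fit, contrib_fit, species=species).category

    n = len(truth)
    planted_counts = {
        cat: sum(EXPECTED_CATEGORY[k] == cat for k in truth.values())
        for cat in EXPECTED_CATEGORY.values()
    }
    recovered_counts = {
        cat: sum(v == cat for v in recovered.values())
        for cat in EXPECTED_CATEGORY.values()
    }
    correct = sum(
        recovered.get(sp) == EXPECTED_CATEGORY[kind] for sp, kind in truth.items()
    )
    return {
        "n_species": n,
        "planted_counts": planted_counts,
        "recovered_counts": recovered_counts,
        "accuracy": correct / n,
        "per_species": {
            sp: {"planted": EXPECTED_CATEGORY[kind], "recovered": recovered.get(sp)}
            for sp, kind in truth.items()
        },
    }


# ---------------------------------------------------------------------------
# filter accounting and timeframe fixtures


def planted_filter_dataset(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Catch table with planted filter targets and their exact expectations.

    Contains a family below 1% of overall biomass, one species below 1%
    of its family's biomass, records in an out-of-region sector, and a
    5% share of records with an impossible (zero) fork length.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def add(species, family, n, length_mean, sector="north"):
        lengths = np.clip(rng.normal(length_mean, length_mean * 0.1, n), 50, None)
        for L in np.rint(lengths).astype(int):
            rows.append(
                {
                    "year": int(rng.integers(1990, 2000)),
                    "fishery": "bottom",
                    "sector": sector,
                    "species": species,
                    "family": family,
                    "fork_length_mm": int(L),
                    "count": 1,
                }
            )

    add("big_a", "famA", 400, 350)
    add("big_b", "famA", 300, 300)
    add("tiny_a", "famA", 4, 120)  # < 1% of famA biomass
    add("big_c", "famB", 420, 320)
    add("rare_x", "famC", 5, 150)  # famC < 1% of overall biomass
    add("big_a", "famA", 30, 350, sector="offshore")  # out of region

    df = pd.DataFrame(rows)
    n_invalid = int(round(0.05 * len(df)))
    invalid_idx = rng.choice(df.index[df["sector"] == "north"], n_invalid, replace=False)
    df.loc[invalid_idx, "fork_length_mm"] = 0

    attributes = pd.DataFrame(
        {
            "species": ["big_a", "big_b", "tiny_a", "big_c", "rare_x"],
            "family": ["famA", "famA", "famA", "famB", "famC"],
            "lw_a": [2.5e-8] * 5,
            "lw_b": [3.0] * 5,
            "lw_source_tier": [1] * 5,
            "max_length_mm": [600, 550, 300, 580, 350],
            "iconic": [False] * 5,
        }
    )
    expectations = {
        "n_invalid": n_invalid,
        "n_out_of_region": int((df["sector"] == "offshore").sum()),
        "dropped_family": "famC",
        "dropped_species": "tiny_a",
    }
    return df, attributes, expectations


def filter_accounting(seed: int = 0) -> dict:
    """Run the filters on the planted dataset and reconcile the accounting."""
    records, attributes, expected = planted_filter_dataset(seed)
    config = FilterConfig(region_sectors=["north"], strict=True)
    filtered, report = apply_filters(records, attributes, config)
    dropped_mass = (
        report.mass_dropped_kg
        + sum(e["mass_kg"] for e in report.dropped_families)
        + sum(e["mass_kg"] for e in report.dropped_species)
    )
    return {
        "expected": expected,
        "report": report.to_dict(),
        "n_invalid_dropped": report.dropped_records.get("invalid_measurement", {}).get(
            "n_records", 0
        ),
        "n_out_of_region_dropped": report.dropped_records.get("out_of_region", {}).get(
            "n_records", 0
        ),
        "dropped_families": [e["family"] for e in report.dropped_families],
        "dropped_species": [e["species"] for e in report.dropped_species],
        "mass_reconciliation_error_kg": abs(
            report.mass_in_kg - report.mass_out_kg - dropped_mass
        ),
        "n_records_out": report.n_records_out,
    }


TIMEFRAME_EXAMPLE_KG = [10.0, 80.0, 90.0, 80.0, 10.0, 10.0, 70.0, 10.0]
TIMEFRAME_EXAMPLE_EXPECTED = (1991, 1993)  # years 2-4 of a series starting 1990


def timeframe_example() -> dict:
    """The hand-checkable rolling-mean timeframe case.

    Annual landings [10, 80, 90, 80, 10, 10, 70, 10] kg from 1990: the
    centered 3-year means for 1991-1993 are 60, 83.3 and 60 (all >= 50)
    while the late spike's mean is 30, so the analysis window is
    1991-1993.
    """
    years = np.arange(1990, 1990 + len(TIMEFRAME_EXAMPLE_KG))
    records = pd.DataFrame(
        {"fishery": "bottom", "year": years, "biomass_kg": TIMEFRAME_EXAMPLE_KG}
    )
    result = fishery_timeframe(records, threshold_kg_per_yr=50.0, window=3)
    return {"result": result["bottom"], "expected": TIMEFRAME_EXAMPLE_EXPECTED}
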