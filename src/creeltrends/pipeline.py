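"""End-to-end pipeline: config in, tables/figures/logs out.

``run_pipeline`` wires the stages together — simulate or load records,
filter, determine per-fishery timeframes, size-classify families, build
and fit trend series, classify species into management categories — and
writes every product under one output directory:

* ``filter_report.json`` / ``filter.log`` — exact exclusion accounting
* ``timeframes.json``                    — analysis years per fishery
* ``size_classes.csv``                   — natural-breaks classes per family
* ``trend_fits.csv``                     — selected model per series
* ``species_management.csv``             — per-species trend pair + category
* ``management_summary.json``            — category counts and proportions
* ``plots/``                             — one figure per series (optional)

Every random draw flows from the single seed in the config, so a rerun
with the same config is byte-identical in its JSON/CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .filters import FilterConfig, apply_filters, fishery_timeframe
from .management import assignments_table, classify, summarize
from .simulate import (
    attributes_table,
    demo_scenarios,
    generate_catch,
    scenarios_from_yaml,
)
from .sizeclass import classification_table, classify_family_sizes
from .trends import (
    ModelFit,
    TrendSeries,
    build_series,
    equation_string,
    fit_candidates,
    fits_table,
    select_model,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every knob of one pipeline run; round-trips through YAML unchanged."""

    catch_csv: str | None = None  # load records from here ...
    scenario_yaml: str | None = None  # ... or simulate from this scenario file
    attributes_csv: str | None = None
    output_dir: str = "results/pipeline"
    fisheries: list[str] | None = None

    family_threshold: float = 0.01
    species_threshold: float = 0.01
    dominance: float = 0.10
    species_coverage: float = 0.70
    min_fish: int = 50
    timeframe_kg: float = 50.0
    window: int = 3
    alpha: float = 0.05
    gvf_increment: float = 0.10
    length_tolerance: float = 1.5
    region_sectors: list[str] | None = None
    strict: bool = True
    expansion_year: int | None = None
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "family_threshold", "species_threshold", "dominance",
            "species_coverage", "min_fish", "timeframe_kg", "window",
            "alpha", "gvf_increment", "length_tolerance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config threshold {name} must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending entity."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _load_inputs(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.catch_csv:
        records = cio.read_catch_csv(config.catch_csv)
        if config.attributes_csv is None:
            raise StageError("load", "attributes_csv required with catch_csv")
        attributes = cio.read_attributes_csv(config.attributes_csv)
    else:
        if config.scenario_yaml:
            scenarios, effort = scenarios_from_yaml(config.scenario_yaml)
            effort = dataclasses.replace(effort, seed=config.seed)
            records = generate_catch(scenarios, effort, fishery="simulated")
            attributes = attributes_table(scenarios)
        else:
            by_fishery, effort = demo_scenarios(seed=config.seed)
            rng = np.random.default_rng(config.seed)
            frames, attr_frames = [], []
            for fishery, scenarios in by_fishery.items():
                frames.append(generate_catch(scenarios, effort, fishery, rng=rng))
                attr_frames.append(attributes_table(scenarios))
            records = pd.concat(frames, ignore_index=True)
            attributes = (
                pd.concat(attr_frames, ignore_index=True)
                .sort_values(["species", "lw_source_tier"], kind="stable")
                .drop_duplicates("species")
                .reset_index(drop=True)
            )
    if config.fisheries:
        records = records.loc[records["fishery"].isin(config.fisheries)]
    if records.empty:
        raise StageError("load", "no catch records after fishery selection")
    return records, attributes


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the bundle of in-memory products."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records, attributes = _load_inputs(config)

    filter_config = FilterConfig(
        family_threshold=config.family_threshold,
        species_threshold=config.species_threshold,
        region_sectors=config.region_sectors,
        length_tolerance=config.length_tolerance,
        strict=config.strict,
    )
    try:
        filtered, report = apply_filters(records, attributes, filter_config)
    except (KeyError, ValueError) as exc:
        raise StageError("filter", str(exc)) from exc
    report.to_json(out_dir / "filter_report.json")
    (out_dir / "filter.log").write_text("\n".join(report.log_lines()) + "\n")

    timeframes = fishery_timeframe(
        filtered, threshold_kg_per_yr=config.timeframe_kg, window=config.window
    )
    with open(out_dir / "timeframes.json", "w") as fh:
        json.dump({k: list(v) if v else None for k, v in timeframes.items()}, fh, indent=2)

    retained_attrs = attributes.loc[
        attributes["species"].isin(filtered["species"].unique())
    ]
    classifications = classify_family_sizes(
        retained_attrs, gvf_increment=config.gvf_increment
    )
    classification_table(classifications).to_csv(out_dir / "size_classes.csv", index=False)

    series = build_series(
        filtered,
        attributes,
        classifications,
        dominance=config.dominance,
        species_coverage=config.species_coverage,
        min_fish=config.min_fish,
        window=config.window,
        timeframes=timeframes,
    )

    results: list[tuple[TrendSeries, ModelFit | None]] = []
    for s in series:
        if not s.fittable:
            log.warning("series %s has <5 usable years; not fitted", s.label)
            results.append((s, None))
            continue
        try:
            results.append((s, select_model(fit_candidates(s), alpha=config.alpha)))
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("fit", f"{s.label}: {exc}") from exc
    fits_table(results).to_csv(out_dir / "trend_fits.csv", index=False)

    # species-level management classification
    selected = {(s.fishery, s.unit, s.group): fit for s, fit in results}
    species_units = {
        (s.fishery, s.group) for s, _ in results
        if s.unit in ("species_pct", "species_size_mm")
    }
    assignments = []
    share_map, n_map = {}, {}
    for fishery, sub in filtered.groupby("fishery"):
        total = sub["biomass_kg"].sum()
        for species, mass in sub.groupby("species")["biomass_kg"].sum().items():
            share_map[(fishery, species)] = round(100.0 * mass / total, 1)
        for species, n in sub.groupby("species")["count"].sum().items():
            n_map[(fishery, species)] = int(n)
    for fishery, species in sorted(species_units):
        size_fit = selected.get((fishery, "species_size_mm", species))
        contrib_fit = selected.get((fishery, "species_pct", species))
        assignments.append(
            classify(size_fit, contrib_fit, species=species, fishery=fishery)
        )
    table = assignments_table(assignments, share_map, n_map)
    table.to_csv(out_dir / "species_management.csv", index=False)
    summary = summarize(assignments) if assignments else {}
    with open(out_dir / "management_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)

    if config.make_plots:
        plot_dir = out_dir / "plots"
        plot_dir.mkdir(exist_ok=True)
        for s, fit in results:
            plot_series(s, fit, plot_dir, expansion_year=config.expansion_year)

    return {
        "records": filtered,
        "filter_report": report,
        "timeframes": timeframes,
        "classifications": classifications,
        "series": series,
        "results": results,
        "assignments": assignments,
        "summary": summary,
        "output_dir": out_dir,
    }


def plot_series(
    series: TrendSeries,
    fit: ModelFit | None,
    out_dir,
    expansion_year: int | None = None,
) -> Path:
    """One figure per series: points scaled by weight, fitted curve and a
    confidence band only when a model was selected, and an annotation at
    the fishery-expansion year if configured."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import statsmodels.api as sm

    from .trends import _design  # reuse the exact design matrices

    fig, ax = plt.subplots(figsize=(6, 4))
    x_all = np.arange(1, len(series.years) + 1, dtype=float)
    ok = np.isfinite(series.smoothed_values) & (series.weights > 0)
    w = series.weights[ok]
    sizes = 10 + 90 * w / w.max() if len(w) and w.max() > 0 else 20
    ax.scatter(series.years[ok], series.smoothed_values[ok], s=sizes,
               alpha=0.7, edgecolor="k", linewidth=0.4, zorder=3)

    if fit is not None:
        x, y, wts = series.fit_points()
        log_resp = fit.form in ("exponential", "power")
        res = sm.WLS(np.log(y) if log_resp else y, _design(fit.form, x), weights=wts).fit()
        grid = np.linspace(x.min(), x.max(), 120)
        pred = res.get_prediction(_design(fit.form, grid)).summary_frame(alpha=0.05)
        mean, lo, hi = (
            pred["mean"].to_numpy(), pred["mean_ci_lower"].to_numpy(),
            pred["mean_ci_upper"].to_numpy(),
        )
        if log_resp:
            mean, lo, hi = np.exp(mean), np.exp(lo), np.exp(hi)
        year_grid = series.years[0] + (grid - 1.0)
        ax.plot(year_grid, mean, color="C3", zorder=2)
        ax.fill_between(year_grid, lo, hi, color="C3", alpha=0.2, zorder=1)
        ax.set_title(f"{series.label}\n{equation_string(fit)}", fontsize=9)
    else:
        ax.set_title(f"{series.label}\n(no significant model)", fontsize=9)

    if expansion_year is not None and series.years[0] <= expansion_year <= series.years[-1]:
        ax.axvline(expansion_year, color="gray", linestyle="--", linewidth=1)
        ax.annotate("expansion", (expansion_year, ax.get_ylim()[1]),
                    fontsize=7, ha="center", va="top", color="gray")
    ax.set_xlabel("year")
    ax.set_ylabel(series.unit)
    fig.tight_layout()
    safe = series.label.replace("/", "_").replace(" ", "-")
    path = Path(out_dir) / f"{safe}.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
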