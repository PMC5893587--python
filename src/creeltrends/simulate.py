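"""Synthetic creel-survey data with known per-species trend structure.

The creel records this package analyzes (species-level landings with fork
lengths, collected by intercepting returning fishers) are held by a
government monitoring program and are not openly distributed.  This module
generates datasets with the same schema and with *known* ground truth:
each species follows a configurable trajectory for its proportional
contribution to landings and for its mean fork length, so parameter
recovery and classification recovery can be tested end to end.

Design of the generative model:

* Annual measured-fish totals are Poisson around a (possibly year-varying)
  expectation, emulating a reporting effort that rises and collapses over
  the survey's life.  Species counts within a year are multinomial with
  probabilities given by the (normalized) contribution trajectories — the
  varying per-year sample sizes this produces are exactly what the
  downstream weighted regressions exist to handle.
* Individual fork lengths are normal around the year's trajectory mean with
  a standard deviation proportional to that mean, truncated to
  (0, max_length] and rounded to the nearest mm, matching how creel staff
  record fish.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

CATCH_COLUMNS = [
    "year",
    "fishery",
    "sector",
    "species",
    "family",
    "fork_length_mm",
    "count",
]

#: trajectory shapes; "exponential" is saturating (fast early change that
#: levels off), "humped" is quadratic (rise-then-fall or fall-then-rise).
PATH_FORMS = ("constant", "linear", "exponential", "humped")

DEFAULT_SECTORS = ("north", "east", "south", "west")


@dataclass(frozen=True)
class PathSpec:
    """One dependent variable's true trajectory over the survey years.

    ``start`` is the value in the first year and ``net_change`` the signed
    end-minus-start difference, so the generating truth used by recovery
    tests can be read directly off the spec.  ``hump`` adds a symmetric
    quadratic bump (peak amplitude at mid-series) and is only meaningful
    for the "humped" form.
    """

    form: str
    start: float
    net_change: float = 0.0
    hump: float = 0.0
    rate: float = 3.0  # saturation speed of the exponential form

    def __post_init__(self) -> None:
        if self.form not in PATH_FORMS:
            raise ValueError(f"unknown path form {self.form!r}; use one of {PATH_FORMS}")

    def values(self, n_years: int) -> np.ndarray:
        """Evaluate the trajectory at each of ``n_years`` annual steps."""
        if n_years < 1:
            raise ValueError("need at least one year")
        if n_years == 1:
            return np.array([self.start], dtype=float)
        s = np.linspace(0.0, 1.0, n_years)
        if self.form == "constant":
            out = np.full(n_years, self.start, dtype=float)
        elif self.form == "linear":
            out = self.start + self.net_change * s
        elif self.form == "exponential":
            scale = -math.expm1(-self.rate)  # 1 - exp(-rate)
            out = self.start + self.net_change * (-np.expm1(-self.rate * s)) / scale
        else:  # humped
            out = self.start + self.net_change * s + self.hump * 4.0 * s * (1.0 - s)
        return out


@dataclass(frozen=True)
class SpeciesScenario:
    """Generating truth for one species in one simulated fishery."""

    species_id: str
    family: str
    max_length_mm: float
    lw_a: float  # allometric coefficient, mm -> kg basis
    lw_b: float  # allometric exponent
    contribution_path: PathSpec  # proportion of landed fish, pre-normalization
    size_path: PathSpec  # mean fork length, mm
    length_cv: float = 0.15
    iconic: bool = False
    lw_source_tier: int = 1

    def __post_init__(self) -> None:
        if not (2.5 <= self.lw_b <= 3.5):
            raise ValueError(f"{self.species_id}: lw_b {self.lw_b} outside [2.5, 3.5]")
        if self.max_length_mm <= 0:
            raise ValueError(f"{self.species_id}: max_length_mm must be positive")
        if not (0.0 < self.length_cv <= 0.5):
            raise ValueError(f"{self.species_id}: length_cv {self.length_cv} outside (0, 0.5]")


@dataclass(frozen=True)
class EffortSchedule:
    """Survey coverage: which years are sampled and how hard.

    ``annual_n_fish`` is either a single expectation applied to every year
    or a per-year sequence, which lets scenarios emulate the collapse in
    reporting that real creel programs experience.
    """

    start_year: int
    end_year: int
    annual_n_fish: float | Sequence[float] = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("end_year before start_year")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def expected_counts(self) -> np.ndarray:
        years = self.years
        if np.isscalar(self.annual_n_fish):
            out = np.full(len(years), float(self.annual_n_fish))
        else:
            out = np.asarray(self.annual_n_fish, dtype=float)
            if len(out) != len(years):
                raise ValueError(
                    f"annual_n_fish has {len(out)} entries for {len(years)} years"
                )
        if (out < 0).any():
            raise ValueError("annual_n_fish must be >= 0 for every year")
        return out


def _contribution_matrix(
    scenarios: Sequence[SpeciesScenario], n_years: int
) -> np.ndarray:
    """(n_years, n_species) matrix of normalized contribution probabilities."""
    probs = np.column_stack([s.contribution_path.values(n_years) for s in scenarios])
    for j, scen in enumerate(scenarios):
        if (probs[:, j] < 0).any():
            raise ValueError(
                f"scenario {scen.species_id!r}: contribution path goes negative"
            )
    totals = probs.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("contribution paths sum to zero in at least one year")
    return probs / totals[:, None]


def generate_catch(
    scenarios: Sequence[SpeciesScenario],
    effort: EffortSchedule,
    fishery: str,
    sectors: Sequence[str] = DEFAULT_SECTORS,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a creel-record table (one row per measured fish).

    Counts per species-year are multinomial draws conditional on a Poisson
    annual total; lengths are truncated normals around the size trajectory,
    rounded to integer mm.  The same seed always yields the same table.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("need at least one SpeciesScenario")
    years = effort.years
    if len(years) < 4:
        raise ValueError("year range must span at least 4 years")
    for scen in scenarios:
        if (scen.size_path.values(len(years)) <= 0).any():
            raise ValueError(f"scenario {scen.species_id!r}: size path goes non-positive")

    if rng is None:
        rng = np.random.default_rng(effort.seed)
    probs = _contribution_matrix(scenarios, len(years))
    size_means = np.column_stack([s.size_path.values(len(years)) for s in scenarios])
    expected = effort.expected_counts()

    rows: list[pd.DataFrame] = []
    for i, year in enumerate(years):
        total = rng.poisson(expected[i])
        if total == 0:
            continue
        counts = rng.multinomial(total, probs[i])
        for j, scen in enumerate(scenarios):
            n = int(counts[j])
            if n == 0:
                continue
            mean = size_means[i, j]
            sd = mean * scen.length_cv
            lengths = rng.normal(mean, sd, size=n)
            # redraw out-of-support lengths rather than clipping, so the
            # realized distribution is a true truncated normal
            bad = (lengths <= 0) | (lengths > scen.max_length_mm)
            while bad.any():
                lengths[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                bad = (lengths <= 0) | (lengths > scen.max_length_mm)
            lengths = np.clip(np.rint(lengths), 1, int(scen.max_length_mm)).astype(int)
            rows.append(
                pd.DataFrame(
                    {
                        "year": year,
                        "fishery": fishery,
                        "sector": rng.choice(sectors, size=n),
                        "species": scen.species_id,
                        "family": scen.family,
                        "fork_length_mm": lengths,
                        "count": 1,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=CATCH_COLUMNS)
    out = pd.concat(rows, ignore_index=True)
    return out[CATCH_COLUMNS]


def scenario_truth(
    scenarios: Sequence[SpeciesScenario], effort: EffortSchedule
) -> pd.DataFrame:
    """Tabulate the generating form and signed net change per species/variable.

    Net change is evaluated from the path formula at the first and last
    year, so humped paths report their end-minus-start difference, not the
    hump amplitude.
    """
    n_years = len(effort.years)
    records = []
    for scen in scenarios:
        for variable, path in (
            ("contribution", scen.contribution_path),
            ("size", scen.size_path),
        ):
            vals = path.values(n_years)
            records.append(
                {
                    "species": scen.species_id,
                    "family": scen.family,
                    "variable": variable,
                    "form": path.form,
                    "start": vals[0],
                    "net_change": vals[-1] - vals[0],
                }
            )
    return pd.DataFrame(records)


def attributes_table(scenarios: Sequence[SpeciesScenario]) -> pd.DataFrame:
    """Species-attribute table (length-weight coefficients etc.) for a scenario set."""
    return pd.DataFrame(
        {
            "species": [s.species_id for s in scenarios],
            "family": [s.family for s in scenarios],
            "lw_a": [s.lw_a for s in scenarios],
            "lw_b": [s.lw_b for s in scenarios],
            "lw_source_tier": [s.lw_source_tier for s in scenarios],
            "max_length_mm": [s.max_length_mm for s in scenarios],
            "iconic": [s.iconic for s in scenarios],
        }
    )


# ---------------------------------------------------------------------------
# scenario (de)serialization


def scenarios_to_yaml(
    scenarios: Sequence[SpeciesScenario], effort: EffortSchedule, path
) -> None:
    payload = {
        "effort": {
            "start_year": effort.start_year,
            "end_year": effort.end_year,
            "annual_n_fish": (
                float(effort.annual_n_fish)
                if np.isscalar(effort.annual_n_fish)
                else [float(v) for v in effort.annual_n_fish]
            ),
            "seed": int(effort.seed),
        },
        "species": [
            {
                **{
                    k: v
                    for k, v in dataclasses.asdict(s).items()
                    if k not in ("contribution_path", "size_path")
                },
                "contribution_path": dataclasses.asdict(s.contribution_path),
                "size_path": dataclasses.asdict(s.size_path),
            }
            for s in scenarios
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def scenarios_from_yaml(path) -> tuple[list[SpeciesScenario], EffortSchedule]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    effort = EffortSchedule(**payload["effort"])
    scenarios = []
    for entry in payload["species"]:
        entry = dict(entry)
        entry["contribution_path"] = PathSpec(**entry["contribution_path"])
        entry["size_path"] = PathSpec(**entry["size_path"])
        scenarios.append(SpeciesScenario(**entry))
    return scenarios, effort


# ---------------------------------------------------------------------------
# a packaged demonstration fishery


def demo_scenarios(seed: int = 0) -> tuple[dict[str, list[SpeciesScenario]], EffortSchedule]:
    """A small island-scale scenario set spanning three fisheries.

    Mimics the broad strokes of a Pacific reef fishery: a bottom fishery
    dominated by emperors/snappers/groupers with the large species fading,
    a spear fishery dominated by parrotfishes and surgeonfishes with
    large-to-small replacement, and compensating 'other' species.  Numbers
    (sizes, allometric coefficients) are realistic for the families named.
    """

    def sp(name, fam, maxlen, a, b, cpath, spath, cv=0.15, iconic=False, tier=1):
        return SpeciesScenario(
            species_id=name,
            family=fam,
            max_length_mm=maxlen,
            lw_a=a,
            lw_b=b,
            contribution_path=cpath,
            size_path=spath,
            length_cv=cv,
            iconic=iconic,
            lw_source_tier=tier,
        )

    P = PathSpec
    bottom = [
        sp("Lethrinus rubrioperculatus", "Lethrinidae", 500, 2.6e-8, 3.0,
           P("linear", 0.28, -0.10), P("linear", 290, -35)),
        sp("Lethrinus xanthochilus", "Lethrinidae", 600, 2.8e-8, 3.0,
           P("exponential", 0.06, 0.05), P("constant", 380)),
        sp("Lethrinus harak", "Lethrinidae", 400, 3.0e-8, 3.0,
           P("linear", 0.06, 0.03), P("linear", 250, -30)),
        sp("Aprion virescens", "Lutjanidae", 900, 1.6e-8, 3.05,
           P("exponential", 0.10, -0.08), P("linear", 520, -60)),
        sp("Lutjanus bohar", "Lutjanidae", 760, 2.9e-8, 3.0,
           P("linear", 0.03, 0.04), P("constant", 420)),
        sp("Lutjanus gibbus", "Lutjanidae", 450, 3.2e-8, 2.95,
           P("linear", 0.08, 0.02), P("linear", 270, -20)),
        sp("Variola louti", "Serranidae", 700, 1.9e-8, 3.02,
           P("exponential", 0.09, -0.07), P("linear", 430, -40)),
        sp("Cephalopholis sonnerati", "Serranidae", 570, 2.4e-8, 3.0,
           P("linear", 0.05, -0.03), P("linear", 350, -45)),
        sp("Epinephelus fasciatus", "Serranidae", 400, 2.7e-8, 3.0,
           P("linear", 0.05, 0.05), P("linear", 240, -25)),
        sp("Gymnosarda unicolor", "Scombridae", 1900, 1.2e-8, 3.05,
           P("linear", 0.02, 0.035), P("constant", 780), iconic=True, tier=4),
        sp("Caranx ignobilis", "Carangidae", 1650, 2.0e-8, 3.0,
           P("constant", 0.02), P("linear", 640, -70), iconic=True, tier=2),
        sp("Sphyraena qenie", "Sphyraenidae", 1700, 6.0e-9, 3.1,
           P("linear", 0.02, 0.03), P("constant", 700), tier=4),
        sp("Parupeneus barberinus", "Mullidae", 500, 2.5e-8, 3.0,
           P("humped", 0.05, 0.01, hump=0.03), P("linear", 260, -30)),
        sp("Myripristis berndti", "Holocentridae", 300, 3.5e-8, 2.95,
           P("linear", 0.04, 0.02), P("constant", 210)),
    ]
    scuba = [
        sp("Hipposcarus longiceps", "Scaridae", 600, 2.3e-8, 3.0,
           P("exponential", 0.16, -0.10), P("linear", 420, -80)),
        sp("Scarus altipinnis", "Scaridae", 600, 2.5e-8, 3.0,
           P("exponential", 0.10, -0.08), P("linear", 400, -50)),
        sp("Chlorurus microrhinos", "Scaridae", 700, 2.2e-8, 3.0,
           P("linear", 0.09, -0.06), P("linear", 430, -40)),
        sp("Scarus rubroviolaceus", "Scaridae", 700, 2.4e-8, 3.0,
           P("exponential", 0.06, -0.045), P("linear", 410, -55)),
        sp("Chlorurus spilurus", "Scaridae", 400, 2.8e-8, 3.0,
           P("linear", 0.05, 0.06), P("linear", 230, -15)),
        sp("Scarus schlegeli", "Scaridae", 400, 2.7e-8, 3.0,
           P("linear", 0.05, 0.05), P("linear", 250, -35)),
        sp("Naso unicornis", "Acanthuridae", 700, 2.6e-8, 2.95,
           P("linear", 0.10, 0.05), P("linear", 400, -45)),
        sp("Naso lituratus", "Acanthuridae", 460, 3.1e-8, 2.9,
           P("linear", 0.06, -0.02), P("linear", 290, -40)),
        sp("Acanthurus xanthopterus", "Acanthuridae", 700, 2.4e-8, 3.0,
           P("linear", 0.04, 0.02), P("constant", 380)),
        sp("Variola louti", "Serranidae", 700, 1.9e-8, 3.02,
           P("exponential", 0.07, -0.05), P("linear", 420, -60)),
        sp("Epinephelus fasciatus", "Serranidae", 400, 2.7e-8, 3.0,
           P("linear", 0.03, 0.04), P("linear", 240, -20)),
        sp("Cheilinus undulatus", "Labridae", 2290, 1.5e-8, 3.05,
           P("exponential", 0.05, -0.04), P("linear", 900, -150),
           iconic=True, tier=2),
        sp("Siganus punctatus", "Siganidae", 400, 2.9e-8, 3.0,
           P("linear", 0.05, 0.03), P("linear", 280, -45)),
        sp("Monotaxis grandoculis", "Lethrinidae", 600, 3.0e-8, 3.0,
           P("linear", 0.04, 0.02), P("constant", 330)),
        sp("Kyphosus cinerascens", "Kyphosidae", 500, 2.8e-8, 3.0,
           P("linear", 0.03, 0.03), P("linear", 320, -35)),
    ]
    freedive = [
        sp("Chlorurus frontalis", "Scaridae", 500, 2.4e-8, 3.0,
           P("linear", 0.07, 0.03), P("constant", 330)),
        sp("Chlorurus spilurus", "Scaridae", 400, 2.8e-8, 3.0,
           P("linear", 0.08, 0.04), P("linear", 220, -15)),
        sp("Chlorurus microrhinos", "Scaridae", 700, 2.2e-8, 3.0,
           P("exponential", 0.08, -0.06), P("linear", 400, -35)),
        sp("Scarus rubroviolaceus", "Scaridae", 700, 2.4e-8, 3.0,
           P("linear", 0.05, -0.03), P("linear", 390, -45)),
        sp("Scarus psittacus", "Scaridae", 300, 2.9e-8, 3.0,
           P("linear", 0.06, 0.02), P("linear", 200, -25)),
        sp("Scarus schlegeli", "Scaridae", 400, 2.7e-8, 3.0,
           P("linear", 0.06, 0.02), P("linear", 240, -30)),
        sp("Naso unicornis", "Acanthuridae", 700, 2.6e-8, 2.95,
           P("linear", 0.10, 0.06), P("linear", 380, -60)),
        sp("Naso lituratus", "Acanthuridae", 460, 3.1e-8, 2.9,
           P("constant", 0.07), P("linear", 280, -45)),
        sp("Acanthurus lineatus", "Acanthuridae", 380, 3.2e-8, 2.9,
           P("linear", 0.06, 0.01), P("linear", 240, -35)),
        sp("Acanthurus triostegus", "Acanthuridae", 270, 3.4e-8, 2.9,
           P("linear", 0.04, 0.05), P("linear", 180, -20)),
        sp("Siganus spinus", "Siganidae", 280, 3.0e-8, 3.0,
           P("linear", 0.05, 0.06), P("constant", 170)),
        sp("Kyphosus vaigiensis", "Kyphosidae", 600, 2.8e-8, 3.0,
           P("linear", 0.05, -0.02), P("linear", 340, -50)),
        sp("Cheilinus trilobatus", "Labridae", 450, 2.6e-8, 3.0,
           P("linear", 0.04, -0.02), P("linear", 280, -40)),
        sp("Parupeneus barberinus", "Mullidae", 500, 2.5e-8, 3.0,
           P("linear", 0.05, 0.03), P("linear", 250, -35)),
        sp("Epinephelus merra", "Serranidae", 320, 2.9e-8, 3.0,
           P("linear", 0.04, 0.02), P("linear", 210, -25)),
    ]
    # reporting rises, plateaus, then collapses late in the series
    n_years = 25
    ramp = np.concatenate(
        [
            np.linspace(1200, 2600, 8),
            np.full(10, 2800.0),
            np.linspace(2400, 400, 7),
        ]
    )
    effort = EffortSchedule(1985, 1985 + n_years - 1, annual_n_fish=ramp, seed=seed)
    return {"bottom": bottom, "SCUBA": scuba, "freedive": freedive}, effort
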