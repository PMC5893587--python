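# creeltrends

Trend analysis for multispecies coral-reef fisheries from
fisheries-dependent creel surveys: species-level catch records (year,
fishery method, sector, species, fork length in mm) are turned into the
summaries a management agency needs — which families and species are
fading from the landings, whose size structure is eroding, and which
kind of policy (size limits vs gear/quota/area restrictions) each
heavily landed species' trajectory points to.

It is written for quantitative fisheries ecologists working with
long-running intercept-survey databases of the kind Pacific island
agencies maintain, where a few dozen target species dominate landings
and formal stock assessments are out of reach. Because such databases
are typically restricted, the package ships a synthetic-data generator
that emulates the record schema with known per-species trend structure,
so the whole pipeline is testable against ground truth.

## What it computes

1. **Filtering.** Records are reduced to the fishery's main components:
   out-of-region sectors, impossible fork lengths, families under 1% of
   overall biomass and species under 1% of their family's biomass are
   dropped, with exact mass accounting. Each fishery is analyzed over
   the longest run of years whose centered 3-year rolling mean of
   landed mass stays at or above 50 kg/yr.
2. **Biomass.** Length is converted to mass by the allometric law
   W = a·L^b, with species coefficients taken from an attribute table
   that records each coefficient's geographic provenance tier (most
   local wins).
3. **Body-size classes.** Within each family, species are split into 2
   or 3 size categories by Fisher-optimal natural breaks (exact
   dynamic-programming "Jenks" partition) on maximum length; the
   large:small biomass ratio tracks size-structure erosion.
4. **Trends.** Annual series (family % contribution, large:small
   ratios, mean sizes, iconic-species %, per-species % and size) are
   smoothed with a centered 3-year moving average and fitted by
   weighted least squares against the year index, with per-year
   weights equal to landed kg (biomass variables) or fish counted
   (size variables). Four candidate forms compete — y~x, log(y)~x,
   log(y)~log(x), y~x+x² — and the winner is the minimum-AIC
   significant fit whose residuals pass a Shapiro–Wilk check
   (Durbin–Watson autocorrelation is flagged).
5. **Management categories.** For each dominant species the size trend
   and the contribution trend are compared under a four-criterion rule
   (curved immediate declines outrank linear ones; tied strengths are
   resolved by standardized effect sizes with ±1 SE overlap), assigning
   `size`, `gear_quota_area`, `both_either`, or `none`.

## Worked example

The numbered scripts under `analysis/` run the pipeline on the packaged
three-fishery demonstration scenario (25 simulated years, ~160k
records):

```sh
python analysis/01_simulate_fishery.py --seed 0
python analysis/02_filter_landings.py
python analysis/03_size_classes.py
python analysis/04_fit_trends.py
python analysis/05_classify_management.py
```

Step 02 prints the filter accounting —

```
records in: 158870 (168629.6 kg)
records out: 156129 (167909.4 kg)
dropped family Holocentridae [family<1%] (2741 records, 720.3 kg, share 0.43%)
```

— the soldierfish family fell below 1% of overall biomass and is
removed in full. Step 03 reports, e.g., `Scaridae: 3 classes, breaks at
['400 mm', '600 mm'], gvf=0.914`: parrotfishes split into three
body-size categories explaining 91% of the variance in maximum length.
Step 04 prints one selected model per series, such as

```
SCUBA  Scaridae  ratio  y = -1.4x + 0.033x2 + 17.2  0.98  ***
```

a humped (quadratic) collapse of the large:small parrotfish ratio, net
change −74% across the series. Step 05 summarizes the management
assignments:

```
18 species assessed across fisheries; 67% placed in a category
  size: 58% of placed species
  gear_quota_area: 25% of placed species
  both_either: 17% of placed species
```

meaning most placed species were hit harder in size structure than in
their share of the landings — the generating scenario plants exactly
such a mix, and `results/analysis/generating_truth.csv` lists the true
trajectories for comparison. `analysis/06_validate_method.py` runs the
method-validation experiments (natural-breaks oracle, recovery
simulations, type-I control, classification recovery).

A `creeltrends` command-line interface exposes the same stages
(`simulate`, `filter`, `classify-sizes`, `fit-trends`,
`classify-management`, `run-all`); see `creeltrends --help`.

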