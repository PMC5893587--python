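# Methods

This note records the statistical model behind `creeltrends`, the
choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not establish.

## Data model

The unit of observation is one measured landed fish: calendar year,
fishery method (e.g. SCUBA spear, freedive spear, shallow bottom line),
geographic sector, species, fork length in mm, count. Species
attributes are inputs, never estimated: allometric coefficients
(a, b) with a provenance tier (1 = local study … 4 = distant region;
the lowest tier wins when duplicates exist), maximum fork length, and
an iconic-species flag. Coefficients may be supplied on mm→kg, mm→g or
cm→g bases (declared once in the attribute file header) and are
converted to mm→kg on load, eliminating the classic 10^b unit error.

## Filtering

Four sequential filters, each computing its percentage base on the
records surviving the previous step:

1. **location** — sectors outside the configured region;
2. **validity** — fork length missing, ≤ 0, or above the species
   maximum by more than a tolerance (default 1.5×); optionally species
   with no attribute row (strict mode aborts instead);
3. **family** — families below 1% of overall retained biomass (pooled
   across fisheries by default; a per-fishery variant is a config
   flag);
4. **species** — species below 1% of their family's biomass.

Both 1% thresholds are strict inequalities — a group at exactly 1% is
kept — with a 1e-9 relative guard so float rounding cannot flip the
boundary case. The fixed order keeps the percentage bases well defined;
it also makes the operation idempotent, since removing a sub-threshold
group only raises the shares of the remainder. The filter report
reconciles record counts and mass exactly; records whose mass cannot be
computed (invalid length, unknown species) carry 0 kg in the ledger.

Each fishery's **analysis timeframe** is the longest contiguous run of
years whose centered rolling mean (window 3, truncated at the series
ends) of annual landed mass is ≥ 50 kg/yr; ties go to the earlier run.
The floor, window, and every other threshold in this note live in
`RunConfig`.

## Body-size classes and the large:small ratio

Within a family, species' maximum lengths are partitioned by the exact
Fisher dynamic program minimizing total within-class sum of squared
deviations — the optimum over all ordered partitions, verified in the
tests against exhaustive enumeration. Quality is gvf = 1 −
SSD_within/SSD_total. Three classes are used instead of two only when
they raise gvf by ≥ 0.10 (configurable, and explicit class maps can be
pinned per family); families with fewer than three species get a
single-class sentinel and are excluded from ratio analyses. Equal-SSD
ties are broken deterministically toward smaller leading classes.
The large:small ratio for a family-fishery-year is the biomass of all
classes above the smallest divided by the smallest class's biomass;
years with an empty smallest class yield a missing value that is simply
absent from the fitted points (no imputation).

## Trend series and weighted model selection

Every dependent variable becomes an annual series over the fishery's
timeframe: percent contributions are biomass percentages of the
fishery-year total; mean sizes are unweighted means of fork length in
the group-year. Series are smoothed with a centered 3-year moving
average (before–during–after each year); the series ends use the
truncated 2-point window so no years are lost. Per-year confidence
weights are the fishery-year landed kg for biomass-derived variables
(family/species/iconic percentages), the family-year kg for ratios,
and the group-year fish count for size variables.

Fits are weighted least squares against the year index x = 1..T, so
reported intercepts refer to the first analyzed year. Candidate forms:

| form        | model              | fishery reading                      |
|-------------|--------------------|--------------------------------------|
| linear      | y = b0 + b1x       | steady rise or decline               |
| exponential | log y = b0 + b1x   | fast change, then saturation         |
| power       | log y = b0 + b1 ln x | decelerating change                |
| quadratic   | y = b0 + b1x + b2x² | humped rise-then-fall (or reverse)  |

Log-response forms are skipped when the response is not strictly
positive. At least 5 usable years are required; shorter series are
emitted but flagged unfittable. Selection takes the minimum-AIC model
among significant fits (model F-test, α = 0.05) whose residuals pass a
Shapiro–Wilk normality check at the same α; if none pass, the best
significant fit is taken with a `normality_violated` flag. A
Durbin–Watson statistic outside [1, 3] adds an `autocorrelated` flag
without vetoing. Net change is the fitted last-year value minus the
fitted first-year value on the original response scale.

Two numerical choices deserve note:

* **Cross-scale AIC.** To compare log- and identity-response fits, each
  model's fitted values are back-transformed to the original scale and
  a Gaussian likelihood is computed from the weighted residuals there
  (no smearing or Jacobian correction; the choice is isolated in
  `_original_scale_aic`, and weights enter identically for all forms so
  their scaling cancels). A proper lognormal likelihood is a defensible
  alternative; in our validation experiments it changes selections only
  at the margin.
* **Weights are used unnormalized**, which leaves WLS point estimates
  untouched and only shifts all likelihoods by a common constant.

## Management classification

For each assessed species the selected size fit and contribution fit
(either may be absent) are compared:

1. a *declining* trend is a selected fit with negative net change; a
   curved form (exponential/power/quadratic) whose fitted derivative is
   negative at the first year ("immediate decline") outranks a linear
   decline; a lone declining variable wins outright;
2. equal strengths are resolved by effect sizes: the standardized slope
   (linear-term coefficient after z-scoring predictor and response on
   the model's own scales, fitted with the series weights) with its SE;
   non-overlapping ±1 SE intervals give the larger-magnitude variable's
   category;
3. overlapping intervals make the strategies equal (`both_either`);
4. species with no declining trend — stable or increasing — get no
   category; an increase in one variable never blocks classification by
   a decline in the other.

Size declines map to `size` (size-based policies); contribution
declines map to `gear_quota_area`. The effect-size measure and its
overlap convention are the least constrained part of the rule; the
standardized slope with ±1 SE is the default, and a net-change-fraction
alternative is selectable. A quadratic that rises before falling is
*not* an immediate decline and ranks with linear declines.
Species are assessed per fishery for the dominant set: ranked by
biomass, cumulatively reaching 70% of fishery biomass, each with ≥ 50
measured fish.

## Synthetic data

The generator emulates the schema and the statistical character of a
creel database while every trend is known: per-species contribution and
mean-size trajectories follow constant, linear, saturating-exponential,
or humped-quadratic paths; annual totals are Poisson around a
year-varying effort expectation (including late-series reporting
collapse — the reason the regressions are weighted); species counts are
multinomial on the normalized contributions; lengths are truncated
normals (sd = mean × CV, default CV 0.15) rounded to mm, as survey
staff record them. Sectors are uniform; the sector dimension exists
only for schema fidelity. It does not emulate gear selectivity, spatial
structure, within-year seasonality, market-driven targeting shifts, or
length-measurement bias — so passing recovery tests demonstrates that
the estimators recover the trends they model, not that real creel data
satisfy those models.

Default experiment sizes (chosen as realistic desk-scale conditions):
demonstration fisheries run 25 years at roughly 1200–2800 measured fish
per fishery-year; the classification-recovery cohort uses 40 species ×
20 years at ~4000 fish/yr (≈100 per species-year) with a planted
40/20/10/30 mix of size-decline / contribution-decline / both-equal /
stable scenarios, declines of −20% (size) and −50% (contribution), and
every species assessed (coverage 100%).

## Known limitations

* **Model-family identifiability.** A weakly humped decline (small
  positive curvature on a falling trend) is closely approximated by the
  saturating log-forms with one fewer parameter, so AIC selection
  attributes such series to the exponential/power family in a large
  fraction of replicates; the validation experiments quantify this
  (`analysis/06_validate_method.py`). Coefficient estimates of the
  quadratic itself remain unbiased, and strongly humped or saturating
  shapes are recovered reliably.
* Because candidate forms are tested jointly, the flat-series
  false-positive rate sits at or slightly above the per-test α; the
  type-I experiment measures it.
* Smoothing before fitting leaves residual autocorrelation in clean
  series; the Durbin–Watson flag is advisory, as the fitted parameters
  are used comparatively (size vs contribution), not as absolute rates.
* The large:small ratio is undefined in years without smallest-class
  landings; long gaps shorten the usable series and can make a family
  unfittable.
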