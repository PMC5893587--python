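"""Smoothed annual trend series and weighted candidate-model selection.

Each dependent variable (a family's percent contribution to landings, a
family's large:small biomass ratio, a group's mean fork length, ...) is
turned into an annual series, smoothed with a centered three-year moving
average, and fitted with weighted least squares against the year index
x = 1..T.  The weights carry the confidence of each annual value: total
landed kilograms for biomass-derived variables, fish counted for size
variables — so poorly reported years pull the fit less.

Four candidate forms are fitted, covering the trajectories a fishery can
realistically follow:

* ``linear``       y = b0 + b1 x            (steady rise or decline)
* ``exponential``  log(y) = b0 + b1 x       (fast change, then saturation)
* ``power``        log(y) = b0 + b1 log(x)  (decelerating change)
* ``quadratic``    y = b0 + b1 x + b2 x^2   (humped rise-then-fall)

The winner is chosen by AIC among significant fits, preferring fits
whose residuals pass a Shapiro-Wilk normality check; Durbin-Watson
residual autocorrelation outside [1, 3] is flagged but does not veto.
To make AIC comparable across log- and identity-response forms, every
model's likelihood is evaluated on the original response scale from
back-transformed fitted values (no smearing correction; the choice is
isolated in ``_original_scale_aic``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.stattools import durbin_watson

log = logging.getLogger(__name__)

FORMS = ("linear", "exponential", "power", "quadratic")

#: forms that can express an "immediate decline" stronger than a straight line
CURVED_FORMS = frozenset({"exponential", "power", "quadratic"})


def moving_average(values, window: int = 3) -> np.ndarray:
    """Centered moving average; ends use the truncated available window.

    NaNs inside a window are skipped; a position is NaN only when every
    value in its window is missing.  ``window`` must be odd so the
    smoother is symmetric (before-during-after each year for window 3);
    window 1 is the identity.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot smooth an empty series")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    out = np.empty_like(values)
    for i in range(len(values)):
        chunk = values[max(0, i - half) : i + half + 1]
        out[i] = np.nan if np.isnan(chunk).all() else np.nanmean(chunk)
    return out


@dataclass
class TrendSeries:
    """One dependent variable's annual values with per-year confidence weights."""

    fishery: str
    unit: str  # e.g. family_pct, ratio, mean_size_mm, species_pct, iconic_pct
    group: str  # family, species, "other fishes", or "iconic"
    years: np.ndarray
    raw_values: np.ndarray
    smoothed_values: np.ndarray
    weights: np.ndarray

    @classmethod
    def from_raw(cls, fishery, unit, group, years, raw_values, weights, window=3):
        years = np.asarray(years, dtype=int)
        raw = np.asarray(raw_values, dtype=float)
        w = np.asarray(weights, dtype=float)
        if not (len(years) == len(raw) == len(w)):
            raise ValueError("years, values and weights must align")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        return cls(fishery, unit, group, years, raw, moving_average(raw, window), w)

    @property
    def label(self) -> str:
        return f"{self.fishery}/{self.group}/{self.unit}"

    def fit_points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Usable (x, y, w): year index from 1, smoothed y, positive weight."""
        x = np.arange(1, len(self.years) + 1, dtype=float)
        ok = np.isfinite(self.smoothed_values) & (self.weights > 0)
        return x[ok], self.smoothed_values[ok], self.weights[ok]

    @property
    def n_usable(self) -> int:
        return int(np.sum(np.isfinite(self.smoothed_values) & (self.weights > 0)))

    @property
    def fittable(self) -> bool:
        return self.n_usable >= 5


@dataclass
class ModelFit:
    """One fitted candidate regression and its diagnostics."""

    form: str
    params: dict[str, float]
    bse: dict[str, float]
    r2: float
    p_value: float
    aic: float
    shapiro_p: float
    dw: float
    n: int
    net_change: float
    net_change_pct: float
    derivative_start: float
    std_slope: float
    std_slope_se: float
    selected: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def declining(self) -> bool:
        return self.net_change < 0

    @property
    def immediate_decline(self) -> bool:
        return self.derivative_start < 0

    @property
    def strength_class(self) -> str:
        """Curved forms that fall from the outset outrank straight lines."""
        if self.form in CURVED_FORMS and self.immediate_decline:
            return "strong"
        return "weak"


def _design(form: str, x: np.ndarray) -> np.ndarray:
    if form == "linear" or form == "exponential":
        return sm.add_constant(x, has_constant="add")
    if form == "power":
        return sm.add_constant(np.log(x), has_constant="add")
    if form == "quadratic":
        return sm.add_constant(np.column_stack([x, x**2]), has_constant="add")
    raise ValueError(f"unknown form {form!r}")


_PARAM_NAMES = {
    "linear": ["intercept", "slope"],
    "exponential": ["intercept", "slope"],
    "power": ["intercept", "slope"],
    "quadratic": ["intercept", "slope", "quad"],
}


def _predict_original(form: str, params: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = _design(form, x)
    eta = X @ params
    return np.exp(eta) if form in ("exponential", "power") else eta


def _derivative_at(form: str, params: np.ndarray, x0: float) -> float:
    if form == "linear":
        return float(params[1])
    if form == "quadratic":
        return float(params[1] + 2.0 * params[2] * x0)
    y0 = float(_predict_original(form, params, np.array([x0]))[0])
    if form == "exponential":
        return float(params[1]) * y0
    return float(params[1]) * y0 / x0  # power


def _original_scale_aic(
    form: str, params: np.ndarray, x, y, w
) -> float:
    """Gaussian AIC with residuals on the original response scale.

    Log-response fits are back-transformed before residuals are taken so
    identity- and log-scale candidates compete on one likelihood; the
    weighted residual variance uses the same (unnormalized) weights for
    every form, so weight scaling cancels out of the comparison.
    """
    resid = y - _predict_original(form, params, x)
    n = len(y)
    wrss = float(np.sum(w * resid**2))
    k = len(params) + 1  # coefficients + residual variance
    if wrss <= 0:
        return -math.inf  # perfect fit
    sigma2 = wrss / n
    llf = -0.5 * n * (math.log(2 * math.pi) + math.log(sigma2) + 1.0) + 0.5 * float(
        np.sum(np.log(w))
    )
    return 2 * k - 2 * llf


def _standardized_slope(form, x, y, w) -> tuple[float, float]:
    """Linear-term coefficient after z-scoring predictor and response.

    Computed on the model's own scales (log where the form is fitted in
    logs) with the series weights, giving a dimensionless effect size
    whose magnitude is comparable across variables measured in different
    units.
    """
    u = np.log(x) if form == "power" else x.astype(float)
    v = np.log(y) if form in ("exponential", "power") else y.astype(float)
    su, sv = u.std(ddof=0), v.std(ddof=0)
    if su == 0 or sv == 0:
        return 0.0, 0.0
    uz, vz = (u - u.mean()) / su, (v - v.mean()) / sv
    X = sm.add_constant(np.column_stack([uz, uz**2])) if form == "quadratic" else sm.add_constant(uz)
    res = sm.WLS(vz, X, weights=w).fit()
    return float(res.params[1]), float(res.bse[1])


def fit_candidates(
    series: TrendSeries, forms=FORMS, min_points: int = 5
) -> list[ModelFit]:
    """Fit every candidate form to a series' usable smoothed points.

    Log-response forms are skipped (with a log entry) when the response
    is not strictly positive.  Requires at least ``min_points`` usable
    years; the quadratic consumes the most degrees of freedom, and
    shorter series are considered unfittable altogether.
    """
    x, y, w = series.fit_points()
    if len(x) < min_points:
        raise ValueError(
            f"series {series.label} has {len(x)} usable years; need {min_points}"
        )
    fits: list[ModelFit] = []
    for form in forms:
        log_response = form in ("exponential", "power")
        if log_response and (y <= 0).any():
            log.info("skipping %s fit for %s: non-positive response", form, series.label)
            continue
        yfit = np.log(y) if log_response else y
        X = _design(form, x)
        res = sm.WLS(yfit, X, weights=w).fit()

        resid = res.resid
        if np.allclose(resid, 0.0, atol=1e-12):
            shapiro_p = 1.0  # exact fit: nothing to test
        else:
            shapiro_p = float(stats.shapiro(resid).pvalue)
        yhat = _predict_original(form, res.params, x)
        start, end = float(yhat[0]), float(yhat[-1])
        std_slope, std_slope_se = _standardized_slope(form, x, y, w)
        names = _PARAM_NAMES[form]
        fits.append(
            ModelFit(
                form=form,
                params=dict(zip(names, (float(p) for p in res.params))),
                bse=dict(zip(names, (float(s) for s in res.bse))),
                r2=float(res.rsquared),
                p_value=float(res.f_pvalue),
                aic=_original_scale_aic(form, res.params, x, y, w),
                shapiro_p=shapiro_p,
                dw=float(durbin_watson(resid)),
                n=len(x),
                net_change=end - start,
                net_change_pct=100.0 * (end - start) / start if start != 0 else math.nan,
                derivative_start=_derivative_at(form, res.params, x[0]),
                std_slope=std_slope,
                std_slope_se=std_slope_se,
            )
        )
    return fits


def select_model(fits: list[ModelFit], alpha: float = 0.05) -> ModelFit | None:
    """Pick the best candidate: minimal AIC among significant fits whose
    residuals look normal; fall back to significant fits flagged
    ``normality_violated``; None when nothing is significant.

    Durbin-Watson outside [1, 3] adds an ``autocorrelated`` flag on the
    winner but never vetoes it.
    """
    if not fits:
        raise ValueError("no candidate fits to select from")
    for f in fits:
        f.selected = False
    significant = [f for f in fits if f.p_value < alpha]
    if not significant:
        return None
    normal = [f for f in significant if f.shapiro_p >= alpha]
    pool = normal or significant
    best = min(pool, key=lambda f: f.aic)
    best.selected = True
    if not normal:
        best.flags.append("normality_violated")
    if not (1.0 <= best.dw <= 3.0):
        best.flags.append("autocorrelated")
    return best


def p_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _fmt(v: float) -> str:
    """2 significant digits for small coefficients, 1 decimal above 10."""
    if v == 0:
        return "0"
    if abs(v) >= 10:
        return f"{round(v, 1):g}"
    return f"{float(f'{v:.2g}'):g}"


def equation_string(fit: ModelFit) -> str:
    """Human-readable fitted equation, 2 significant decimals."""
    b = fit.params

    def tail(intercept: float) -> str:
        return f" - {_fmt(-intercept)}" if intercept < 0 else f" + {_fmt(intercept)}"

    if fit.form == "linear":
        return f"y = {_fmt(b['slope'])}x{tail(b['intercept'])}"
    if fit.form == "quadratic":
        sq = b["quad"]
        sq_part = f" - {_fmt(-sq)}x2" if sq < 0 else f" + {_fmt(sq)}x2"
        return f"y = {_fmt(b['slope'])}x{sq_part}{tail(b['intercept'])}"
    if fit.form == "exponential":
        return f"log(y) = {_fmt(b['slope'])}x{tail(b['intercept'])}"
    return f"log(y) = {_fmt(b['slope'])} log(x){tail(b['intercept'])}"


# ---------------------------------------------------------------------------
# series construction from filtered records


def _annual(frame: pd.DataFrame, years: np.ndarray, col: str, how: str) -> np.ndarray:
    grouped = frame.groupby("year")[col].agg(how)
    return grouped.reindex(years).to_numpy(dtype=float)


def build_series(
    records: pd.DataFrame,
    attributes: pd.DataFrame,
    classifications: dict,
    dominance: float = 0.10,
    species_coverage: float = 0.70,
    min_fish: int = 50,
    window: int = 3,
    timeframes: dict | None = None,
) -> list[TrendSeries]:
    """Assemble every dependent-variable series the analysis tracks.

    Per fishery (restricted to its reporting timeframe when given):

    * percent contribution of each dominant family (> ``dominance`` of
      the fishery's biomass) and of the pooled remainder ("other fishes");
    * large:small biomass ratio per dominant family with usable size
      classes;
    * mean fork length of the "other fishes" pool;
    * percent contribution of large iconic species, when present;
    * per-species percent contribution and mean size for the species
      cumulatively making up ``species_coverage`` of biomass, each with
      at least ``min_fish`` measured fish.

    Percent-contribution values are biomass percentages; weights are the
    fishery-year landed kilograms for biomass variables and the group's
    annual fish count for size variables.  Series are emitted regardless
    of length; those with fewer than 5 usable years report
    ``fittable == False``.
    """
    from .sizeclass import large_small_ratio  # local: avoids import cycle

    iconic_species = set(attributes.loc[attributes["iconic"], "species"])
    out: list[TrendSeries] = []

    for fishery, sub in records.groupby("fishery"):
        if timeframes and timeframes.get(fishery):
            y0, y1 = timeframes[fishery]
            sub = sub.loc[(sub["year"] >= y0) & (sub["year"] <= y1)]
        if sub.empty:
            continue
        years = np.arange(sub["year"].min(), sub["year"].max() + 1)
        total_kg = _annual(sub, years, "biomass_kg", "sum")
        total_kg = np.nan_to_num(total_kg)
        kg_weights = total_kg.copy()

        def pct_series(mask_frame: pd.DataFrame) -> np.ndarray:
            kg = np.nan_to_num(_annual(mask_frame, years, "biomass_kg", "sum"))
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(total_kg > 0, 100.0 * kg / total_kg, np.nan)

        fam_share = sub.groupby("family")["biomass_kg"].sum() / sub["biomass_kg"].sum()
        dominant = sorted(fam_share.index[fam_share > dominance])

        for family in dominant:
            fam_frame = sub.loc[sub["family"] == family]
            out.append(
                TrendSeries.from_raw(
                    fishery, "family_pct", family, years,
                    pct_series(fam_frame), kg_weights, window,
                )
            )
            cls = classifications.get(family)
            if cls is not None and cls.usable:
                table = large_small_ratio(fam_frame, cls).set_index("year")
                ratio = table["ratio"].reindex(years).to_numpy(dtype=float)
                fam_kg = np.nan_to_num(_annual(fam_frame, years, "biomass_kg", "sum"))
                out.append(
                    TrendSeries.from_raw(
                        fishery, "ratio", family, years, ratio, fam_kg, window
                    )
                )

        others = sub.loc[~sub["family"].isin(dominant)]
        if not others.empty:
            out.append(
                TrendSeries.from_raw(
                    fishery, "other_pct", "other fishes", years,
                    pct_series(others), kg_weights, window,
                )
            )
            counts = np.nan_to_num(_annual(others, years, "count", "sum"))
            out.append(
                TrendSeries.from_raw(
                    fishery, "mean_size_mm", "other fishes", years,
                    _annual(others, years, "fork_length_mm", "mean"), counts, window,
                )
            )

        iconic_frame = sub.loc[sub["species"].isin(iconic_species)]
        if not iconic_frame.empty:
            out.append(
                TrendSeries.from_raw(
                    fishery, "iconic_pct", "iconic", years,
                    pct_series(iconic_frame), kg_weights, window,
                )
            )

        # species-level series: biomass-ranked head reaching the coverage cut
        sp_kg = sub.groupby("species")["biomass_kg"].sum().sort_values(ascending=False)
        shares = sp_kg / sp_kg.sum()
        cum = shares.cumsum()
        n_keep = int(np.searchsorted(cum.to_numpy(), species_coverage) + 1)
        head = list(shares.index[: min(n_keep, len(shares))])
        sp_counts = sub.groupby("species")["count"].sum()
        for species in head:
            if sp_counts.get(species, 0) < min_fish:
                continue
            sp_frame = sub.loc[sub["species"] == species]
            out.append(
                TrendSeries.from_raw(
                    fishery, "species_pct", species, years,
                    pct_series(sp_frame), kg_weights, window,
                )
            )
            counts = np.nan_to_num(_annual(sp_frame, years, "count", "sum"))
            out.append(
                TrendSeries.from_raw(
                    fishery, "species_size_mm", species, years,
                    _annual(sp_frame, years, "fork_length_mm", "mean"), counts, window,
                )
            )
    return out


def fits_table(results: list[tuple[TrendSeries, ModelFit | None]]) -> pd.DataFrame:
    """Summary table of selected fits, one row per series."""
    rows = []
    for series, fit in results:
        if fit is None:
            rows.append(
                {
                    "fishery": series.fishery,
                    "group": series.group,
                    "dependent_variable": series.unit,
                    "equation": "",
                    "r2": np.nan,
                    "p_stars": "",
                    "aic": np.nan,
                    "net_change_pct": np.nan,
                    "flags": "no_significant_model",
                }
            )
        else:
            rows.append(
                {
                    "fishery": series.fishery,
                    "group": series.group,
                    "dependent_variable": series.unit,
                    "equation": equation_string(fit),
                    "r2": round(fit.r2, 2),
                    "p_stars": p_stars(fit.p_value),
                    "aic": round(fit.aic, 1),
                    "net_change_pct": round(fit.net_change_pct, 1),
                    "flags": ";".join(fit.flags),
                }
            )
    return pd.DataFrame(rows)
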