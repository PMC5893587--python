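"""Assign potential-management categories from paired trend fits.

For each heavily landed species two selected trends are compared: mean
fork length ("size") and percent contribution to landings
("contribution").  A species whose size structure erodes faster than its
presence in the catch is a candidate for size-based policies (minimum or
slot limits); one that fades out of the fishery while its sizes hold is
a candidate for gear, quota or area policies.  Four ordered criteria
resolve every case:

1. a curved model with an immediate decline (saturating drop, or a
   quadratic falling from the first year) outranks a linear decline, and
   a lone declining variable wins outright;
2. when both variables decline under the same model strength, their
   standardized effect sizes are compared: non-overlapping +/-1 SE
   intervals give the category of the larger-magnitude effect;
3. overlapping intervals make the two strategies equal ("both_either");
4. species with no significant declines (stable or increasing trends)
   are placed in no category.

A significant *increase* in one variable never blocks classification by
a decline in the other; criterion 4 only voids species with no declines
at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .trends import ModelFit

CATEGORY_SIZE = "size"
CATEGORY_GEAR = "gear_quota_area"
CATEGORY_BOTH = "both_either"
CATEGORY_NONE = "none"

#: strategy -> how to measure an effect size for criterion 2
EFFECT_MEASURES = ("standardized_slope", "net_change_frac")


@dataclass
class ManagementAssignment:
    species: str
    fishery: str
    category: str
    rationale: int  # index of the criterion that resolved the case
    size_fit: ModelFit | None = None
    contribution_fit: ModelFit | None = None
    detail: str = ""


def _effect_interval(fit: ModelFit, measure: str) -> tuple[float, float]:
    """(|effect|, SE) for the chosen effect-size measure."""
    if measure == "standardized_slope":
        return abs(fit.std_slope), fit.std_slope_se
    if measure == "net_change_frac":
        # fractional net change with no sampling SE available -> point value
        return abs(fit.net_change_pct) / 100.0, 0.0
    raise ValueError(f"unknown effect measure {measure!r}")


def classify(
    size_fit: ModelFit | None,
    contribution_fit: ModelFit | None,
    species: str = "",
    fishery: str = "",
    effect_measure: str = "standardized_slope",
) -> ManagementAssignment:
    """Apply the four-criterion decision rule to one species' fits.

    ``size_fit`` and ``contribution_fit`` are the *selected* models (or
    None when no candidate was significant); significance is therefore
    implied by presence.
    """
    size_declining = size_fit is not None and size_fit.declining
    contrib_declining = contribution_fit is not None and contribution_fit.declining

    if not size_declining and not contrib_declining:
        return ManagementAssignment(
            species, fishery, CATEGORY_NONE, 4,
            size_fit, contribution_fit,
            detail="no significant declining trend",
        )
    if size_declining != contrib_declining:
        if size_declining:
            return ManagementAssignment(
                species, fishery, CATEGORY_SIZE, 1, size_fit, contribution_fit,
                detail="only the size trend declines",
            )
        return ManagementAssignment(
            species, fishery, CATEGORY_GEAR, 1, size_fit, contribution_fit,
            detail="only the contribution trend declines",
        )

    # both decline: compare model strength first
    s_strength = size_fit.strength_class
    c_strength = contribution_fit.strength_class
    if s_strength != c_strength:
        winner = CATEGORY_SIZE if s_strength == "strong" else CATEGORY_GEAR
        return ManagementAssignment(
            species, fishery, winner, 1, size_fit, contribution_fit,
            detail=f"model strength {s_strength} (size) vs {c_strength} (contribution)",
        )

    s_eff, s_se = _effect_interval(size_fit, effect_measure)
    c_eff, c_se = _effect_interval(contribution_fit, effect_measure)
    overlap = (s_eff - s_se) <= (c_eff + c_se) and (c_eff - c_se) <= (s_eff + s_se)
    if overlap:
        return ManagementAssignment(
            species, fishery, CATEGORY_BOTH, 3, size_fit, contribution_fit,
            detail=f"effects overlap: {s_eff:.2f}±{s_se:.2f} vs {c_eff:.2f}±{c_se:.2f}",
        )
    winner = CATEGORY_SIZE if s_eff > c_eff else CATEGORY_GEAR
    return ManagementAssignment(
        species, fishery, winner, 2, size_fit, contribution_fit,
        detail=f"effects separate: {s_eff:.2f}±{s_se:.2f} vs {c_eff:.2f}±{c_se:.2f}",
    )


def summarize(assignments: list[ManagementAssignment]) -> dict:
    """Category counts and proportions, per fishery and overall.

    ``placed_fraction`` is the share of assessed species given any
    category; within-category proportions are over placed species only.
    A consistency table lists species assessed in more than one fishery
    and whether their categories agree.
    """
    if not assignments:
        raise ValueError("no assignments to summarize")
    df = pd.DataFrame(
        {
            "species": [a.species for a in assignments],
            "fishery": [a.fishery for a in assignments],
            "category": [a.category for a in assignments],
        }
    )

    def block(frame: pd.DataFrame) -> dict:
        placed = frame.loc[frame["category"] != CATEGORY_NONE]
        counts = frame["category"].value_counts().to_dict()
        out = {
            "n_assessed": int(len(frame)),
            "n_placed": int(len(placed)),
            "placed_fraction": len(placed) / len(frame),
            "counts": {c: int(counts.get(c, 0)) for c in
                       (CATEGORY_SIZE, CATEGORY_GEAR, CATEGORY_BOTH, CATEGORY_NONE)},
        }
        if len(placed):
            out["placed_proportions"] = {
                c: float((placed["category"] == c).mean())
                for c in (CATEGORY_SIZE, CATEGORY_GEAR, CATEGORY_BOTH)
            }
        return out

    summary = {"overall": block(df), "per_fishery": {}}
    for fishery, frame in df.groupby("fishery"):
        summary["per_fishery"][str(fishery)] = block(frame)

    multi = df.groupby("species")["fishery"].nunique()
    cross = []
    for species in multi.index[multi > 1]:
        cats = df.loc[df["species"] == species]
        cross.append(
            {
                "species": species,
                "fisheries": sorted(cats["fishery"]),
                "categories": list(cats["category"]),
                "consistent": cats["category"].nunique() == 1,
            }
        )
    summary["cross_fishery"] = cross
    return summary


def assignments_table(
    assignments: list[ManagementAssignment],
    biomass_share: dict[tuple[str, str], float] | None = None,
    n_fish: dict[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """Species table in the style of a landings-trend report."""
    from .trends import p_stars

    def cell(fit: ModelFit | None) -> str:
        if fit is None:
            return "—"
        return f"{fit.r2:.2f}{p_stars(fit.p_value)}"

    rows = []
    for a in assignments:
        key = (a.fishery, a.species)
        rows.append(
            {
                "fishery": a.fishery,
                "species": a.species,
                "n": (n_fish or {}).get(key, pd.NA),
                "proportional_biomass_pct": (biomass_share or {}).get(key, pd.NA),
                "size_r2_stars": cell(a.size_fit),
                "contribution_r2_stars": cell(a.contribution_fit),
                "potential_management": a.category,
                "criterion": a.rationale,
            }
        )
    return pd.DataFrame(rows)
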