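"""Body-size classes from natural breaks on maximum length, and the
large:small biomass ratio built on them.

Within each target family, species are split into 2 or 3 body-size
categories by their maximum fork lengths using Fisher's optimal 1-D
partitioning ("Jenks natural breaks"): the exact dynamic program that
minimizes the total within-class sum of squared deviations over all
ordered partitions.  Classification quality is summarized by the
goodness of variance fit, gvf = 1 - SSD_within / SSD_total.

The number of classes follows the range of sizes in the family: three
classes are used only when they explain appreciably more variance than
two (gvf gain >= 0.10 by default); families with fewer than three
species cannot support a split and are excluded from ratio analyses.

The large:small ratio for a family-year is the summed biomass of all
classes above the smallest divided by the biomass of the smallest class
— a size-structure indicator that collapses as large-bodied species drop
out of the landings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _ssd_matrix_terms(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s1 = np.concatenate([[0.0], np.cumsum(values)])
    s2 = np.concatenate([[0.0], np.cumsum(values**2)])
    return s1, s2


def _segment_ssd(s1: np.ndarray, s2: np.ndarray, i: int, j: int) -> float:
    """SSD of sorted_values[i..j] inclusive (0-based)."""
    m = j - i + 1
    total = s1[j + 1] - s1[i]
    return float(s2[j + 1] - s2[i] - total * total / m)


def fisher_partition(sorted_values: np.ndarray, k: int) -> tuple[list[int], float]:
    """Optimal ordered partition of sorted values into k contiguous classes.

    Returns the class sizes (in order) and the minimal total within-class
    SSD.  Ties between equally optimal partitions are broken toward the
    smallest leading-class cardinalities, by always preferring the
    smallest feasible boundary when costs are equal.
    """
    n = len(sorted_values)
    if k < 1 or k > n:
        raise ValueError(f"cannot split {n} values into {k} classes")
    s1, s2 = _ssd_matrix_terms(sorted_values)

    # dp[m][j] = minimal cost of splitting the first j values into m classes
    dp = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    dp[0][0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best = np.inf
            arg = m - 1
            for i in range(m - 1, j):
                cost = dp[m - 1][i] + _segment_ssd(s1, s2, i, j - 1)
                if cost < best:  # strict: first (smallest) i wins ties
                    best = cost
                    arg = i
            dp[m][j] = best
            split[m][j] = arg

    sizes: list[int] = []
    j = n
    for m in range(k, 0, -1):
        i = split[m][j]
        sizes.append(j - i)
        j = i
    sizes.reverse()
    return sizes, float(dp[k][n])


def goodness_of_variance_fit(values: np.ndarray, within_ssd: float) -> float:
    values = np.asarray(values, dtype=float)
    total = float(np.sum((values - values.mean()) ** 2))
    if total == 0.0:
        return 1.0
    return 1.0 - within_ssd / total


def jenks_breaks(values, k: int) -> tuple[list[float], np.ndarray, float]:
    """Natural-breaks classification of ``values`` into ``k`` classes.

    Returns ``(breaks, assignment, gvf)`` where ``breaks`` are the k-1
    internal cut points (the maxima of classes 1..k-1, ascending),
    ``assignment`` gives each input value's class index (1 = smallest
    class, in input order) and ``gvf`` the goodness of variance fit.
    Classes are contiguous in sorted order and the partition is the
    exact SSD optimum; the result is deterministic and invariant to the
    input order and to positive affine rescaling of the values.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if k < 2:
        raise ValueError("need at least 2 classes; use a sentinel for fewer")
    n_distinct = len(np.unique(values))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct values")

    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    sizes, within = fisher_partition(sorted_vals, k)

    assignment = np.empty(len(values), dtype=int)
    start = 0
    for cls, size in enumerate(sizes, start=1):
        assignment[order[start : start + size]] = cls
        start += size
    breaks = [float(sorted_vals[e - 1]) for e in np.cumsum(sizes)[:-1]]
    return breaks, assignment, goodness_of_variance_fit(values, within)


def choose_k(values, gvf_increment: float = 0.10) -> int:
    """Pick 2 or 3 size classes for a family's maximum lengths.

    Three classes are chosen only when they raise the goodness of
    variance fit by at least ``gvf_increment`` over two; otherwise two.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 species to form size classes")
    n_distinct = len(np.unique(values))
    if n_distinct < 2:
        raise ValueError("all maximum lengths identical; no classes possible")
    _, _, gvf2 = jenks_breaks(values, 2)
    if n_distinct < 3:
        return 2
    _, _, gvf3 = jenks_breaks(values, 3)
    return 3 if gvf3 - gvf2 >= gvf_increment else 2


@dataclass
class SizeClassification:
    """Per-family size classes: cut points and species assignments."""

    family: str
    n_classes: int
    breaks: list[float]
    assignment: dict[str, int]  # species -> class index, 1 = smallest-bodied
    gvf: float
    note: str = ""

    @property
    def usable(self) -> bool:
        return self.n_classes >= 2


def classify_family_sizes(
    attributes: pd.DataFrame,
    families=None,
    gvf_increment: float = 0.10,
    overrides: dict[str, dict[str, int]] | None = None,
) -> dict[str, SizeClassification]:
    """Size-classify every family's species by maximum length.

    Families with fewer than 3 species (or no size variation) get a
    single-class sentinel and are skipped by ratio analyses.
    ``overrides`` pins explicit species -> class maps for chosen families
    in place of the natural-breaks result.
    """
    overrides = overrides or {}
    out: dict[str, SizeClassification] = {}
    wanted = families if families is not None else attributes["family"].unique()
    for family in wanted:
        sub = attributes.loc[attributes["family"] == family]
        species = list(sub["species"])
        lengths = sub["max_length_mm"].to_numpy(dtype=float)
        if family in overrides:
            assignment = dict(overrides[family])
            out[family] = SizeClassification(
                family=family,
                n_classes=max(assignment.values()),
                breaks=[],
                assignment=assignment,
                gvf=float("nan"),
                note="override",
            )
            continue
        if len(species) < 3 or len(np.unique(lengths)) < 2:
            out[family] = SizeClassification(
                family=family,
                n_classes=1,
                breaks=[],
                assignment={s: 1 for s in species},
                gvf=float("nan"),
                note="insufficient",
            )
            continue
        k = choose_k(lengths, gvf_increment=gvf_increment)
        breaks, assignment, gvf = jenks_breaks(lengths, k)
        out[family] = SizeClassification(
            family=family,
            n_classes=k,
            breaks=breaks,
            assignment=dict(zip(species, (int(c) for c in assignment))),
            gvf=gvf,
        )
    return out


def classification_table(classes: dict[str, SizeClassification]) -> pd.DataFrame:
    rows = []
    for family, cls in classes.items():
        for species, idx in cls.assignment.items():
            rows.append(
                {
                    "family": family,
                    "species": species,
                    "class_index": idx,
                    "n_classes": cls.n_classes,
                    "break_points": ";".join(f"{b:g}" for b in cls.breaks),
                    "gvf": cls.gvf,
                    "note": cls.note,
                }
            )
    return pd.DataFrame(rows)


def large_small_ratio(
    records: pd.DataFrame,
    classification: SizeClassification,
    year: int | None = None,
) -> pd.DataFrame:
    """Large:small biomass ratio per fishery-year for one family.

    Ratio = biomass of classes >= 2 over biomass of class 1.  Years whose
    smallest class landed nothing yield a missing ratio (NaN), which
    downstream regressions drop from the fitted points.
    """
    if not classification.usable:
        raise ValueError(
            f"family {classification.family!r} has no usable size classes"
        )
    sub = records.loc[records["family"] == classification.family].copy()
    if year is not None:
        sub = sub.loc[sub["year"] == year]
    sub["size_class"] = sub["species"].map(classification.assignment)
    grouped = (
        sub.groupby(["fishery", "year"])
        .apply(
            lambda g: pd.Series(
                {
                    "small_kg": g.loc[g["size_class"] == 1, "biomass_kg"].sum(),
                    "large_kg": g.loc[g["size_class"] >= 2, "biomass_kg"].sum(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        grouped["ratio"] = np.where(
            grouped["small_kg"] > 0, grouped["large_kg"] / grouped["small_kg"], np.nan
        )
    grouped["family"] = classification.family
    return grouped[["fishery", "family", "year", "small_kg", "large_kg", "ratio"]]
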