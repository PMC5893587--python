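"""Fit weighted trend models to every dependent-variable series.

Builds smoothed annual series (family contributions, large:small
ratios, other-fish sizes, iconic contributions, per-species trends),
fits the four candidate forms by weighted least squares and selects the
best by AIC subject to residual normality.
"""

import json
import pickle
from pathlib import Path

import pandas as pd

from creeltrends.io import read_attributes_csv
from creeltrends.sizeclass import classify_family_sizes
from creeltrends.trends import build_series, fit_candidates, fits_table, select_model

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    scratch = ROOT / "scratch" / "analysis"
    results = ROOT / "results" / "analysis"
    filtered = pd.read_csv(scratch / "filtered.csv")
    attributes = read_attributes_csv(results / "attributes.csv")
    with open(results / "timeframes.json") as fh:
        timeframes = {
            k: tuple(v) if v else None for k, v in json.load(fh).items()
        }

    classes = classify_family_sizes(
        attributes.loc[attributes["species"].isin(filtered["species"].unique())]
    )
    series = build_series(filtered, attributes, classes, timeframes=timeframes)
    fitted = unfittable = 0
    results_list = []
    for s in series:
        if not s.fittable:
            unfittable += 1
            results_list.append((s, None))
            continue
        best = select_model(fit_candidates(s))
        fitted += best is not None
        results_list.append((s, best))
    table = fits_table(results_list)
    table.to_csv(results / "trend_fits.csv", index=False)
    with open(scratch / "fit_results.pkl", "wb") as fh:
        pickle.dump(results_list, fh)

    print(f"{len(series)} series; {fitted} with a selected model, "
          f"{unfittable} too short to fit")
    selected = table.loc[table["equation"] != ""]
    print(selected.to_string(index=False, max_colwidth=34))


if __name__ == "__main__":
    main()
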