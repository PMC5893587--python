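"""Assign potential-management categories to the dominant species.

Pairs each assessed species' mean-size and percent-contribution trend
fits and applies the four-criterion rule: species hit hardest in size
structure point to size-based policies; species fading from the catch
point to gear/quota/area policies.
"""

import json
import pickle
from pathlib import Path

from creeltrends.management import assignments_table, classify, summarize

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    scratch = ROOT / "scratch" / "analysis"
    results = ROOT / "results" / "analysis"
    with open(scratch / "fit_results.pkl", "rb") as fh:
        fit_results = pickle.load(fh)

    selected = {(s.fishery, s.unit, s.group): fit for s, fit in fit_results}
    pairs = sorted(
        {(s.fishery, s.group) for s, _ in fit_results
         if s.unit in ("species_pct", "species_size_mm")}
    )
    assignments = [
        classify(
            selected.get((fishery, "species_size_mm", species)),
            selected.get((fishery, "species_pct", species)),
            species=species,
            fishery=fishery,
        )
        for fishery, species in pairs
    ]
    assignments_table(assignments).to_csv(
        results / "species_management.csv", index=False
    )
    summary = summarize(assignments)
    with open(results / "management_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)

    overall = summary["overall"]
    print(f"{overall['n_assessed']} species assessed across fisheries; "
          f"{100 * overall['placed_fraction']:.0f}% placed in a category")
    if "placed_proportions" in overall:
        for cat, frac in overall["placed_proportions"].items():
            print(f"  {cat}: {100 * frac:.0f}% of placed species")
    for entry in summary["cross_fishery"]:
        tag = "consistent" if entry["consistent"] else "DIFFERS"
        print(f"  {entry['species']} assessed in {len(entry['fisheries'])} "
              f"fisheries: {tag}")


if __name__ == "__main__":
    main()
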