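"""Filter the simulated landings and determine each fishery's timeframe.

Applies the exclusion filters (location, measurement validity, <1%
families, <1% species-within-family) and the 50 kg/yr rolling-average
reporting rule, printing the exact accounting of what was removed.
"""

import json
from pathlib import Path

from creeltrends.filters import FilterConfig, apply_filters, fishery_timeframe
from creeltrends.io import read_attributes_csv, read_catch_csv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    scratch = ROOT / "scratch" / "analysis"
    results = ROOT / "results" / "analysis"
    records = read_catch_csv(scratch / "catch.csv")
    attributes = read_attributes_csv(results / "attributes.csv")

    filtered, report = apply_filters(records, attributes, FilterConfig())
    report.to_json(results / "filter_report.json")
    filtered.to_csv(scratch / "filtered.csv", index=False)

    timeframes = fishery_timeframe(filtered, threshold_kg_per_yr=50.0)
    with open(results / "timeframes.json", "w") as fh:
        json.dump({k: list(v) if v else None for k, v in timeframes.items()}, fh, indent=2)

    for line in report.log_lines():
        print(line)
    print("analysis timeframes:", timeframes)


if __name__ == "__main__":
    main()
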