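"""Validate the statistical machinery against independent oracles.

Runs the controlled experiments — natural-breaks vs exhaustive search,
WLS degeneracies, quadratic parameter recovery, type-I control on flat
series, saturating-curve selection, end-to-end classification recovery,
filter accounting and the timeframe rule — and writes their numbers.
"""

import argparse
import json
from pathlib import Path

from creeltrends import experiments as ex

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    seed = args.seed

    out = {
        "jenks_vs_bruteforce": ex.jenks_vs_bruteforce(500, seed=seed),
        "wls_degeneracy": ex.wls_degeneracy_check(seed=seed),
        "quadratic_recovery": ex.quadratic_recovery(500, seed=seed),
        "saturating_selection": ex.saturating_selection(200, seed=seed),
        "type1": ex.type1_rate(200, seed=seed),
        "classification_recovery": {
            k: v for k, v in ex.classification_recovery(seed=seed).items()
            if k != "per_species"
        },
        "filter_accounting": {
            k: v for k, v in ex.filter_accounting(seed=seed).items()
            if k != "report"
        },
        "timeframe_example": ex.timeframe_example(),
    }
    results = ROOT / "results" / "analysis"
    results.mkdir(parents=True, exist_ok=True)
    with open(results / "validation.json", "w") as fh:
        json.dump(out, fh, indent=2, default=str)

    rec = out["quadratic_recovery"]
    print("natural breaks agree with exhaustive search:",
          f"{out['jenks_vs_bruteforce']['n_agree']}/500")
    print("quadratic coefficient recovery |z|:",
          {k: round(abs(v), 2) for k, v in rec["z"].items()})
    print("quadratic selection rate:", rec["quadratic_selection_rate"],
          "(saturating forms absorb weakly humped declines; see docs/methods.md)")
    print("saturating-curve selection rate:",
          out["saturating_selection"]["log_family_selection_rate"])
    print("flat-series selection (type-I) rate:", out["type1"]["selected_rate"])
    print("classification recovery:",
          out["classification_recovery"]["recovered_counts"],
          "planted", out["classification_recovery"]["planted_counts"])


if __name__ == "__main__":
    main()
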