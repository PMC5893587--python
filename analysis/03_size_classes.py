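"""Classify species into body-size categories within each family.

Natural-breaks (Fisher-optimal) partitioning of maximum fork lengths,
2 or 3 classes per family depending on the spread of sizes; families
with too few species are flagged and excluded from ratio analyses.
"""

from pathlib import Path

from creeltrends.io import read_attributes_csv
from creeltrends.sizeclass import classification_table, classify_family_sizes

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results" / "analysis"
    attributes = read_attributes_csv(results / "attributes.csv")
    classes = classify_family_sizes(attributes)
    classification_table(classes).to_csv(results / "size_classes.csv", index=False)

    for family, cls in sorted(classes.items()):
        if cls.usable:
            print(f"{family}: {cls.n_classes} classes, breaks at "
                  f"{[f'{b:.0f} mm' for b in cls.breaks]}, gvf={cls.gvf:.3f}")
        else:
            print(f"{family}: single class ({cls.note}); excluded from ratios")


if __name__ == "__main__":
    main()
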