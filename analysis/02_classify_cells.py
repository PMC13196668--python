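#!/usr/bin/env python
"""Classify every simulated organ by Fisher-Jenks marker thresholding.

Reads the cohort tables from 01, thresholds each organ's two marker
channels independently, assigns hair-cell types, and reports per-cohort
type proportions (the real wild-type split is 49/47/4%).
"""

from pathlib import Path

import pandas as pd

from utriclemap.io import load_cell_table, save_cell_table
from utriclemap.quantify import classify_cells
from utriclemap.stats import proportion_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "classified"
    frames = []
    for path in sorted((ROOT / "cohorts").glob("*_[0-9][0-9].csv")):
        table = classify_cells(load_cell_table(path))
        table["organ_id"] = path.stem
        save_cell_table(table, out / path.name)
        frames.append(table)
    pooled = pd.concat(frames, ignore_index=True)
    pooled["cohort"] = pooled["organ_id"].str.rsplit("_", n=1).str[0]
    for cohort, sub in pooled.groupby("cohort"):
        props = proportion_table(sub)
        acc = (sub["type"] == sub["true_type"]).mean()
        print(f"{cohort}: n={len(sub)}, recovery {acc:.1%}")
        print(props.to_string(index=False))
        props.to_csv(out / f"proportions_{cohort}.csv", index=False)


if __name__ == "__main__":
    main()
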