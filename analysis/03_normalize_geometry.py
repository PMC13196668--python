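#!/usr/bin/env python
"""Map every classified organ into the common unit-circle polar frame.

Concave hull -> ellipse fit -> canonical rotation (marker-majority
orientation) -> unit-circle radius normalization.  Writes the pooled
normalized table and per-organ geometry records.
"""

from pathlib import Path

import pandas as pd

from utriclemap.geometry import normalize_organ
from utriclemap.io import load_cell_table, save_cell_table, save_json

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    frames, geoms = [], {}
    for path in sorted((ROOT / "classified").glob("*_[0-9][0-9].csv")):
        table = load_cell_table(path)
        normalized, geom = normalize_organ(table)
        normalized["organ_id"] = path.stem
        frames.append(normalized)
        geoms[path.stem] = geom
    pooled = pd.concat(frames, ignore_index=True)
    save_cell_table(pooled, ROOT / "normalized_pooled.csv")
    save_json(geoms, ROOT / "organ_geometry.json")
    medial = ((pooled["theta_deg"] > 180) & (pooled["type"] == "extrastriolar")).sum()
    n_es = (pooled["type"] == "extrastriolar").sum()
    print(f"pooled {len(pooled)} cells from {len(frames)} organs")
    print(f"extrastriolar cells in medial half: {medial}/{n_es} ({medial / n_es:.0%})")


if __name__ == "__main__":
    main()
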