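#!/usr/bin/env python
"""Simulate the study cohorts.

Generates a wild-type-like cohort of ten utricles (~73 hair cells each,
matching the ten-ear / 703-cell pooled sample of the real experiment) at
random orientations and ear sides, plus a photoconversion cohort in which
~23% of cells are flagged early-born with the observed 81% medial bias.
Writes one cell table per organ under results/cohorts/.
"""

from pathlib import Path

import numpy as np

from utriclemap.io import save_cell_table, save_json
from utriclemap.simulate import SimParams, generate_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"
SEED = 2026


def main() -> None:
    rng = np.random.default_rng(SEED)
    manifest = {}
    for cohort, n_organs, frac_early in [("wildtype", 10, 0.0), ("photoconverted", 11, 0.23)]:
        total = 0
        for i in range(n_organs):
            params = SimParams(
                seed=int(rng.integers(2**31)),
                rotation_deg=float(rng.uniform(0, 360)),
                mirror=bool(rng.integers(2)),
                frac_early_born=frac_early,
            )
            table, geom = generate_dataset(params)
            organ = f"{cohort}_{i:02d}"
            save_cell_table(table, OUT / f"{organ}.csv")
            save_json(geom, OUT / f"{organ}_geometry.json")
            total += len(table)
        manifest[cohort] = {"n_organs": n_organs, "n_cells": total}
        print(f"{cohort}: {n_organs} organs, {total} cells")
    save_json(manifest, OUT / "cohorts.json")


if __name__ == "__main__":
    main()
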