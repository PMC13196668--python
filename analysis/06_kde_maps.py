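#!/usr/bin/env python
"""Summary kernel-density maps of zonal occupancy.

2D Gaussian KDE (Scott bandwidth) of each hair-cell type's normalized
positions on the unit disk, written as coarse CSV grids plus a composite
PNG overview under scratch/ (figures are for eyeballing only).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from utriclemap.spatial import kde_map

ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    pooled = pd.read_csv(ROOT / "normalized_pooled.csv")
    grids = {}
    for cell_type, sub in pooled[pooled["type"] != "negative"].groupby("type"):
        grid = kde_map(sub["theta_deg"], sub["r"], grid_n=50)
        grids[cell_type] = grid
        i, j = np.unravel_index(np.argmax(grid.density), grid.density.shape)
        print(
            f"{cell_type}: n={len(sub)}, bandwidth factor {grid.bandwidth_factor:.3f}, "
            f"density peak at (x={grid.x[j]:+.2f}, y={grid.y[i]:+.2f})"
        )
        pd.DataFrame(grid.density, index=grid.y, columns=grid.x).to_csv(
            ROOT / f"kde_{cell_type}.csv"
        )
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        SCRATCH.mkdir(exist_ok=True)
        fig, axes = plt.subplots(1, len(grids), figsize=(4 * len(grids), 4))
        for ax, (cell_type, grid) in zip(np.atleast_1d(axes), grids.items()):
            ax.imshow(grid.density, extent=[-1, 1, -1, 1], origin="lower", cmap="magma")
            ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, color="w", lw=0.8))
            ax.set_title(cell_type)
        fig.savefig(SCRATCH / "kde_maps.png", dpi=120)
        print(f"figure: {SCRATCH / 'kde_maps.png'}")
    except ImportError:
        pass


if __name__ == "__main__":
    main()
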