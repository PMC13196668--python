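#!/usr/bin/env python
"""Zonal sector statistics on the pooled normalized cohorts.

Per hair-cell type: exact binomial tests of sector occupancy against the
uniform-angle null (medial half for extrastriolar cells, lateral half for
striolar, boundary quarter for intermediates; early-born cells tested in
the medial half).  Also re-derives the published two-proportion z-tests
from the printed count tables as a cross-check of the test machinery.
"""

from pathlib import Path

import pandas as pd

from utriclemap.geometry import BOUNDARY_QUARTER, LATERAL_HALF, MEDIAL_HALF, sector_fraction
from utriclemap.io import save_json
from utriclemap.stats import binom_test, two_prop_z

ROOT = Path(__file__).resolve().parents[1] / "results"

PUBLISHED = [
    ("RA-treated vs control cabp1b medial", (159, 265), (302, 346)),
    ("RA-treated vs control cabp2b lateral", (80, 94), (297, 332)),
]


def main() -> None:
    pooled = pd.read_csv(ROOT / "normalized_pooled.csv")
    records = []
    for cell_type, sector in [
        ("extrastriolar", MEDIAL_HALF),
        ("striolar", LATERAL_HALF),
        ("intermediate", BOUNDARY_QUARTER),
    ]:
        mask = pooled["type"] == cell_type
        k, n = sector_fraction(pooled["theta_deg"], sector, mask=mask)
        res = binom_test(k, n, sector.null_fraction)
        records.append(
            {"subset": cell_type, "sector": sector.name, "k": k, "n": n,
             "fraction": k / n, "null": sector.null_fraction, "p": res.p_value}
        )
        print(f"{cell_type}: {k}/{n} ({k / n:.0%}) in {sector.name}, p={res.p_value:.2e}")
    early = pooled["early_born"].astype(bool)
    if early.any():
        k, n = sector_fraction(pooled["theta_deg"], MEDIAL_HALF, mask=early)
        res = binom_test(k, n, 0.5)
        records.append({"subset": "early_born", "sector": "medial_half", "k": k,
                        "n": n, "fraction": k / n, "null": 0.5, "p": res.p_value})
        print(f"early-born: {k}/{n} ({k / n:.0%}) medial, p={res.p_value:.2e}")
    for label, (k1, n1), (k2, n2) in PUBLISHED:
        z = two_prop_z(k1, n1, k2, n2)
        print(f"{label}: z={z.statistic:.2f}, p={z.p_value:.2e}")
        records.append({"subset": label, "sector": "printed_counts",
                        "k": k1, "n": n1, "z": z.statistic, "p": z.p_value})
    save_json(records, ROOT / "sector_tests.json")


if __name__ == "__main__":
    main()
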