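"""End-to-end pipeline: quantify -> classify -> normalize -> zonal stats
-> join counts -> KDE, per organ and pooled across organs."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from utriclemap import geometry, io, quantify, spatial, stats
from utriclemap.quantify import MarkerPanel
from utriclemap.simulate import TYPE_EXTRASTRIOLAR, TYPE_INTERMEDIATE, TYPE_STRIOLAR

log = logging.getLogger("utriclemap")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, JSON-serializable.

    ``sectors`` maps sector names to lists of [start, end) degree
    intervals; defaults cover the medial/lateral halves and the boundary
    quarter.  ``flip_overrides`` maps organ ids to explicit
    (flip_across_major, flip_along_major) pairs for marker-free images.
    """

    statistic: str = "mean"
    extrastriolar_channel: int = 1
    striolar_channel: int = 2
    n_classes: int = 2
    concave_k: int = 3
    orientation_policy: str = "marker-majority"
    flip_overrides: dict = field(default_factory=dict)
    sectors: dict = field(default_factory=lambda: {
        "medial_half": [[180.0, 360.0]],
        "lateral_half": [[0.0, 180.0]],
        "boundary_quarter": [[157.5, 202.5], [337.5, 22.5]],
    })
    knn_k: int = 7
    n_permutations: int = 9999
    kde_grid_n: int = 100
    kde_bandwidth_rule: str = "scott"
    seed: int = 0

    @property
    def panel(self) -> MarkerPanel:
        return MarkerPanel(
            extrastriolar_channel=self.extrastriolar_channel,
            striolar_channel=self.striolar_channel,
            statistic=self.statistic,
        )

    def sector_specs(self) -> dict[str, geometry.SectorSpec]:
        return {
            name: geometry.SectorSpec(tuple(tuple(iv) for iv in ivs), name=name)
            for name, ivs in self.sectors.items()
        }


_TYPE_SECTOR = {
    TYPE_EXTRASTRIOLAR: "medial_half",
    TYPE_STRIOLAR: "lateral_half",
    TYPE_INTERMEDIATE: "boundary_quarter",
}


def process_organ(table: pd.DataFrame, config: PipelineConfig, organ_id: str = "organ"):
    """Classify and normalize one organ's cell table."""
    classified = quantify.classify_cells(table, config.panel)
    n_neg = int((classified["type"] == "negative").sum())
    log.info("%s: %d cells, %d double-negative", organ_id, len(classified), n_neg)
    policy = config.orientation_policy
    flips = config.flip_overrides.get(organ_id, (False, False))
    if organ_id in config.flip_overrides:
        policy = "explicit"
    normalized, geom = geometry.normalize_organ(
        classified,
        orientation_policy=policy,
        flip_across_major=bool(flips[0]),
        flip_along_major=bool(flips[1]),
        concave_k=config.concave_k,
    )
    normalized["organ_id"] = organ_id
    return normalized, geom


def pooled_sector_tests(pooled: pd.DataFrame, config: PipelineConfig) -> list[dict]:
    """Binomial sector tests per hair-cell type on pooled normalized cells.

    Negative cells are excluded.  Each type is tested in its canonical
    sector (extrastriolar: medial half, striolar: lateral half,
    intermediate: boundary quarter) against the sector's uniform null.
    """
    specs = config.sector_specs()
    results = []
    for cell_type, sector_name in _TYPE_SECTOR.items():
        if sector_name not in specs:
            continue
        spec = specs[sector_name]
        mask = pooled["type"] == cell_type
        k, n = geometry.sector_fraction(pooled["theta_deg"], spec, mask=mask)
        if n == 0:
            results.append(
                {"type": cell_type, "sector": sector_name, "k": 0, "n": 0, "flag": "empty"}
            )
            continue
        res = stats.binom_test(k, n, spec.null_fraction)
        results.append(
            {
                "type": cell_type,
                "sector": sector_name,
                "k": k,
                "n": n,
                "fraction": k / n,
                "percent": round(100.0 * k / n),
                "null": spec.null_fraction,
                "p_value": res.p_value,
            }
        )
    return results


def run_pipeline(
    config: PipelineConfig,
    tables: dict[str, pd.DataFrame],
) -> dict:
    """Run the full analysis over per-organ cell tables.

    Returns a dict with per-organ normalized tables and geometry, the
    pooled table, pooled type proportions, sector tests, join-count
    results, KDE grids per type, and a run manifest.
    """
    if not tables:
        raise ValueError("no input organs")
    per_organ = {}
    normalized_tables = []
    for organ_id, table in tables.items():
        normalized, geom = process_organ(table, config, organ_id)
        per_organ[organ_id] = {"geometry": geom}
        normalized_tables.append(normalized)
    pooled = pd.concat(normalized_tables, ignore_index=True)
    typed = pooled[pooled["type"] != "negative"]

    proportions = stats.proportion_table(pooled)
    sector_tests = pooled_sector_tests(pooled, config)

    join = None
    if len(typed) > config.knn_k and typed["type"].nunique() >= 2:
        xy = np.column_stack(
            [
                typed["r"] * np.cos(np.deg2rad(typed["theta_deg"])),
                typed["r"] * np.sin(np.deg2rad(typed["theta_deg"])),
            ]
        )
        graph = spatial.knn_graph(xy, k=config.knn_k)
        join = spatial.permutation_null(
            typed["type"].to_numpy(),
            graph,
            n_perm=config.n_permutations,
            seed=config.seed,
        )

    kdes = {}
    for cell_type in typed["type"].unique():
        sub = typed[typed["type"] == cell_type]
        if len(sub) >= 2:
            try:
                kdes[cell_type] = spatial.kde_map(
                    sub["theta_deg"],
                    sub["r"],
                    grid_n=config.kde_grid_n,
                    bandwidth_rule=config.kde_bandwidth_rule,
                )
            except (ValueError, np.linalg.LinAlgError):
                log.warning("KDE skipped for %s: degenerate spread", cell_type)

    manifest = io.make_manifest(
        asdict(config), list(tables.keys()), {}, seed=config.seed
    )
    return {
        "per_organ": per_organ,
        "pooled": pooled,
        "proportions": proportions,
        "sector_tests": sector_tests,
        "join_counts": join,
        "kde": kdes,
        "manifest": manifest,
    }
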