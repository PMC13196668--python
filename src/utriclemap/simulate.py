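"""Ground-truthed synthetic utricles.

The generator draws hair-cell centroids inside a rotated, translated
ellipse (the organ outline), assigns each cell a true zonal type from its
signed distance to the major axis — medial side extrastriolar, lateral
side striolar, a thin band at the axis intermediate — and gives every cell
log-normal marker intensities: bright on its own zone's channel(s), dim
background otherwise.  An optional "early-born" cohort (emulating nuclear
photoconversion before 36 hpf) is biased toward the medial half.  Cells can
be rendered as disjoint disks into a label image plus two noisy channel
images, standing in for segmented maximum-intensity projections.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

TYPE_EXTRASTRIOLAR = "extrastriolar"
TYPE_STRIOLAR = "striolar"
TYPE_INTERMEDIATE = "intermediate"
TYPE_NEGATIVE = "negative"

#: minimum centre-to-centre spacing, in units of cell_radius_px
_MIN_SPACING_FACTOR = 2.2

CELL_TABLE_COLUMNS = [
    "cell_id",
    "x",
    "y",
    "area",
    "ch1_mean",
    "ch1_sum",
    "ch2_mean",
    "ch2_sum",
    "true_type",
    "early_born",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of one synthetic utricle.

    Defaults emulate a wild-type 5 dpf organ: ~73 hair cells in an oval
    epithelium whose true type split is near 49% extrastriolar / 47%
    striolar / 4% intermediate, with channel 1 carrying the extrastriolar
    marker (cabp1b) and channel 2 the striolar marker (cabp2b).

    ``boundary_band_frac`` is the width of the intermediate band as a
    fraction of the semi-minor axis (band half-width = frac * b / 2).
    ``early_born_medial_bias`` is the fraction of the early-born cohort
    placed in the medial half (default 0.81, the observed medial share of
    photoconverted cells).  ``mirror`` flips the medial side across the
    major axis, emulating the left/right ear.
    """

    n_cells: int = 73
    semi_major: float = 110.0
    semi_minor: float = 70.0
    rotation_deg: float = 0.0
    center_xy: tuple[float, float] = (256.0, 256.0)
    boundary_band_frac: float = 0.08
    pos_intensity_mean: float = 5000.0
    bg_intensity_mean: float = 500.0
    intensity_cv: float = 0.2
    pixel_noise_sd: float = 50.0
    cell_radius_px: float = 6.0
    frac_early_born: float = 0.0
    early_born_medial_bias: float = 0.81
    mirror: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.semi_major >= self.semi_minor > 0:
            raise ValueError("require semi_major >= semi_minor > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0 <= self.boundary_band_frac < 1:
            raise ValueError("boundary_band_frac must be in [0, 1)")
        if not self.pos_intensity_mean > self.bg_intensity_mean >= 0:
            raise ValueError("require pos_intensity_mean > bg_intensity_mean >= 0")
        if not 0 <= self.frac_early_born <= 1:
            raise ValueError("frac_early_born must be in [0, 1]")
        if not 0 <= self.early_born_medial_bias <= 1:
            raise ValueError("early_born_medial_bias must be in [0, 1]")
        if self.intensity_cv < 0 or self.pixel_noise_sd < 0:
            raise ValueError("intensity_cv and pixel_noise_sd must be >= 0")
        if self.cell_radius_px <= 0:
            raise ValueError("cell_radius_px must be > 0")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Log-normal draws with the given arithmetic mean and CV."""
    if mean == 0:
        return np.zeros(size)
    if cv == 0:
        return np.full(size, float(mean))
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def _poisson_disk_in_ellipse(
    rng: np.random.Generator,
    n: int,
    a: float,
    b: float,
    min_dist: float,
    max_attempts: int = 200_000,
) -> np.ndarray:
    """Rejection-sampled hard-core point process in the axis-aligned ellipse.

    Returns n points (u, v) with u^2/a^2 + v^2/b^2 <= margin^2 where the
    margin keeps whole disks of radius min_dist/2 inside the outline.
    """
    if n == 0:
        return np.empty((0, 2))
    pts: list[np.ndarray] = []
    # shrink so rendered disks stay inside the ellipse
    shrink = 1.0 - (min_dist / 2.0) / b
    shrink = max(shrink, 0.05)
    for _ in range(max_attempts):
        u = rng.uniform(-a, a)
        v = rng.uniform(-b, b)
        if (u / (a * shrink)) ** 2 + (v / (b * shrink)) ** 2 > 1.0:
            continue
        p = np.array([u, v])
        if all(np.hypot(*(p - q)) >= min_dist for q in pts):
            pts.append(p)
            if len(pts) == n:
                return np.asarray(pts)
    raise RuntimeError(
        f"could not place {n} cells with spacing {min_dist:.1f} in an "
        f"{a:.0f}x{b:.0f} ellipse; reduce n_cells or cell_radius_px"
    )


def generate_dataset(params: SimParams) -> tuple[pd.DataFrame, dict]:
    """Generate one synthetic utricle as a cell table plus geometry record.

    Returns a DataFrame with columns ``cell_id, x, y, area, ch1_mean,
    ch1_sum, ch2_mean, ch2_sum, true_type, early_born`` and a JSON-ready
    geometry dict echoing the generating parameters.  Identical params
    (including seed) give identical output.
    """
    rng = np.random.default_rng(params.seed)
    a, b = params.semi_major, params.semi_minor
    min_dist = _MIN_SPACING_FACTOR * params.cell_radius_px

    uv = _poisson_disk_in_ellipse(rng, params.n_cells, a, b, min_dist)
    n = len(uv)

    # zonal ground truth from the signed minor-axis coordinate v:
    # v > 0 medial (extrastriolar), v < 0 lateral (striolar),
    # |v| < band half-width intermediate.
    half_band = params.boundary_band_frac * b / 2.0
    v = uv[:, 1] if n else np.empty(0)
    true_type = np.where(
        np.abs(v) < half_band,
        TYPE_INTERMEDIATE,
        np.where(v > 0, TYPE_EXTRASTRIOLAR, TYPE_STRIOLAR),
    )

    # early-born cohort, biased to the medial half
    early = np.zeros(n, dtype=bool)
    n_early = int(round(params.frac_early_born * n))
    if n_early > 0:
        medial = v > 0
        idx_med = np.flatnonzero(medial)
        idx_lat = np.flatnonzero(~medial)
        k_med = min(int(round(params.early_born_medial_bias * n_early)), len(idx_med))
        k_lat = min(n_early - k_med, len(idx_lat))
        chosen = np.concatenate(
            [
                rng.choice(idx_med, size=k_med, replace=False),
                rng.choice(idx_lat, size=k_lat, replace=False),
            ]
        )
        early[chosen.astype(int)] = True

    # marker intensities: bright on own zone's channel(s), background else
    es_pos = np.isin(true_type, [TYPE_EXTRASTRIOLAR, TYPE_INTERMEDIATE])
    s_pos = np.isin(true_type, [TYPE_STRIOLAR, TYPE_INTERMEDIATE])
    ch1 = np.where(
        es_pos,
        _lognormal(rng, params.pos_intensity_mean, params.intensity_cv, n),
        _lognormal(rng, params.bg_intensity_mean, params.intensity_cv, n),
    )
    ch2 = np.where(
        s_pos,
        _lognormal(rng, params.pos_intensity_mean, params.intensity_cv, n),
        _lognormal(rng, params.bg_intensity_mean, params.intensity_cv, n),
    )

    # place in the image frame: optional mirror, rotation, translation
    xy = uv.copy()
    if params.mirror and n:
        xy[:, 1] = -xy[:, 1]
    phi = np.deg2rad(params.rotation_deg)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    xy = xy @ rot.T + np.asarray(params.center_xy)

    area = np.full(n, np.pi * params.cell_radius_px**2)
    table = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "x": xy[:, 0] if n else np.empty(0),
            "y": xy[:, 1] if n else np.empty(0),
            "area": area,
            "ch1_mean": ch1,
            "ch1_sum": ch1 * area,
            "ch2_mean": ch2,
            "ch2_sum": ch2 * area,
            "true_type": true_type,
            "early_born": early,
        },
        columns=CELL_TABLE_COLUMNS,
    )
    geometry = {
        "params": dataclasses.asdict(params),
        "n_cells": int(n),
        "type_counts": {
            t: int((true_type == t).sum())
            for t in (TYPE_EXTRASTRIOLAR, TYPE_STRIOLAR, TYPE_INTERMEDIATE)
        },
    }
    return table, geometry


def render_images(
    cells: pd.DataFrame,
    cell_radius_px: float,
    image_shape: tuple[int, int],
    pixel_noise_sd: float,
    seed: int,
    bg_level: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a cell table into a label image and a 2-channel stack.

    Each cell becomes a filled disk carrying its integer ``cell_id``; each
    channel pixel inside a disk is that cell's configured channel mean plus
    Gaussian noise of SD ``pixel_noise_sd``.  Background pixels sit at
    ``bg_level`` (no noise).  Disks must be pairwise disjoint and fully
    inside the image; overlaps raise, because segmentation masks are
    disjoint by construction.

    Returns ``(label_image int32 HxW, channels float64 2xHxW)``.
    """
    from skimage.draw import disk as _disk

    h, w = image_shape
    labels = np.zeros((h, w), dtype=np.int32)
    channels = np.full((2, h, w), float(bg_level))
    rng = np.random.default_rng(seed)

    for row in cells.itertuples(index=False):
        # note image row = y, column = x
        rr, cc = _disk((row.y, row.x), cell_radius_px, shape=None)
        if rr.min() < 0 or cc.min() < 0 or rr.max() >= h or cc.max() >= w:
            raise ValueError(f"cell {row.cell_id} does not fit inside the image")
        if np.any(labels[rr, cc] != 0):
            raise ValueError(f"cell {row.cell_id} overlaps a previously drawn cell")
        labels[rr, cc] = int(row.cell_id)
        npx = len(rr)
        for ch, mean in ((0, row.ch1_mean), (1, row.ch2_mean)):
            vals = np.full(npx, float(mean))
            if pixel_noise_sd > 0:
                vals = vals + rng.normal(0.0, pixel_noise_sd, size=npx)
            channels[ch, rr, cc] = vals
    return labels, channels
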