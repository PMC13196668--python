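"""Canonical-frame geometry: hulls, ellipse fit, normalization, sectors."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from shapely.geometry import Point, Polygon

from conftest import angle_diff_deg
from utriclemap.geometry import (
    BOUNDARY_QUARTER,
    LATERAL_HALF,
    MEDIAL_HALF,
    SectorSpec,
    canonicalize,
    compute_center,
    concave_hull,
    fit_ellipse,
    normalize_organ,
    sector_fraction,
    unit_circle_normalize,
)
from utriclemap.quantify import classify_cells
from utriclemap.simulate import SimParams, generate_dataset


def ellipse_samples(a, b, phi_deg, n=50, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    phi = np.deg2rad(phi_deg)
    x = center[0] + a * np.cos(t) * np.cos(phi) - b * np.sin(t) * np.sin(phi)
    y = center[1] + a * np.cos(t) * np.sin(phi) + b * np.sin(t) * np.cos(phi)
    return np.column_stack([x, y])


class TestCenter:
    def test_square_corners(self):
        c = compute_center([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert np.allclose(c, [0.5, 0.5])

    def test_single_point(self):
        assert np.allclose(compute_center([[3.0, -2.0]]), [3.0, -2.0])

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(40, 2))
        shift = np.array([13.2, -7.9])
        assert np.allclose(compute_center(pts + shift), compute_center(pts) + shift)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_center(np.empty((0, 2)))


class TestConcaveHull:
    def test_convex_input_equals_convex_hull(self):
        square = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], float)
        ring = concave_hull(square)
        assert Polygon(ring).equals(Polygon(square))

    def test_crescent_is_tighter_than_convex_hull(self):
        rng = np.random.default_rng(0)
        ang = rng.uniform(0, np.pi, 400)
        rad = rng.uniform(0.7, 1.0, 400)
        pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        ring = concave_hull(pts)
        poly = Polygon(ring)
        assert poly.is_valid
        assert poly.area < 0.8 * ConvexHull(pts).volume
        buffered = poly.buffer(1e-9)
        assert all(buffered.covers(Point(p)) for p in pts)

    def test_duplicates_ignored(self):
        square = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], float)
        with_dups = np.vstack([square, square, [[1, 1]]])
        assert Polygon(concave_hull(with_dups)).equals(
            Polygon(concave_hull(np.vstack([square, [[1, 1]]])))
        )

    @pytest.mark.parametrize(
        "bad",
        [np.array([[0.0, 0.0], [1.0, 1.0]]), np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])],
    )
    def test_too_few_or_collinear_rejected(self, bad):
        with pytest.raises(ValueError):
            concave_hull(bad)


class TestEllipseFit:
    def test_recovers_generating_parameters(self):
        pts = ellipse_samples(2.0, 1.0, 30.0, center=(0.4, -0.7))
        fit = fit_ellipse(pts)
        assert abs(fit.semi_major - 2.0) / 2.0 < 1e-6
        assert abs(fit.semi_minor - 1.0) < 1e-6
        assert abs(fit.phi - np.deg2rad(30.0)) < 1e-6
        assert np.allclose(fit.center_xy, (0.4, -0.7), atol=1e-6)

    def test_circle_degeneracy_gives_equal_axes(self):
        pts = ellipse_samples(1.0, 1.0, 0.0)
        fit = fit_ellipse(pts)
        assert abs(fit.semi_major - fit.semi_minor) < 1e-9
        assert 0 <= fit.phi < np.pi  # any orientation is acceptable

    def test_rotation_equivariance_mod_180(self):
        base = fit_ellipse(ellipse_samples(2.0, 1.0, 30.0))
        rot = fit_ellipse(ellipse_samples(2.0, 1.0, 120.0))
        assert abs((rot.phi - base.phi) % np.pi - np.pi / 2) < 1e-9
        assert np.isclose(rot.semi_major, base.semi_major)
        assert np.isclose(rot.semi_minor, base.semi_minor)

    def test_degenerate_conic_rejected(self):
        line = np.column_stack([np.arange(6.0), 2.0 * np.arange(6.0)])
        with pytest.raises(ValueError):
            fit_ellipse(line)
        with pytest.raises(ValueError, match="5"):
            fit_ellipse(np.array([[0, 0], [1, 0], [0, 1], [1, 1.0]]))


class TestCanonicalize:
    def test_requires_markers_or_explicit_flags(self):
        pts = ellipse_samples(2.0, 1.0, 0.0)
        fit = fit_ellipse(pts)
        with pytest.raises(ValueError, match="explicit"):
            canonicalize(pts, fit, es_positive=np.zeros(len(pts), bool))
        out = canonicalize(pts, fit, orientation_policy="explicit")
        assert out.shape == pts.shape

    def test_true_extrastriolar_cells_land_in_medial_half(self, rotated_organ):
        normalized, _ = normalize_organ(rotated_organ)
        es = normalized[normalized["true_type"] == "extrastriolar"]
        frac = ((es["theta_deg"] > 180) & (es["theta_deg"] < 360)).mean()
        assert frac >= 0.8

    def test_idempotent_on_canonical_input(self, wt_classified):
        first, _ = normalize_organ(wt_classified)
        again = wt_classified.copy()
        # rebuild raw coordinates from the canonical frame and re-run
        from utriclemap.geometry import concave_hull as chull, fit_ellipse as fell

        pts = wt_classified[["x", "y"]].to_numpy()
        pts = pts - pts.mean(axis=0)
        ell = fell(chull(pts))
        canon = canonicalize(pts, ell, es_positive=wt_classified["es_call"].to_numpy())
        again["x"], again["y"] = canon[:, 0], canon[:, 1]
        second, _ = normalize_organ(again)
        assert angle_diff_deg(first["theta_deg"], second["theta_deg"]).max() < 1e-9
        assert np.abs(first["r"] - second["r"]).max() < 1e-9


class TestUnitCircle:
    def test_square_hull_examples(self):
        hull = np.array([[1, 1], [-1, 1], [-1, -1], [1, -1]], float)
        theta, r = unit_circle_normalize(
            np.array([[0.5, 0.0], [0.0, 0.0], [1.0, 1.0]]), hull
        )
        assert r[0] == pytest.approx(0.5)  # ray hits the x=1 edge
        assert r[1] == 0.0  # origin
        assert r[2] == pytest.approx(1.0)  # hull vertex
        assert theta[2] == pytest.approx(45.0)

    def test_radii_bounded_and_boundary_attained(self, wt_classified):
        normalized, _ = normalize_organ(wt_classified)
        assert (normalized["r"] >= 0).all() and (normalized["r"] <= 1).all()
        assert np.isclose(normalized["r"].max(), 1.0)

    def test_origin_outside_hull_rejected(self):
        hull = np.array([[2, 2], [3, 2], [3, 3], [2, 3]], float)
        with pytest.raises(ValueError, match="origin"):
            unit_circle_normalize(np.array([[2.5, 2.5]]), hull)


class TestSectors:
    def test_direct_membership(self):
        theta = [10.0, 170.0, 190.0, 350.0]
        assert sector_fraction(theta, MEDIAL_HALF) == (2, 4)
        assert sector_fraction(theta, LATERAL_HALF) == (2, 4)

    def test_boundary_quarter_contains_200_degrees(self):
        assert BOUNDARY_QUARTER.contains([200.0]).all()
        assert not BOUNDARY_QUARTER.contains([90.0]).any()
        assert BOUNDARY_QUARTER.null_fraction == pytest.approx(0.25)

    def test_halves_are_additive(self, wt_classified):
        normalized, _ = normalize_organ(wt_classified)
        k_med, n = sector_fraction(normalized["theta_deg"], MEDIAL_HALF)
        k_lat, _ = sector_fraction(normalized["theta_deg"], LATERAL_HALF)
        assert k_med + k_lat == n == len(normalized)

    def test_empty_subset_flagged_as_zero(self):
        assert sector_fraction([10.0, 20.0], MEDIAL_HALF, mask=[False, False]) == (0, 0)

    def test_uniform_angles_fill_quarter_at_null_rate(self):
        rng = np.random.default_rng(1)
        theta = rng.uniform(0, 360, 10_000)
        k, n = sector_fraction(theta, BOUNDARY_QUARTER)
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(k / n - 0.25) < 3 * se


class TestFrameInvariance:
    def test_rigid_transform_and_scaling_leave_frame_unchanged(self, rotated_organ):
        base, _ = normalize_organ(rotated_organ)
        moved = rotated_organ.copy()
        ang, s = np.deg2rad(201.3), 0.37
        x, y = rotated_organ["x"].to_numpy(), rotated_organ["y"].to_numpy()
        moved["x"] = s * (x * np.cos(ang) - y * np.sin(ang)) - 55.5
        moved["y"] = s * (x * np.sin(ang) + y * np.cos(ang)) + 91.1
        other, _ = normalize_organ(moved)
        assert angle_diff_deg(base["theta_deg"], other["theta_deg"]).max() < 1e-6
        assert np.abs(base["r"] - other["r"]).max() < 1e-6

    def test_mirrored_ear_resolves_to_same_pattern(self):
        for seed in (4, 6, 7):
            right, _ = generate_dataset(SimParams(seed=seed))
            left, _ = generate_dataset(SimParams(seed=seed, mirror=True))
            n_r, _ = normalize_organ(classify_cells(right))
            n_l, _ = normalize_organ(classify_cells(left))
            assert angle_diff_deg(n_r["theta_deg"], n_l["theta_deg"]).max() < 1e-6
            assert np.abs(n_r["r"] - n_l["r"]).max() < 1e-6
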