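import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

from endoquant import benchmarks
from endoquant.morphometrics import (
    DetectionParams,
    area_cov,
    dead_fraction,
    detect_nuclei,
    estimate_density,
    match_points,
    neighbor_analysis,
    points_in_rect,
)
from endoquant.mosaic_synth import generate_mosaic


def gaussian_blob(shape, center, sigma, amplitude, background=0.0):
    rr, cc = np.mgrid[: shape[0], : shape[1]].astype(float)
    return background + amplitude * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2)
    )


class TestDetectNuclei:
    def test_single_blob_single_detection_at_center(self):
        img = gaussian_blob((101, 101), (50, 50), 4.0, 60.0, background=100.0)
        pts = detect_nuclei(img, DetectionParams(cell_width_px=25.0))
        assert len(pts) == 1
        assert np.hypot(pts[0, 0] - 50, pts[0, 1] - 50) <= 1.0

    def test_regular_grid_fully_recovered(self):
        """100 nuclei on a grid: every one detected within 2 px."""
        img = np.full((260, 260), 100.0)
        truth = []
        for i in range(10):
            for j in range(10):
                c = (25 * i + 13, 25 * j + 13)
                truth.append(c)
                img += gaussian_blob(img.shape, c, 3.0, 30.0)
        pts = detect_nuclei(img, DetectionParams(cell_width_px=25.0))
        assert len(pts) == 100
        pairs, recall, precision = match_points(pts, np.array(truth), radius=2.0)
        assert recall == 1.0 and precision == 1.0

    def test_separation_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            detect_nuclei(np.zeros((20, 20)), DetectionParams(cell_width_px=100.0))

    def test_recall_on_rendered_field_channels(self, field, field_truth_px):
        """Nuclei channel sees every nucleus; calcein misses the no-contrast ones."""
        gt, channels = field
        params = benchmarks.field_detection_params()
        radius = params.cell_width_px / 2.0
        pts_n = detect_nuclei(channels["nuclei"], params)
        _, recall_n, prec_n = match_points(pts_n, field_truth_px, radius)
        assert recall_n >= 0.98 and prec_n >= 0.99
        pts_c = detect_nuclei(channels["calcein"], params)
        _, recall_c, prec_c = match_points(pts_c, field_truth_px, radius)
        assert recall_c == pytest.approx(0.925, abs=0.03)
        assert prec_c >= 0.99

    def test_localization_within_2px_of_truth(self, field, field_truth_px):
        gt, channels = field
        params = benchmarks.field_detection_params()
        pts = detect_nuclei(channels["nuclei"], params)
        pairs, _, _ = match_points(pts, field_truth_px, params.cell_width_px / 2)
        errs = [np.hypot(*(pts[i] - field_truth_px[j])) for i, j in pairs]
        assert np.median(errs) <= 2.0


class TestDensity:
    def test_density_is_count_over_area(self):
        est = estimate_density(np.zeros((250, 2)), 0.1)
        assert est.density == 2500.0
        assert estimate_density(np.empty((0, 2)), 0.1).density == 0.0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            estimate_density(np.zeros((5, 2)), 0.0)

    def test_nuclei_channel_density_unbiased(self):
        """Nuclei-channel counting tracks generator truth within 2%."""
        ref, _ = benchmarks.paired_density_fields(31, n_fields=6)
        assert abs(ref.mean() - 2500.0) / 2500.0 < 0.02


def hex_lattice(n=12, a=1.0):
    pts = []
    for i in range(n):
        for j in range(n):
            pts.append((a * (i + 0.5 * (j % 2)), a * j * np.sqrt(3) / 2))
    return np.array(pts)


class TestNeighborAnalysis:
    def test_hexagonal_lattice_is_100pct_hexagonal(self):
        res = neighbor_analysis(hex_lattice())
        assert res.hexagonality_pct == 100.0
        assert res.n_interior > 0

    def test_square_lattice_is_0pct_hexagonal(self):
        """Diagonal degeneracy broken by an infinitesimal seeded jitter."""
        rng = np.random.default_rng(4)
        xx, yy = np.mgrid[0:12, 0:12].astype(float)
        pts = np.c_[xx.ravel(), yy.ravel()] + rng.normal(0, 1e-6, (144, 2))
        res = neighbor_analysis(pts)
        assert res.hexagonality_pct == 0.0
        assert set(res.neighbor_counts) == {4}

    def test_handshake_identity(self, small_gt):
        """Sum of all neighbor counts equals twice the number of adjacency edges."""
        res = neighbor_analysis(small_gt.centroids)
        assert res.all_neighbor_counts.sum() == 2 * res.n_edges

    def test_invariance_under_similarity_transforms(self):
        """Translation, uniform scaling and quarter-turn rotation preserve the
        statistic exactly (the border-exclusion box rotates with the data)."""
        pts = hex_lattice() + np.random.default_rng(7).normal(0, 0.05, (144, 2))
        base = neighbor_analysis(pts).hexagonality_pct
        quarter = np.array([[0.0, -1.0], [1.0, 0.0]])
        assert neighbor_analysis(pts @ quarter.T).hexagonality_pct == base
        assert neighbor_analysis(pts * 3.7 + [100, -40]).hexagonality_pct == base

    def test_collinear_points_rejected(self):
        pts = np.c_[np.arange(10.0), np.zeros(10)]
        with pytest.raises(ValueError):
            neighbor_analysis(pts)

    def test_relaxed_mosaic_more_hexagonal_than_poisson(self):
        """Lloyd relaxation raises hexagonality, seed for seed."""
        spec = replace(benchmarks.FIELD_SPEC, graft_diameter_mm=0.6, pixel_size_um=5.0)
        wins = 0
        for seed in range(5):
            rough = generate_mosaic(replace(spec, regularity=0, rng_seed=seed))
            smooth = generate_mosaic(replace(spec, regularity=10, rng_seed=seed))
            h0 = neighbor_analysis(rough.centroids).hexagonality_pct
            h1 = neighbor_analysis(smooth.centroids).hexagonality_pct
            wins += h1 > h0
        assert wins == 5


class TestAreaCov:
    def test_identical_areas_zero(self):
        assert area_cov(np.full(10, 7.0)) == 0.0

    def test_hand_arithmetic_pair(self):
        assert area_cov(np.array([1.0, 3.0])) == 0.5

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            area_cov(np.array([1.0, -2.0]))

    def test_truth_vs_voronoi_reconstructed_areas(self, small_gt):
        """Polygon-area oracle: shoelace areas of a fresh tessellation of the
        generator sites agree with the stored per-cell areas."""
        from scipy.spatial import Voronoi

        rr = np.hypot(*small_gt.points.T)
        interior = rr < small_gt.radius_um - 100  # clear of the mirrored rim band
        vor = Voronoi(small_gt.points)
        areas, truth_areas = [], []
        for i in np.flatnonzero(interior):
            region = vor.regions[vor.point_region[i]]
            if -1 in region:
                continue
            v = vor.vertices[region]
            x, y = v[:, 0], v[:, 1]
            areas.append(0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1))))
            truth_areas.append(small_gt.areas_um2[i])
        assert len(areas) > 500
        assert area_cov(np.array(areas)) == pytest.approx(
            area_cov(np.array(truth_areas)), rel=0.05
        )


class TestDeadFraction:
    def test_hand_counts(self):
        live = np.random.default_rng(0).uniform(0, 1000, (990, 2))
        dead = np.random.default_rng(1).uniform(2000, 3000, (10, 2))
        assert dead_fraction(live, dead, matching_radius=5.0) == pytest.approx(1.0)

    def test_no_dead_points(self):
        assert dead_fraction(np.zeros((5, 2)), np.empty((0, 2)), 5.0) == 0.0

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            dead_fraction(np.empty((0, 2)), np.empty((0, 2)), 5.0)

    def test_duplicate_across_channels_resolves_to_dead(self):
        live = np.array([[10.0, 10.0], [50.0, 50.0]])
        dead = np.array([[11.0, 10.0]])
        # the live point at (10,10) is the same cell as the dead detection
        assert dead_fraction(live, dead, matching_radius=3.0) == pytest.approx(50.0)

    def test_synthetic_field_known_dead_percentage(self, calibrated_spec):
        """~4% of cells killed in place in a high-magnification field; the
        live/dead channel pair recovers the percentage within a point."""
        from endoquant.mosaic_synth import (
            DamageSpec, PolygonPatch, apply_damage, generate_mosaic, render,
        )
        spec = replace(benchmarks.FIELD_SPEC, graft_diameter_mm=0.6, rng_seed=3)
        gt = generate_mosaic(spec)
        rng = np.random.default_rng(3)
        R = gt.radius_um
        prims = []
        while True:
            probe = apply_damage(gt, DamageSpec(tuple(prims)))
            if (probe.states == 1).mean() >= 0.04:
                gt = probe
                break
            cx, cy = rng.uniform(-0.8 * R, 0.8 * R, 2)
            s = 25.0
            prims.append(PolygonPatch(
                vertices=((cx - s, cy - s), (cx + s, cy - s), (cx + s, cy + s),
                          (cx - s, cy + s)),
                mode="dead_attached"))
        true_dead_pct = 100.0 * (gt.states == 1).sum() / (gt.states != 2).sum()
        out = render(gt, calibrated_spec, seed=9, channels=("nuclei", "dead"))
        params = benchmarks.field_detection_params()
        all_pts = detect_nuclei(out["nuclei"], params)
        dead_pts = detect_nuclei(out["dead"], params)
        got = dead_fraction(all_pts, dead_pts, matching_radius=params.cell_width_px / 2)
        assert got == pytest.approx(true_dead_pct, abs=1.0)


class TestMatchPoints:
    def test_greedy_matches_optimal_assignment_oracle(self):
        """Cardinality equality with scipy's optimal assignment on 150 points."""
        rng = np.random.default_rng(12)
        truth = rng.uniform(0, 500, (150, 2))
        detected = truth + rng.normal(0, 1.5, truth.shape)
        detected = detected[rng.permutation(150)[:140]]
        radius = 6.0
        pairs, recall, precision = match_points(detected, truth, radius)
        d = np.linalg.norm(detected[:, None, :] - truth[None, :, :], axis=2)
        cost = np.where(d <= radius, d, 1e6)
        ri, ci = linear_sum_assignment(cost)
        optimal = int((d[ri, ci] <= radius).sum())
        assert len(pairs) == optimal

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_points_in_rect_consistent(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, (50, 2))
        sub = points_in_rect(pts, (20, 80), (30, 70))
        assert all(20 <= r < 80 and 30 <= c < 70 for r, c in sub)
        outside = {tuple(p) for p in pts} - {tuple(p) for p in sub}
        assert all(not (20 <= r < 80 and 30 <= c < 70) for r, c in outside)
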