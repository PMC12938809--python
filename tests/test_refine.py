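import numpy as np
import pytest

from conftest import make_ring_edge_map
from hipwear.geometry import Circle, DegenerateGeometryError
from hipwear.refine import (
    EdgeSnapConfig,
    InsufficientDataError,
    NoValidFitError,
    OutOfBoundsError,
    RansacConfig,
    anatomical_filter,
    edge_snap,
    fit_prosthesis,
    generate_cup_candidates,
    harvest_ring_points,
    hough_circles,
    ransac_circle,
    score_cup_candidate,
)
from hipwear.roi import RoiBox, oracle_roi_provider
from hipwear.synthetic import PhantomSpec, generate_phantom


def circle_points(cx, cy, r, n, rng=None, sigma=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    rr = r + (rng.normal(0, sigma, n) if sigma else 0.0)
    return np.column_stack([cx + rr * np.cos(t), cy + rr * np.sin(t)])


class TestEdgeSnap:
    def test_snaps_to_true_ring(self, ring_edge_map):
        c, support = edge_snap(ring_edge_map, Circle(64, 64, 45))
        assert c.r == pytest.approx(50.0, abs=1.0)
        assert (c.cx, c.cy) == (64, 64)  # center untouched
        assert support > 0.9

    def test_uniform_map_keeps_radius(self):
        em = make_ring_edge_map()
        em.combined[:] = 0.0
        c, support = edge_snap(em, Circle(64, 64, 45))
        assert c.r == 45
        assert support == 0.0

    def test_band_excluding_ring_keeps_radius(self, ring_edge_map):
        # annulus 0.2 around r=30 spans [24, 36]; the true ring is at 50
        c, support = edge_snap(ring_edge_map, Circle(64, 64, 30))
        assert c.r == 30
        assert support < 0.1

    def test_fully_outside_raises(self, ring_edge_map):
        with pytest.raises(OutOfBoundsError):
            edge_snap(ring_edge_map, Circle(500, 500, 20))


class TestHarvest:
    def test_blank_map_empty(self):
        em = make_ring_edge_map()
        em.combined[:] = 0.0
        assert len(harvest_ring_points(em, Circle(64, 64, 50))) == 0

    def test_points_stay_in_band(self, ring_edge_map):
        pts = harvest_ring_points(ring_edge_map, Circle(64, 64, 50), ring_frac=0.1)
        d = np.hypot(pts[:, 0] - 64, pts[:, 1] - 64)
        assert len(pts) > 50
        assert np.all(np.abs(d - 50) <= 5.0 + 1e-9)

    def test_count_monotone_in_ring_frac(self, ring_edge_map):
        counts = [
            len(harvest_ring_points(ring_edge_map, Circle(64, 64, 48), ring_frac=f))
            for f in (0.05, 0.10, 0.20)
        ]
        assert counts[0] <= counts[1] <= counts[2]


class TestRansac:
    def test_exact_points_recovered(self):
        pts = circle_points(80, 80, 40, 100)
        c, n_in, frac = ransac_circle(pts, RansacConfig(n_iter=200, seed=0))
        assert (c.cx, c.cy, c.r) == pytest.approx((80, 80, 40), abs=1e-6)
        assert frac == 1.0

    def test_outlier_robustness(self):
        rng = np.random.default_rng(42)
        inliers = circle_points(80, 80, 40, 80, rng=rng, sigma=1.0)
        outliers = rng.uniform(0, 160, size=(20, 2))
        pts = np.vstack([inliers, outliers])
        c, n_in, _ = ransac_circle(pts, RansacConfig(n_iter=500, seed=42))
        assert (c.cx, c.cy) == pytest.approx((80, 80), abs=1.0)
        assert c.r == pytest.approx(40, abs=1.0)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            ransac_circle([(0, 0), (1, 1)])

    def test_all_collinear_raises(self):
        pts = [(float(i), float(i)) for i in range(6)]
        with pytest.raises(DegenerateGeometryError):
            ransac_circle(pts)

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(3)
        pts = np.vstack(
            [circle_points(50, 50, 20, 30, rng=rng, sigma=1.5), rng.uniform(0, 100, (40, 2))]
        )
        cfg = RansacConfig(n_iter=100, seed=9)
        r1 = ransac_circle(pts, cfg)
        r2 = ransac_circle(pts, cfg)
        assert r1 == r2


class TestHough:
    def test_single_ring_recovered(self, ring_edge_map):
        peaks = hough_circles(ring_edge_map, 40, 60, r_step=1.0, n_peaks=3)
        c, score = peaks[0]
        assert (c.cx, c.cy) == pytest.approx((64, 64), abs=2.0)
        assert c.r == pytest.approx(50, abs=1.0)

    def test_blank_map_empty(self):
        em = make_ring_edge_map()
        em.combined[:] = 0.0
        assert hough_circles(em, 10, 40) == []

    def test_two_disjoint_rings_both_found(self):
        em = make_ring_edge_map(
            shape=(128, 256), cx=60, cy=64, r=40, extra_rings=((190, 64, 30),)
        )
        peaks = hough_circles(em, 25, 50, r_step=1.0, n_peaks=2)
        found = sorted((round(c.cx), round(c.r)) for c, _ in peaks)
        assert abs(found[0][0] - 60) <= 2 and abs(found[0][1] - 40) <= 1
        assert abs(found[1][0] - 190) <= 2 and abs(found[1][1] - 30) <= 1


class TestCandidates:
    def test_identity_grid(self):
        c0 = Circle(100, 100, 40)
        assert generate_cup_candidates(c0, n_shifts=1, n_scales=1) == [c0]

    def test_grid_size(self):
        c0 = Circle(100, 100, 40)
        cands = generate_cup_candidates(c0, n_shifts=3, n_scales=5)
        # 3x3 offsets x 5 scales; c0 is the central offset at scale 1.0 when
        # the scale grid contains 1.0, otherwise it is prepended
        assert len(cands) in (45, 46)

    def test_center_shift_bound(self):
        c0 = Circle(100, 100, 40)
        for c in generate_cup_candidates(c0, n_shifts=5, shift_frac=0.1, n_scales=3):
            d = np.hypot(c.cx - 100, c.cy - 100)
            assert d <= 0.1 * 40 * np.sqrt(2) + 1e-9

    def test_includes_c0(self):
        c0 = Circle(10, 10, 5)
        assert c0 in generate_cup_candidates(c0, n_shifts=2, n_scales=2)


class TestScoring:
    def test_perfect_rim_scores_high(self, ring_edge_map):
        s = score_cup_candidate(Circle(64, 64, 50), ring_edge_map, None, (64, 64))
        assert s.edge_support > 0.9
        assert s.angular_coverage > 0.9
        assert s.longest_arc == pytest.approx(2 * np.pi, rel=0.05)
        assert s.gradient_alignment > 0.95

    def test_blank_region_scores_low(self, ring_edge_map):
        # candidate far from the ring, ROI center far from the candidate
        s = score_cup_candidate(Circle(20, 20, 6), ring_edge_map, None, (100, 100))
        assert s.total < 0.1

    def test_outside_fraction_ordering(self):
        em = make_ring_edge_map(cx=64, cy=64, r=50, extra_rings=((64, 64, 30),))
        femoral = Circle(64, 64, 30)
        enclosing = score_cup_candidate(Circle(64, 64, 50), em, femoral, (64, 64))
        cutting = score_cup_candidate(Circle(64, 64, 30), em, femoral, (64, 64))
        assert enclosing.outside_fraction > cutting.outside_fraction

    def test_deleting_support_never_raises_score(self, ring_edge_map):
        full = score_cup_candidate(Circle(64, 64, 50), ring_edge_map, None, (64, 64))
        em2 = make_ring_edge_map()
        # delete a 90-degree wedge of edge pixels
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        ang = np.arctan2(yy - 64, xx - 64)
        wedge = (ang > 0) & (ang < np.pi / 2)
        em2.combined[wedge] = 0.0
        em2.edges[wedge] = False
        cut = score_cup_candidate(Circle(64, 64, 50), em2, None, (64, 64))
        assert cut.edge_support <= full.edge_support + 1e-9
        assert cut.angular_coverage <= full.angular_coverage + 1e-9

    def test_bad_weights_rejected(self, ring_edge_map):
        with pytest.raises(ValueError):
            score_cup_candidate(
                Circle(64, 64, 50), ring_edge_map, None, (64, 64), weights=[0] * 6
            )


class TestAnatomicalFilter:
    def test_concentric_clean_pair_passes(self):
        em = make_ring_edge_map(cx=64, cy=64, r=60, extra_rings=((64, 64, 40),))
        ok, reasons = anatomical_filter(
            Circle(64, 64, 40), Circle(64, 64, 60), em, min_gap=1.0
        )
        assert ok and reasons == []

    def test_equal_radii_fail_radius_ordering(self):
        em = make_ring_edge_map(cx=64, cy=64, r=40)
        ok, reasons = anatomical_filter(Circle(64, 64, 40), Circle(64, 64, 40), em)
        assert not ok
        assert any("radius ordering" in r for r in reasons)

    def test_intersecting_circles_fail_gap(self):
        em = make_ring_edge_map(cx=64, cy=64, r=50, extra_rings=((80, 64, 40),))
        ok, reasons = anatomical_filter(Circle(80, 64, 40), Circle(64, 64, 50), em)
        assert not ok
        assert any("joint-space gap" in r for r in reasons)

    def test_cup_center_outside_roi(self):
        em = make_ring_edge_map(cx=64, cy=64, r=50, extra_rings=((64, 64, 30),))
        roi = RoiBox(0, 0, 40, 40)
        ok, reasons = anatomical_filter(
            Circle(64, 64, 30), Circle(64, 64, 50), em, roi=roi
        )
        assert not ok
        assert any("outside ROI" in r for r in reasons)


class TestFitProsthesis:
    def test_clean_phantom_within_two_percent(self):
        spec = PhantomSpec(noise_sigma=0.0, n_screw_lines=0)
        img, truth = generate_phantom(spec)
        rois = oracle_roi_provider(truth, spec.dims, jitter=0.0)
        fit = fit_prosthesis(img, rois)
        norm = spec.dims.mean_dim
        for pred, t in ((fit.femoral, spec.femoral), (fit.cup, spec.cup)):
            assert np.hypot(pred.cx - t.cx, pred.cy - t.cy) / norm <= 0.02
            assert abs(pred.r - t.r) / norm <= 0.02
        assert fit.method == "ransac"

    def test_determinism(self):
        spec = PhantomSpec(seed=5)
        img, truth = generate_phantom(spec)
        rois = oracle_roi_provider(truth, spec.dims, jitter=0.02, seed=11)
        f1 = fit_prosthesis(img, rois)
        f2 = fit_prosthesis(img, rois)
        assert f1.femoral == f2.femoral and f1.cup == f2.cup
        assert f1.method == f2.method

    def test_blank_roi_raises_no_valid_fit(self):
        rng = np.random.default_rng(0)
        img = np.clip(rng.normal(40, 3, (320, 320)), 0, 255).astype(np.uint8)
        rois = [RoiBox(100, 100, 180, 180, cls=0), RoiBox(90, 90, 200, 200, cls=1)]
        with pytest.raises(NoValidFitError) as exc:
            fit_prosthesis(img, rois)
        assert exc.value.diagnostics  # carries the per-stage trail

    def test_returned_fit_satisfies_anatomy(self):
        """Fuzz: whatever the fit returns obeys the anatomical constraints."""
        rng = np.random.default_rng(99)
        from hipwear.synthetic import random_spec

        for i in range(4):
            spec = random_spec(rng)
            img, truth = generate_phantom(spec)
            rois = oracle_roi_provider(truth, spec.dims, jitter=0.03, seed=i)
            fit = fit_prosthesis(img, rois)
            assert fit.cup.r > fit.femoral.r
            d = np.hypot(fit.cup.cx - fit.femoral.cx, fit.cup.cy - fit.femoral.cy)
            assert fit.cup.r - fit.femoral.r - d >= 1.0

    def test_no_roi_rejected(self):
        with pytest.raises(ValueError):
            fit_prosthesis(np.zeros((64, 64), dtype=np.uint8), [])
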