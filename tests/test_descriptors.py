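"""Descriptor correctness against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from rosettakit.descriptors import (
    DESCRIPTOR_NAMES,
    EmptyMaskError,
    chain_length,
    contours,
    extract_all,
    largest_component,
    max_pairwise_distance,
    min_enclosing_circle_of,
    principal_axis_stats,
    trace_boundary,
)
from rosettakit.segmentation import BinaryMask
from rosettakit.synthetic import RosettePhenotypeParams, render_rosette

from conftest import annulus_grid, disc_grid, rotated_rect_grid, square_grid, star_grid


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation path)
# ---------------------------------------------------------------------------


def boundary_pixel_corners(grid: np.ndarray) -> np.ndarray:
    """All pixel-square corners of the boundary pixels of a component."""
    from scipy.ndimage import binary_erosion

    boundary = grid & ~binary_erosion(grid)
    pts = np.argwhere(boundary).astype(float)
    return np.unique(
        np.concatenate(
            [pts + off for off in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
        ),
        axis=0,
    )


def gift_wrap_hull(points: np.ndarray) -> np.ndarray:
    """Jarvis gift-wrapping convex hull (independent of qhull)."""
    pts = np.unique(points, axis=0)
    start = pts[np.lexsort((pts[:, 1], pts[:, 0]))][0]
    hull = [start]
    while True:
        cur = hull[-1]
        cand = pts[0] if not np.array_equal(pts[0], cur) else pts[1]
        for p in pts:
            cross = (cand[0] - cur[0]) * (p[1] - cur[1]) - (cand[1] - cur[1]) * (p[0] - cur[0])
            if cross > 1e-12 or (
                abs(cross) <= 1e-12
                and np.hypot(*(p - cur)) > np.hypot(*(cand - cur))
            ):
                cand = p
        if np.array_equal(cand, start):
            break
        hull.append(cand)
        if len(hull) > len(pts):
            raise RuntimeError("gift wrapping failed to close")
    return np.array(hull)


def shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 1], poly[:, 0]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def sweep_min_rect_area(points: np.ndarray, step_deg: float = 0.1, pad: float = 0.0) -> float:
    """Exhaustive orientation sweep for the minimum-area bounding rectangle."""
    best = math.inf
    for deg in np.arange(0.0, 90.0, step_deg):
        a = math.radians(deg)
        c, s = math.cos(a), math.sin(a)
        rot = points @ np.array([[c, -s], [s, c]])
        ext = rot.max(axis=0) - rot.min(axis=0) + pad
        best = min(best, ext[0] * ext[1])
    return best


def exact_min_circle(points: np.ndarray) -> float:
    """O(n^3) exact minimum enclosing circle radius over all pairs/triples."""
    from rosettakit.descriptors import _circle_from

    pts = [tuple(p) for p in points]
    best = None
    candidates = []
    n = len(pts)
    for i in range(n):
        for j in range(i + 1, n):
            candidates.append(_circle_from(pts[i], pts[j]))
            for k in range(j + 1, n):
                candidates.append(_circle_from(pts[i], pts[j], pts[k]))
    arr = np.asarray(pts)
    for cy, cx, r in candidates:
        if np.all(np.hypot(arr[:, 0] - cy, arr[:, 1] - cx) <= r + 1e-9):
            if best is None or r < best:
                best = r
    return best


def small_blob(seed: int, n_target: int = 500) -> np.ndarray:
    """Random connected blob of roughly n_target pixels."""
    rng = np.random.default_rng(seed)
    g = np.zeros((64, 64), dtype=bool)
    r, c = 32, 32
    g[r, c] = True
    while g.sum() < n_target:
        dr, dc = rng.integers(-1, 2, 2)
        r = int(np.clip(r + dr, 1, 62))
        c = int(np.clip(c + dc, 1, 62))
        g[r, c] = True
    return g


# ---------------------------------------------------------------------------
# closed-form shapes
# ---------------------------------------------------------------------------


class TestDisc:
    r = 50

    @pytest.fixture(autouse=True)
    def _extract(self, disc_mask):
        self.d = extract_all(disc_mask)

    def test_area_within_1pct(self):
        assert self.d.area == pytest.approx(math.pi * self.r**2, rel=0.01)

    def test_perimeter_within_3pct(self):
        assert self.d.circumference == pytest.approx(2 * math.pi * self.r, rel=0.03)

    def test_roundness_within_6pct_of_4pi(self):
        assert self.d.roundness == pytest.approx(4 * math.pi, rel=0.06)

    def test_compactness_within_2pct_of_1(self):
        assert self.d.compactness == pytest.approx(1.0, rel=0.02)
        assert self.d.compactness <= 1.0

    def test_mincirclediam_within_2px(self):
        assert abs(self.d.mincirclediam - 2 * self.r) <= 2.0

    def test_minrectarea_circumscribing_square(self):
        assert self.d.minrectarea == pytest.approx((2 * self.r) ** 2, rel=0.03)

    def test_normrotmo_is_inverse_2pi(self):
        assert self.d.normrotmo == pytest.approx(1.0 / (2 * math.pi), rel=0.03)

    def test_axis_stats_mean_abs_coordinate(self):
        # mean |coordinate| of a disc = 4r / (3 pi)
        expect = 4 * self.r / (3 * math.pi)
        assert self.d.normsmallpax == pytest.approx(expect, rel=0.03)
        assert self.d.normlargepax == pytest.approx(expect, rel=0.03)

    def test_paxratio_unity(self):
        assert self.d.paxratio == pytest.approx(1.0, rel=0.03)

    def test_mindistcenbdy_is_radius(self):
        assert abs(self.d.mindistcenbdy - self.r) <= 1.0

    def test_no_holes(self):
        assert self.d.bdrycount == pytest.approx(self.d.circumference)


class TestSquare:
    s = 100

    @pytest.fixture(autouse=True)
    def _extract(self, square_mask):
        self.d = extract_all(square_mask)

    def test_area_exact(self):
        assert self.d.area == self.s**2

    def test_vertical_rectangle_exact(self):
        assert self.d.vrectsizex == self.s
        assert self.d.vrectsizey == self.s

    def test_hull_metrics(self):
        assert self.d.conhullcirc == pytest.approx(4 * self.s, abs=4)
        assert self.d.conhullarea == pytest.approx(self.s**2, rel=1e-9)

    def test_maxdiam_is_diagonal(self):
        assert self.d.maxdiam == pytest.approx(self.s * math.sqrt(2), rel=1e-9)

    def test_mincirclediam_is_diagonal(self):
        assert self.d.mincirclediam == pytest.approx(self.s * math.sqrt(2), rel=1e-6)

    def test_roundness_near_16(self):
        # perimeter quantization keeps this within ~1% of the exact 16
        assert self.d.roundness == pytest.approx(16.0, rel=0.025)

    def test_compactness_one(self):
        assert self.d.compactness == pytest.approx(1.0, rel=1e-9)

    def test_mindistcenbdy_half_side(self):
        assert self.d.mindistcenbdy == pytest.approx(self.s / 2, abs=1.0)

    def test_minrectarea(self):
        assert self.d.minrectarea == pytest.approx(self.s**2, rel=1e-9)


class TestRectangleAndScale:
    def test_axis_aligned_rect(self):
        g = np.zeros((120, 80), dtype=bool)
        g[20:100, 20:60] = True  # 40 wide, 80 tall
        d = extract_all(BinaryMask(g, 1.0))
        assert d.vrectsizex == 40
        assert d.vrectsizey == 80
        assert d.minrectarea == pytest.approx(3200, rel=1e-9)

    def test_rect_scale_factor_halves_lengths(self):
        g = np.zeros((120, 80), dtype=bool)
        g[20:100, 20:60] = True
        d1 = extract_all(BinaryMask(g, 1.0))
        d2 = extract_all(BinaryMask(g, 2.0))
        assert d2.area == pytest.approx(d1.area / 4)
        assert d2.vrectsizex == pytest.approx(d1.vrectsizex / 2)
        assert d2.circumference == pytest.approx(d1.circumference / 2)
        for ratio in ("compactness", "roundness", "normrotmo", "paxratio",
                      "normsmallpax", "normlargepax", "bdryround", "excentricity"):
            assert getattr(d1, ratio) == pytest.approx(getattr(d2, ratio), abs=1e-9)

    def test_rotated_rect_min_area_matches_sweep_oracle(self):
        g = rotated_rect_grid(40, 80, 30.0)
        d = extract_all(BinaryMask(g, 1.0))
        oracle = sweep_min_rect_area(boundary_pixel_corners(g))
        assert d.minrectarea == pytest.approx(oracle, rel=0.005)
        # the pixel-square union of the digitized rectangle genuinely
        # spans (40 + cos30 + sin30) x (80 + cos30 + sin30), ~5% above
        # the continuous 3200 at this size
        assert d.minrectarea == pytest.approx(3200, rel=0.055)

    def test_rotated_rect_min_area_large_within_3pct(self):
        g = rotated_rect_grid(80, 160, 30.0, size=400)
        d = extract_all(BinaryMask(g, 1.0))
        assert d.minrectarea == pytest.approx(80 * 160, rel=0.03)

    def test_line_maxdiam(self):
        g = np.zeros((20, 120), dtype=bool)
        g[10, 10:110] = True  # 100 px segment
        d = extract_all(BinaryMask(g, 1.0))
        assert d.maxdiam == pytest.approx(100.0, abs=0.1)


class TestAnnulus:
    def test_contour_counts(self, annulus_mask, square_mask):
        cs = contours(annulus_mask)
        assert sum(not c.is_hole for c in cs) == 1
        assert sum(c.is_hole for c in cs) == 1
        assert all(not c.is_hole for c in contours(square_mask))

    def test_bdrycount_exceeds_circumference(self, annulus_mask):
        d = extract_all(annulus_mask)
        assert d.bdrycount > d.circumference

    def test_bdrycount_within_2pct(self, annulus_mask):
        d = extract_all(annulus_mask)
        assert d.bdrycount == pytest.approx(400 + 200, rel=0.02)

    def test_mindistcenbdy_to_hole(self, annulus_mask):
        # centroid sits in the hole centre; nearest boundary is the hole
        # contour at half the hole side
        d = extract_all(annulus_mask)
        assert d.mindistcenbdy == pytest.approx(25.0, abs=1.0)

    def test_bdryround_consistency(self, annulus_mask):
        d = extract_all(annulus_mask)
        assert d.bdryround == pytest.approx(d.bdrycount**2 / d.area, rel=1e-9)
        assert d.bdrytoarearatio == pytest.approx(d.bdrycount / d.area, rel=1e-9)


class TestTriangleAndStar:
    def test_equilateral_triangle_circumdiameter(self):
        from skimage.draw import polygon as draw_polygon

        a = 90.0
        h = a * math.sqrt(3) / 2
        g = np.zeros((140, 140), dtype=bool)
        rr, cc = draw_polygon([120, 120 - h, 120], [20, 20 + a / 2, 20 + a], shape=g.shape)
        g[rr, cc] = True
        d = extract_all(BinaryMask(g, 1.0))
        assert d.mincirclediam == pytest.approx(2 * a / math.sqrt(3), rel=0.02)

    def test_star_hull_exceeds_area(self):
        d = extract_all(BinaryMask(star_grid(), 1.0))
        assert d.conhullarea > d.area
        assert d.compactness < 0.8


# ---------------------------------------------------------------------------
# oracle equivalence on random blobs
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", [0, 1, 2])
class TestBlobOracles:
    @pytest.fixture(autouse=True)
    def _blob(self, seed):
        self.grid = small_blob(seed)
        self.mask = BinaryMask(self.grid, 1.0)
        self.d = extract_all(self.mask)
        self.corners = boundary_pixel_corners(self.grid)

    def test_maxdiam_matches_all_pairs(self):
        assert self.d.maxdiam == pytest.approx(
            max_pairwise_distance(self.corners), rel=1e-12
        )

    def test_vertical_rect_matches_coordinate_scan(self):
        rows, cols = np.nonzero(self.grid)
        assert self.d.vrectsizex == cols.max() - cols.min() + 1
        assert self.d.vrectsizey == rows.max() - rows.min() + 1

    def test_hull_area_matches_gift_wrap(self):
        hull = gift_wrap_hull(self.corners)
        assert self.d.conhullarea == pytest.approx(shoelace_area(hull), rel=1e-9)

    def test_min_rect_matches_sweep(self):
        oracle = sweep_min_rect_area(self.corners)
        assert self.d.minrectarea == pytest.approx(oracle, rel=0.005)
        assert self.d.minrectarea <= oracle + 1e-6

    def test_min_circle_matches_exact(self):
        from scipy.spatial import ConvexHull

        hull_pts = self.corners[ConvexHull(self.corners).vertices]
        exact = exact_min_circle(hull_pts)
        assert self.d.mincirclediam == pytest.approx(2 * exact, rel=1e-6)

    def test_axis_stats_match_pixel_loop(self):
        rows, cols = np.nonzero(self.grid)
        cy, cx = rows.mean(), cols.mean()
        cov = np.cov(np.vstack([rows - cy, cols - cx]), ddof=0)
        evals, evecs = np.linalg.eigh(cov)
        total_major = total_minor = total_r2 = 0.0
        for r, c in zip(rows, cols):
            dy, dx = r - cy, c - cx
            total_major += abs(dy * evecs[0, 1] + dx * evecs[1, 1])
            total_minor += abs(dy * evecs[0, 0] + dx * evecs[1, 0])
            total_r2 += dy * dy + dx * dx
        n = rows.size
        assert self.d.normlargepax == pytest.approx(total_major / n, rel=1e-9)
        assert self.d.normsmallpax == pytest.approx(total_minor / n, rel=1e-9)
        assert self.d.normrotmo == pytest.approx(total_r2 / n**2, rel=1e-9)

    def test_mindistcenbdy_matches_vertex_scan(self):
        rows, cols = np.nonzero(self.grid)
        cy, cx = rows.mean(), cols.mean()
        best = min(
            float(np.hypot(c.vertices[:, 0] - cy, c.vertices[:, 1] - cx).min())
            for c in contours(self.mask)
        )
        assert self.d.mindistcenbdy == pytest.approx(best, rel=1e-12)


# ---------------------------------------------------------------------------
# structural behaviour
# ---------------------------------------------------------------------------


class TestStructure:
    def test_exactly_20_descriptors(self, disc_mask):
        values = extract_all(disc_mask).as_dict()
        assert len(values) == 20
        assert tuple(values) == DESCRIPTOR_NAMES

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError, match="no plant"):
            extract_all(BinaryMask(np.zeros((5, 5), dtype=bool), 1.0))

    def test_largest_component_selected(self):
        g = disc_grid(20, pad=40)
        g[2:5, 2:5] = True  # small satellite blob
        comp = largest_component(BinaryMask(g, 1.0))
        assert not comp[2:5, 2:5].any()
        assert comp.sum() == disc_grid(20, pad=40).sum()

    def test_single_pixel_degenerate(self):
        g = np.zeros((5, 5), dtype=bool)
        g[2, 2] = True
        d = extract_all(BinaryMask(g, 1.0))
        assert d.area == 1.0
        assert d.vrectsizex == 1.0 and d.vrectsizey == 1.0
        assert math.isnan(d.paxratio)

    def test_collinear_pixels_flagged_missing(self):
        g = np.zeros((5, 20), dtype=bool)
        g[2, 3:17] = True
        nspax, nlpax, paxr, exc, nrotmo = principal_axis_stats(BinaryMask(g, 1.0))
        assert nspax == 0.0
        assert math.isnan(paxr)
        assert np.isfinite(nrotmo)

    def test_rotation_90_swaps_vrect(self):
        g = rotated_rect_grid(40, 80, 25.0)
        d1 = extract_all(BinaryMask(g, 1.0))
        d2 = extract_all(BinaryMask(np.rot90(g).copy(), 1.0))
        assert d1.vrectsizex == d2.vrectsizey
        assert d1.vrectsizey == d2.vrectsizex
        for name in ("area", "maxdiam", "mincirclediam", "minrectarea",
                     "compactness", "roundness"):
            assert getattr(d1, name) == pytest.approx(getattr(d2, name), rel=0.01)

    def test_chain_length_diagonal_steps(self):
        contour = np.array([[0, 0], [1, 1], [1, 2]])
        # closed: sqrt2 + 1 + back to start sqrt(1+4)
        assert chain_length(contour) == pytest.approx(math.sqrt(2) + 1 + math.sqrt(5))

    def test_trace_boundary_square(self):
        g = square_grid(4, pad=2)
        b = trace_boundary(g)
        assert len(b) == 12  # 4x4 square boundary pixels
        assert (b.min(), b.max()) == (2, 5)


def test_ordering_invariants_on_random_rosettes():
    """Ordering invariants over many random synthetic rosettes."""
    rng = np.random.default_rng(42)
    eps = 1e-6
    checked = 0
    for i in range(1000):
        params = RosettePhenotypeParams(
            n_leaves=int(rng.integers(1, 9)),
            leaf_length=float(rng.uniform(2.5, 6.0)),
            leaf_width=float(rng.uniform(1.2, 3.0)),
            petiole_length=float(rng.uniform(0.0, 4.0)),
            jitter_sd=float(rng.uniform(0.0, 8.0)),
            image_size=96,
            px_per_mm=4.0,
        )
        d = extract_all(render_rosette(params, seed=i))
        assert d.conhullarea >= d.area - eps
        assert 0.0 < d.compactness <= 1.0 + eps
        assert d.maxdiam <= d.mincirclediam * (1 + 1e-6)
        assert d.minrectarea <= d.vrectsizex * d.vrectsizey + eps
        assert d.roundness >= 4 * math.pi * (1 - 0.1)
        assert d.bdrycount >= d.circumference - eps
        checked += 1
    assert checked == 1000


def test_min_circle_welzl_validity():
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 100, size=(40, 2))
    cy, cx, r = min_enclosing_circle_of(pts)
    dist = np.hypot(pts[:, 0] - cy, pts[:, 1] - cx)
    assert np.all(dist <= r + 1e-6)
    assert exact_min_circle(pts) == pytest.approx(r, rel=1e-6)
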