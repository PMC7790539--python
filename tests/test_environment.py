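"""Pillar lattices, disorder, rasterization, and Voronoi statistics."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist

import stericlv as slv
from stericlv.environment import GeometryError


def brute_force_lattice(L, dx):
    """Direct enumeration of triangular-lattice sites inside [0, L]²."""
    row_h = dx * np.sqrt(3) / 2
    pts = []
    for j in range(int(L / row_h) + 2):
        y = dx / 2 + j * row_h
        if y > L:
            break
        x0 = dx / 2 if j % 2 else 0.0
        k = 0
        while x0 + k * dx <= L:
            pts.append((x0 + k * dx, y))
            k += 1
    return np.array(pts)


class TestTriangularLattice:
    def test_nearest_neighbor_spacing(self):
        centers = slv.build_triangular_lattice(150, 10.5, 3)
        d = pdist(centers)
        assert d.min() == pytest.approx(10.5, rel=1e-12)
        # every pillar's nearest neighbor sits at exactly the lattice constant
        dm = cdist(centers, centers)
        np.fill_diagonal(dm, np.inf)
        assert np.allclose(dm.min(axis=1), 10.5)

    def test_small_lattice_matches_enumeration(self):
        centers = slv.build_triangular_lattice(21, 10.5, 3)
        expected = brute_force_lattice(21, 10.5)
        assert len(centers) == len(expected)
        assert np.allclose(np.sort(centers, axis=0),
                           np.sort(expected, axis=0))

    def test_centers_inside_box(self):
        centers = slv.build_triangular_lattice(40, 9, 3)
        assert np.all(centers >= 0) and np.all(centers <= 40)

    def test_overlapping_lattice_rejected(self):
        with pytest.raises(GeometryError):
            slv.build_triangular_lattice(150, 5.9, 3)


class TestDisorder:
    def test_zero_disorder_is_identity(self, rng):
        centers = slv.build_triangular_lattice(42, 10.5, 3)
        out = slv.apply_disorder(centers, 0.0, 10.5, 3, rng)
        assert np.array_equal(out, centers)

    def test_max_displacement_magnitude(self, rng):
        centers = slv.build_triangular_lattice(150, 10.5, 3)
        out = slv.apply_disorder(centers, 1.0, 10.5, 3, rng)
        disp = np.linalg.norm(out - centers, axis=1)
        w = 1.0 * (10.5 - 3) / 2  # = 3.75
        assert disp.max() <= w + 1e-12
        assert disp.max() > 0.9 * w  # uniform magnitude actually reaches w

    def test_reproducible_given_seed(self):
        centers = slv.build_triangular_lattice(42, 10.5, 3)
        a = slv.apply_disorder(centers, 0.7, 10.5, 3, 99, L=42)
        b = slv.apply_disorder(centers, 0.7, 10.5, 3, 99, L=42)
        assert np.array_equal(a, b)

    def test_clamped_to_box(self):
        centers = slv.build_triangular_lattice(42, 10.5, 3)
        out = slv.apply_disorder(centers, 1.0, 10.5, 3, 3, L=42)
        assert np.all(out >= 0) and np.all(out <= 42)

    def test_large_disorder_approaches_random_pattern(self):
        """Pairwise-distance distributions move monotonically toward the
        uniform-random pattern as delta grows."""
        L, dx, R = 60.0, 10.5, 3.0
        centers = slv.build_triangular_lattice(L, dx, R)
        rng = np.random.default_rng(0)
        rand = [rng.uniform(0, L, size=centers.shape) for _ in range(20)]
        d_rand = np.concatenate([pdist(s) for s in rand])
        bins = np.linspace(0, L, 25)
        h_rand, _ = np.histogram(d_rand, bins=bins, density=True)

        def dist_to_random(delta):
            if delta == 0:
                samples = [centers]
            else:
                samples = [slv.apply_disorder(centers, delta, dx, R, rng,
                                              L=L) for _ in range(20)]
            d = np.concatenate([pdist(s) for s in samples])
            h, _ = np.histogram(d, bins=bins, density=True)
            return np.abs(h - h_rand).sum()

        d0, d1, d4 = (dist_to_random(v) for v in (0.0, 1.0, 4.0))
        assert d1 < d0
        assert d4 < d1
        assert d4 < 0.2 * d0


class TestRasterization:
    def test_empty_box_area(self):
        mask, area = slv.rasterize_mask(np.empty((0, 2)), 3, 150)
        assert mask.all()
        assert area == pytest.approx(150 ** 2, rel=1e-12)

    def test_single_pillar_area_deficit(self):
        _, empty = slv.rasterize_mask(np.empty((0, 2)), 3, 150)
        _, area = slv.rasterize_mask(np.array([[75.0, 75.0]]), 3, 150)
        # pixel counting matches the analytic disk area to ~ one pixel row
        # along the perimeter
        px = 1.0 / slv.PIXELS_PER_LAMBDA
        assert empty - area == pytest.approx(np.pi * 9, abs=2 * np.pi * 3 * px)

    def test_pillar_outside_box_ignored(self):
        ref, _ = slv.rasterize_mask(np.empty((0, 2)), 3, 40)
        mask, _ = slv.rasterize_mask(np.array([[80.0, 80.0]]), 3, 40)
        assert np.array_equal(mask, ref)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(GeometryError):
            slv.rasterize_mask(np.empty((0, 2)), 0.1, 1.0)

    def test_resolution_convergence(self):
        """Invalid-pixel area converges to the disk area as resolution
        doubles and quadruples."""
        centers = np.array([[20.0, 20.0], [32.0, 20.0]])
        target = 2 * np.pi * 9
        errs = []
        for mult in (1, 2, 4):
            ppl = slv.PIXELS_PER_LAMBDA * mult
            mask, area = slv.rasterize_mask(centers, 3, 40, ppl)
            errs.append(abs((40 ** 2 - area) - target))
        assert errs[2] < errs[0]
        assert errs[2] < target * 0.01


class TestVoronoi:
    def test_ordered_interior_pillars_have_six_neighbors(
            self, standard_lattice_env):
        nb = slv.pillar_voronoi(standard_lattice_env.centers, 150)
        counts = nb.neighbor_counts()
        assert len(counts) > 50
        assert set(counts.values()) == {6}

    def test_disordered_neighbor_counts_concentrate_on_5_to_7(self):
        env = slv.make_environment(150, 10.5, 3, delta=1.0, seed=7)
        nb = slv.pillar_voronoi(env.centers, 150)
        counts = np.array(list(nb.neighbor_counts().values()))
        frac_5_7 = np.mean((counts >= 5) & (counts <= 7))
        assert frac_5_7 > 0.9

    def test_symmetric_no_self_pairs(self, small_lattice_env):
        nb = slv.pillar_voronoi(small_lattice_env.centers, 42)
        for i, j in nb.neighbor_pairs:
            assert i < j
        assert np.all(nb.nn_distances > 0)

    def test_four_corner_pillars_all_edge(self):
        centers = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        nb = slv.pillar_voronoi(centers, 1.0)
        assert not nb.interior.any()
        assert nb.neighbor_pairs == set()

    def test_collinear_pillars_degenerate(self):
        centers = np.column_stack([np.linspace(1, 9, 5), np.full(5, 5.0)])
        with pytest.raises(GeometryError):
            slv.pillar_voronoi(centers, 10)

    def test_brute_force_delaunay_agreement(self):
        """Tessellation neighbor pairs agree with an independent all-pairs
        empty-circumcircle check on a small disordered instance."""
        env = slv.make_environment(42, 10.5, 3, delta=0.8, seed=11)
        pts = env.centers
        assert len(pts) <= 30
        nb = slv.pillar_voronoi(pts, 42)
        interior = nb.interior
        # brute force: i, j are Delaunay neighbors iff some circle through
        # i and j contains no other point; test circles through each third
        # point plus the diametral circle
        from itertools import combinations
        brute = set()
        n = len(pts)
        for i, j in combinations(range(n), 2):
            if not (interior[i] and interior[j]):
                continue
            neighbor = False
            mid = (pts[i] + pts[j]) / 2
            r = np.linalg.norm(pts[i] - pts[j]) / 2
            d = np.linalg.norm(pts - mid, axis=1)
            d[[i, j]] = np.inf
            if d.min() > r:
                neighbor = True
            else:
                for k in range(n):
                    if k in (i, j):
                        continue
                    c, rc = _circumcircle(pts[i], pts[j], pts[k])
                    if c is None:
                        continue
                    dd = np.linalg.norm(pts - c, axis=1)
                    dd[[i, j, k]] = np.inf
                    if dd.min() > rc + 1e-9:
                        neighbor = True
                        break
            if neighbor:
                brute.add((i, j))
        assert brute == nb.neighbor_pairs


def _circumcircle(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None, None
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, np.linalg.norm(a - center)


class TestDistanceDistributions:
    def test_ordered_nn_point_mass_at_dx(self, standard_lattice_env):
        d = slv.distance_distributions(standard_lattice_env)
        assert np.allclose(d["voronoi_nn"], 10.5)

    def test_disorder_creates_closer_neighbors(self):
        env = slv.make_environment(150, 10.5, 3, delta=1.0, seed=3)
        d = slv.distance_distributions(env)
        assert np.mean(d["voronoi_nn"] < 10.5) > 0.1

    def test_two_pillars(self):
        env = slv.StericEnvironment(
            box_side=40.0, pillar_radius=3.0, lattice_spacing=20.0,
            disorder=0.0, centers=np.array([[10.0, 20.0], [30.0, 20.0]]))
        d = slv.distance_distributions(env)
        assert d["pairwise"].shape == (1,)
        assert d["pairwise"][0] == pytest.approx(20.0)

    def test_scale_free_disorder(self):
        """Same (dx, R, delta) at L and 2L give matching nearest-neighbor
        distance distributions within sampling error."""
        ds = {}
        for L in (75.0, 150.0):
            samples = []
            for seed in range(4):
                env = slv.make_environment(L, 10.5, 3, delta=0.8, seed=seed)
                samples.append(
                    slv.distance_distributions(env)["voronoi_nn"])
            ds[L] = np.concatenate(samples)
        from scipy.stats import ks_2samp
        stat, p = ks_2samp(ds[75.0], ds[150.0])
        assert p > 0.01


class TestLocalDomainStats:
    def test_ordered_longest_edge_equals_dx(self, standard_lattice_env):
        nb = slv.pillar_voronoi(standard_lattice_env.centers, 150)
        stats = slv.local_domain_stats(standard_lattice_env.centers, nb,
                                       10.5)
        edges = np.array(list(stats["longest_edge"].values()))
        assert np.allclose(edges, 10.5, atol=1e-9)
        assert stats["fraction_below_dx"] == 0.0

    def test_disorder_creates_tight_domains(self):
        """Across an ensemble of disordered environments some neighbor
        polygons become tighter than the ordered lattice allows."""
        edges = []
        for seed in range(5):
            env = slv.make_environment(150, 10.5, 3, delta=1.0, seed=seed)
            nb = slv.pillar_voronoi(env.centers, 150)
            stats = slv.local_domain_stats(env.centers, nb, 10.5)
            edges.extend(stats["longest_edge"].values())
        assert np.mean(np.array(edges) < 10.5) > 0.0


class TestMinSystemArea:
    def test_values_and_warning(self):
        out = slv.min_system_area(8, 10.5, L=150)
        assert out["min_area"] == pytest.approx(882.0)
        assert out["too_small"] is False
        assert slv.min_system_area(1, 10.5)["min_area"] == \
            pytest.approx(10.5 ** 2)
        assert slv.min_system_area(8, 10.5, L=20)["too_small"] is True
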