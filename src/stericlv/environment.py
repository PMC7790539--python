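"""Steric environments: pillar lattices, disorder, rasterized masks, and
point-pattern statistics.

The habitat is a square box of side ``L`` (in units of the natural length
λ = sqrt(D/r)) containing impenetrable circular pillars of radius ``R``.
Pillars sit on a triangular lattice with nearest-neighbor spacing ``dx`` and
may be displaced by a controlled amount of positional disorder ``delta``.
The box is discretized on a pixel grid (default 5 pixels per 1.29 λ) and a
boolean mask marks habitable pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, Voronoi
from scipy.spatial.distance import pdist

#: Default pixel density: 5 pixels span 1.29 natural lengths.
PIXELS_PER_LAMBDA = 5.0 / 1.29


class GeometryError(ValueError):
    """Invalid steric geometry (overlapping lattice, degenerate grid, ...)."""


@dataclass
class StericEnvironment:
    """A pillared habitat plus its rasterization.

    All lengths are in natural units λ.  ``valid_mask`` is True on habitable
    pixels (inside the box, outside every pillar disk); ``valid_area`` is the
    habitable area in λ².
    """

    box_side: float
    pillar_radius: float
    lattice_spacing: float
    disorder: float
    centers: np.ndarray
    pixels_per_lambda: float = PIXELS_PER_LAMBDA
    seed: int | None = None
    valid_mask: np.ndarray = field(default=None, repr=False)
    valid_area: float = field(default=None)

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.size == 0:
            self.centers = self.centers.reshape(0, 2)
        if self.valid_mask is None:
            self.valid_mask, self.valid_area = rasterize_mask(
                self.centers, self.pillar_radius, self.box_side,
                self.pixels_per_lambda)
        # effective pixel scale: the grid tiles [0, L]² exactly
        self.pixels_per_lambda = self.valid_mask.shape[0] / self.box_side

    @property
    def n_pillars(self) -> int:
        return len(self.centers)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.valid_mask.shape

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in λ²."""
        return (1.0 / self.pixels_per_lambda) ** 2

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinates (x, y) in λ, shaped like the mask."""
        n = self.valid_mask.shape[0]
        c = (np.arange(n) + 0.5) / self.pixels_per_lambda
        x, y = np.meshgrid(c, c)  # row index = y, column index = x
        return x, y


def build_triangular_lattice(L: float, dx: float, R: float) -> np.ndarray:
    """Pillar centers of an ordered triangular lattice inside [0, L]².

    Rows run parallel to the x-axis with vertical spacing dx·√3/2; the first
    row sits at y = dx/2 and alternate rows are offset by +dx/2 in x.
    """
    if dx <= 2 * R:
        raise GeometryError(
            f"lattice spacing dx={dx} must exceed pillar diameter {2 * R}")
    if L <= dx:
        raise GeometryError(f"box side L={L} must exceed lattice spacing {dx}")
    row_h = dx * np.sqrt(3.0) / 2.0
    centers = []
    j = 0
    y = dx / 2.0
    while y <= L:
        x0 = (dx / 2.0) if (j % 2) else 0.0
        x = x0
        while x <= L:
            centers.append((x, y))
            x += dx
        j += 1
        y = dx / 2.0 + j * row_h
    return np.array(centers, dtype=float)


def apply_disorder(centers: np.ndarray, delta: float, dx: float, R: float,
                   rng, L: float | None = None) -> np.ndarray:
    """Displace each center by Uniform[0, w] in a uniform random direction.

    The displacement width w = delta·(dx − R)/2 follows the dimensionless
    disorder definition delta = 2w/(dx − R).  Centers pushed outside the box
    are clamped to its boundary.  Pillar overlap is allowed.
    """
    if delta < 0:
        raise ValueError("disorder delta must be >= 0")
    rng = np.random.default_rng(rng)
    centers = np.asarray(centers, dtype=float)
    if delta == 0 or len(centers) == 0:
        return centers.copy()
    w = delta * (dx - R) / 2.0
    mag = rng.uniform(0.0, w, size=len(centers))
    theta = rng.uniform(0.0, 2 * np.pi, size=len(centers))
    out = centers + np.column_stack([mag * np.cos(theta), mag * np.sin(theta)])
    if L is not None:
        np.clip(out, 0.0, L, out=out)
    return out


def rasterize_mask(centers: np.ndarray, R: float, L: float,
                   pixels_per_lambda: float = PIXELS_PER_LAMBDA,
                   ) -> tuple[np.ndarray, float]:
    """Boolean habitability mask and habitable area A (λ²).

    A pixel is invalid iff its center lies within distance R of any pillar
    center.  Grid side n = round(L · pixels_per_lambda); the grid tiles the
    box exactly, so the effective pixel scale is n/L (within a fraction of a
    percent of the request) and pixel (i, j) has its center at
    x = (j + 0.5)·L/n, y = (i + 0.5)·L/n.
    """
    if pixels_per_lambda <= 0:
        raise ValueError("pixels_per_lambda must be positive")
    n = int(round(L * pixels_per_lambda))
    if n < 10:
        raise GeometryError(f"grid side {n} px is degenerate (< 10 pixels)")
    mask = np.ones((n, n), dtype=bool)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.size:
        c = (np.arange(n) + 0.5) * (L / n)
        x, y = np.meshgrid(c, c)
        r2 = R * R
        for cx, cy in centers:
            # skip pillars entirely outside the grid's reach
            if cx < -R or cx > L + R or cy < -R or cy > L + R:
                continue
            mask &= (x - cx) ** 2 + (y - cy) ** 2 > r2
    area = mask.sum() * (L / n) ** 2
    return mask, float(area)


def make_environment(L: float, dx: float, R: float, delta: float = 0.0,
                     seed=None,
                     pixels_per_lambda: float = PIXELS_PER_LAMBDA,
                     ) -> StericEnvironment:
    """Build a (possibly disordered) pillared environment in one call."""
    centers = build_triangular_lattice(L, dx, R)
    if delta > 0:
        centers = apply_disorder(centers, delta, dx, R,
                                 np.random.default_rng(seed), L=L)
    return StericEnvironment(box_side=L, pillar_radius=R, lattice_spacing=dx,
                             disorder=delta, centers=centers, seed=seed,
                             pixels_per_lambda=pixels_per_lambda)


def empty_environment(L: float,
                      pixels_per_lambda: float = PIXELS_PER_LAMBDA,
                      ) -> StericEnvironment:
    """An isotropic (pillar-free) box, for unstructured control runs."""
    return StericEnvironment(box_side=L, pillar_radius=0.0,
                             lattice_spacing=L, disorder=0.0,
                             centers=np.empty((0, 2)),
                             pixels_per_lambda=pixels_per_lambda)


@dataclass
class VoronoiNeighborhood:
    """Voronoi adjacency of the pillar point pattern.

    ``interior`` flags pillars whose Voronoi cell is bounded and lies fully
    inside the box; neighbor statistics are restricted to interior pillars,
    which mirrors discarding edge pillars in the image analysis.
    """

    neighbor_pairs: set  # unordered interior-pillar index pairs
    interior: np.ndarray  # per-pillar bool
    nn_distances: np.ndarray  # per interior pair, center-to-center (λ)
    delaunay_triangles: np.ndarray  # (n_tri, 3) interior mutual neighbors
    all_neighbors: dict  # pillar index -> set of Voronoi neighbors (any)

    def neighbor_counts(self) -> dict:
        """Voronoi-neighbor count of every interior pillar (neighbors may
        themselves be edge pillars)."""
        return {int(i): len(self.all_neighbors[int(i)])
                for i in np.flatnonzero(self.interior)}


def pillar_voronoi(centers: np.ndarray, L: float) -> VoronoiNeighborhood:
    """Voronoi tessellation of pillar centers with edge-pillar exclusion.

    A pillar is *interior* iff its Voronoi cell is bounded and all its cell
    vertices lie inside [0, L]².  ``neighbor_pairs`` keeps pairs where both
    pillars are interior; ``all_neighbors`` keeps the full ridge adjacency
    (needed, e.g., for neighbor polygons of interior pillars whose neighbors
    are edge pillars).
    """
    centers = np.asarray(centers, dtype=float)
    if len(centers) < 4:
        raise GeometryError("Voronoi analysis needs at least 4 pillars")
    try:
        vor = Voronoi(centers)
    except Exception as exc:  # qhull degeneracy (collinear input etc.)
        raise GeometryError(f"degenerate tessellation: {exc}") from exc

    m = len(centers)
    interior = np.zeros(m, dtype=bool)
    verts = vor.vertices
    inside = np.all((verts >= 0.0) & (verts <= L), axis=1)
    for i in range(m):
        region = vor.regions[vor.point_region[i]]
        if not region or -1 in region:
            continue  # unbounded cell
        interior[i] = bool(np.all(inside[region]))

    all_neighbors: dict[int, set] = {i: set() for i in range(m)}
    pairs = set()
    for a, b in vor.ridge_points:
        a, b = int(a), int(b)
        all_neighbors[a].add(b)
        all_neighbors[b].add(a)
        if interior[a] and interior[b]:
            pairs.add((min(a, b), max(a, b)))

    nn_d = np.array([np.linalg.norm(centers[i] - centers[j])
                     for i, j in sorted(pairs)])

    tris = []
    if m >= 4:
        tri = Delaunay(centers)
        for simplex in tri.simplices:
            s = sorted(int(v) for v in simplex)
            if all(interior[v] for v in s):
                e = [(s[0], s[1]), (s[0], s[2]), (s[1], s[2])]
                if all(p in pairs for p in e):
                    tris.append(s)
    tris = np.array(tris, dtype=int) if tris else np.empty((0, 3), dtype=int)

    return VoronoiNeighborhood(neighbor_pairs=pairs, interior=interior,
                               nn_distances=nn_d, delaunay_triangles=tris,
                               all_neighbors=all_neighbors)


def distance_distributions(env: StericEnvironment,
                           neighborhood: VoronoiNeighborhood | None = None,
                           bins=None) -> dict:
    """All-pairs and Voronoi-nearest-neighbor distance samples (λ).

    For an ordered lattice the neighbor distances collapse onto the lattice
    constant; with disorder both distributions broaden and a fraction of
    neighbors falls below the lattice constant.  Pass ``bins`` (anything
    ``numpy.histogram`` accepts) to also get density-normalized histograms.
    """
    if env.n_pillars < 2:
        raise GeometryError("need at least 2 pillars for distances")
    out = {"pairwise": pdist(env.centers)}
    if neighborhood is None and env.n_pillars >= 4:
        try:
            neighborhood = pillar_voronoi(env.centers, env.box_side)
        except GeometryError:
            neighborhood = None
    out["voronoi_nn"] = (neighborhood.nn_distances if neighborhood is not None
                         else np.empty(0))
    if bins is not None:
        for key in ("pairwise", "voronoi_nn"):
            if len(out[key]):
                hist, edges = np.histogram(out[key], bins=bins, density=True)
                out[f"{key}_hist"] = (hist, edges)
    return out


def local_domain_stats(centers: np.ndarray,
                       neighborhood: VoronoiNeighborhood,
                       dx: float) -> dict:
    """Longest edge of each interior pillar's neighbor polygon.

    For each interior pillar, take the convex polygon through its Voronoi
    neighbors (interior or not) and record the longest polygon edge; the
    fraction of polygons whose longest edge falls below the lattice constant
    measures how often disorder creates locally *tighter* prospective domains
    than the ordered lattice provides.
    """
    centers = np.asarray(centers, dtype=float)
    idx = np.flatnonzero(neighborhood.interior)
    if idx.size == 0:
        raise GeometryError("no interior pillars")
    longest = {}
    for i in idx:
        nbrs = sorted(neighborhood.all_neighbors[i])
        pts = centers[nbrs]
        if len(pts) < 3:
            continue
        hull = ConvexHull(pts)
        hv = pts[hull.vertices]
        edges = np.linalg.norm(np.roll(hv, -1, axis=0) - hv, axis=1)
        longest[int(i)] = float(edges.max())
    vals = np.array(list(longest.values()))
    return {
        "longest_edge": longest,
        "fraction_below_dx": float(np.mean(vals < dx)) if vals.size else 0.0,
    }


def min_system_area(N: int, dx: float, L: float | None = None) -> dict:
    """Advisory minimum habitable area N·dx² for N species.

    Each species needs at least one Delaunay-triangle-sized domain, which
    sets a lower bound on the system area scaling as N·dx².  If ``L`` is
    given, ``too_small`` flags L² < N·dx².
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    a = N * dx * dx
    out = {"min_area": float(a)}
    if L is not None:
        out["too_small"] = bool(L * L < a)
    return out
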