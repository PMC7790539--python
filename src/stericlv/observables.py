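"""Per-run observables: abundances, domain labeling, interspecies-boundary
segmentation, and the Voronoi connection density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import label as cc_label
from scipy.spatial import cKDTree

from .environment import StericEnvironment, VoronoiNeighborhood

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class AbundanceSummary:
    """Equilibrium abundance summary of one run."""

    area_fractions: np.ndarray  # per species, mean density over valid area
    survivor_count: int
    survivor_indices: np.ndarray
    nsd: float


@dataclass
class BoundaryGraph:
    """Segmented interspecies boundaries and the pillars they connect.

    Components touching the box edge are flagged and excluded from pillar
    pair counting, mirroring the treatment of edge-contacting boundaries in
    the image analysis.
    """

    boundary_mask: np.ndarray
    n_components: int
    component_pillars: list  # per component, sorted tuple of pillar indices
    edge_contact: np.ndarray  # per component bool
    connected_pairs: set  # unordered pillar index pairs (non-edge comps)

    def contact_histogram(self) -> dict:
        """Histogram of pillars-contacted counts over non-edge components."""
        out: dict[int, int] = {}
        for pillars, edge in zip(self.component_pillars, self.edge_contact):
            if edge:
                continue
            out[len(pillars)] = out.get(len(pillars), 0) + 1
        return out


def area_fractions(fields: np.ndarray, env: StericEnvironment) -> np.ndarray:
    """Fraction of the habitable area occupied by each species (its mean
    density over valid pixels)."""
    m = env.valid_mask
    n_valid = int(m.sum())
    return fields[:, m].sum(axis=1) / n_valid


def nsd(fractions: np.ndarray, survivor_indices) -> float:
    """Normalized standard deviation of area fractions across survivors.

    Population standard deviation on the 0-1 area-fraction scale: 0 means
    all coexisting species are equally abundant; values near 1 mean
    abundance differences comparable to the whole system.
    """
    idx = np.asarray(survivor_indices)
    if idx.size == 0:
        raise ValueError("NSD is undefined with zero survivors")
    return float(np.std(np.asarray(fractions)[idx]))


def label_domains(fields: np.ndarray, env: StericEnvironment,
                  boundary_threshold: float = 0.5,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Label each valid pixel by its arg-max species and segment boundaries.

    Ties in the arg-max go to the lowest species index.  A valid pixel is a
    boundary pixel iff the local maximum density falls below
    ``boundary_threshold`` (the depleted zone of active competition) or its
    label differs from a 4-neighbor's.  Invalid pixels carry label −1.
    """
    m = env.valid_mask
    labels = np.argmax(fields, axis=0).astype(np.int32)
    labels[~m] = -1
    peak = fields.max(axis=0)
    boundary = m & (peak < boundary_threshold)
    # label changes across valid 4-neighbor pairs
    for axis in (0, 1):
        a = np.take(labels, range(labels.shape[axis] - 1), axis=axis)
        b = np.take(labels, range(1, labels.shape[axis]), axis=axis)
        diff = (a != b) & (a >= 0) & (b >= 0)
        if axis == 0:
            boundary[:-1] |= diff
            boundary[1:] |= diff
        else:
            boundary[:, :-1] |= diff
            boundary[:, 1:] |= diff
    return labels, boundary


def build_boundary_graph(boundary_mask: np.ndarray, env: StericEnvironment,
                         contact_radius_px: float = 2.0) -> BoundaryGraph:
    """Connected boundary components and the pillar pairs they join.

    Components are 8-connected.  A component contacts a pillar iff any of
    its pixels lies within ``contact_radius_px`` pixels of the pillar disk;
    a component contacting k pillars joins all k·(k−1)/2 pairs.  Components
    touching the image border are flagged as edge components and contribute
    no pairs.
    """
    lab, n = cc_label(boundary_mask, structure=_EIGHT)
    ppl = env.pixels_per_lambda
    reach = env.pillar_radius + contact_radius_px / ppl
    centers = env.centers
    tree = cKDTree(centers) if len(centers) else None

    comp_pillars: list[tuple] = []
    edge = np.zeros(n, dtype=bool)
    pairs: set[tuple[int, int]] = set()
    ny, nx = boundary_mask.shape
    for c in range(1, n + 1):
        ii, jj = np.nonzero(lab == c)
        edge[c - 1] = bool(ii.min() == 0 or jj.min() == 0
                           or ii.max() == ny - 1 or jj.max() == nx - 1)
        contacted: set[int] = set()
        if tree is not None:
            pts = np.column_stack([(jj + 0.5) / ppl, (ii + 0.5) / ppl])
            for hits in tree.query_ball_point(pts, r=reach):
                contacted.update(int(h) for h in hits)
        comp_pillars.append(tuple(sorted(contacted)))
        if not edge[c - 1] and len(contacted) >= 2:
            ps = sorted(contacted)
            for a in range(len(ps)):
                for b in range(a + 1, len(ps)):
                    pairs.add((ps[a], ps[b]))
    return BoundaryGraph(boundary_mask=boundary_mask, n_components=n,
                         component_pillars=comp_pillars, edge_contact=edge,
                         connected_pairs=pairs)


def connection_density(graph: BoundaryGraph,
                       neighborhood: VoronoiNeighborhood) -> dict:
    """Fraction of interior Voronoi-neighbor pillar pairs joined by an
    interspecies boundary, plus the fraction of joined pairs that are not
    Voronoi neighbors (those are excluded from the numerator)."""
    vpairs = neighborhood.neighbor_pairs
    if not vpairs:
        raise ValueError("no interior Voronoi pairs")
    interior_idx = set(np.flatnonzero(neighborhood.interior).tolist())
    joined = graph.connected_pairs
    joined_voronoi = joined & vpairs
    # restrict the non-Voronoi bookkeeping to pairs of interior pillars, so
    # the statistic is not dominated by edge geometry
    joined_interior = {p for p in joined
                      if p[0] in interior_idx and p[1] in interior_idx}
    non_voronoi = joined_interior - vpairs
    frac_nonvor = (len(non_voronoi) / len(joined_interior)
                   if joined_interior else 0.0)
    return {
        "connection_density": len(joined_voronoi) / len(vpairs),
        "non_voronoi_fraction": frac_nonvor,
        "n_voronoi_pairs": len(vpairs),
        "n_connected_voronoi_pairs": len(joined_voronoi),
    }


def summarize_run(trajectory, env: StericEnvironment,
                  threshold: float | None = None,
                  boundary_threshold: float = 0.5,
                  neighborhood: VoronoiNeighborhood | None = None) -> dict:
    """Standard per-run summary: survivors, fractions, NSD and (when a
    Voronoi neighborhood is supplied or computable) connection density."""
    from .dynamics import extinction_threshold, surviving_species
    from .environment import GeometryError, pillar_voronoi

    if threshold is None:
        threshold = extinction_threshold(env)
    count, idx = surviving_species(trajectory, threshold)
    fields = trajectory.final_state.fields
    fr = area_fractions(fields, env)
    out = {
        "survivor_count": int(count),
        "survivor_indices": idx.tolist(),
        "area_fractions": fr.tolist(),
        "nsd": nsd(fr, idx) if count else float("nan"),
        "terminated_by": trajectory.terminated_by,
        "clamp_events": int(trajectory.clamp_events),
        "extinction_threshold": float(threshold),
    }
    if neighborhood is None and env.n_pillars >= 4:
        try:
            neighborhood = pillar_voronoi(env.centers, env.box_side)
        except GeometryError:
            neighborhood = None
    if neighborhood is not None and neighborhood.neighbor_pairs:
        _, bmask = label_domains(fields, env, boundary_threshold)
        graph = build_boundary_graph(bmask, env)
        out.update(connection_density(graph, neighborhood))
    return out


def save_label_image(labels: np.ndarray, path) -> None:
    """Write the domain label map as a PNG (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    masked = np.ma.masked_where(labels < 0, labels)
    ax.imshow(masked, origin="lower", interpolation="nearest",
              cmap="tab20")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
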