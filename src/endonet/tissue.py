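"""Tissue geometry: cell polygons, structural adjacency, and sensitivity maps.

The endothelium is modelled as a planar sheet of polygonal cells. Structural
("physical") connectivity between cells is defined by the zero-separation
rule: two cells are neighbours when the minimum distance between their ROI
polygons is zero (within a configurable contact tolerance). On a defect-free
hexagonal lattice every interior cell then has exactly six neighbours, which
is the packing observed in en-face endothelial preparations.

Cells on the edge of the imaged field have unknown connectivity and are
flagged as boundary cells: the concave hull (alpha shape) of all cell
centres is computed, and any cell with a polygon vertex falling outside that
envelope is flagged. Boundary cells are excluded from downstream analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely import MultiPoint, STRtree, concave_hull
from shapely.geometry import Polygon


@dataclass(frozen=True)
class TissueMap:
    """The physical cell lattice.

    Attributes
    ----------
    polygons : list of shapely.Polygon
        Cell ROI outlines, in micrometres.
    centroids : ndarray, shape (n_cells, 2)
        Cell centre coordinates (µm).
    neighbors : tuple of frozenset
        Structural adjacency; ``neighbors[i]`` is the set of cell ids in
        zero-separation contact with cell ``i``. Symmetric and irreflexive.
    is_boundary : ndarray of bool
        True for cells touching the edge of the field of view.
    shortcuts : frozenset of frozenset
        Optional long-range links (extended cell processes). These are
        usable by signal propagation but are *not* part of the
        six-neighbour structural lattice.
    """

    polygons: list
    centroids: np.ndarray
    neighbors: tuple
    is_boundary: np.ndarray
    shortcuts: frozenset = field(default_factory=frozenset)

    @property
    def n_cells(self) -> int:
        return len(self.polygons)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    @property
    def interior_ids(self) -> np.ndarray:
        """Ids of non-boundary cells (the analyzed population)."""
        return np.flatnonzero(~self.is_boundary)

    def degree(self, cell_id: int) -> int:
        return len(self.neighbors[cell_id])

    def links_for_propagation(self, cell_id: int) -> frozenset:
        """Structural neighbours plus any shortcut partners of a cell."""
        extra = {next(iter(pair - {cell_id}))
                 for pair in self.shortcuts if cell_id in pair}
        return self.neighbors[cell_id] | extra

    def validate(self) -> None:
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValueError(f"self-adjacency at cell {i}")
            for j in nb:
                if i not in self.neighbors[j]:
                    raise ValueError(f"asymmetric adjacency {i}-{j}")


@dataclass(frozen=True)
class SensitivityMap:
    """Per-cell agonist sensitivity with optional planted-cluster labels.

    ``is_initiator`` marks the pacemaker cell of each planted cluster (the
    accretion seed): agonist-driven oscillations in a sensory cluster are
    initiated there and spread to the other members, which produces the
    stereotyped within-cluster activation sequences seen in recordings. In
    random (unclustered) mode every sensitive cell is its own initiator.
    """

    sensitive: np.ndarray          # bool per cell
    cluster_id: np.ndarray         # int per cell, -1 = none
    agonist_name: str = "agonist"
    is_initiator: np.ndarray | None = None

    @property
    def initiators(self) -> np.ndarray:
        if self.is_initiator is None:
            return self.sensitive
        return self.is_initiator

    @property
    def sensitive_ids(self) -> np.ndarray:
        return np.flatnonzero(self.sensitive)

    @property
    def n_sensitive(self) -> int:
        return int(self.sensitive.sum())


def neighbors_from_rois(polygons, contact_tol: float = 1e-9) -> tuple:
    """Structural adjacency by the zero-separation rule.

    Two cells are neighbours iff the minimum distance between their polygons
    is ``<= contact_tol``. The default tolerance is numerically zero; a
    larger epsilon accommodates rasterized (label-image) inputs where shared
    edges are one pixel apart.
    """
    for i, p in enumerate(polygons):
        if not p.is_valid:
            raise ValueError(f"invalid polygon for cell {i}")
    tree = STRtree(polygons)
    nbrs = [set() for _ in polygons]
    pairs = tree.query(polygons, predicate="dwithin", distance=contact_tol)
    for i, j in pairs.T:
        if i != j:
            nbrs[int(i)].add(int(j))
            nbrs[int(j)].add(int(i))
    return tuple(frozenset(s) for s in nbrs)


def flag_boundary_cells(polygons, centroids, ratio: float = 0.2) -> np.ndarray:
    """Flag cells whose ROI extends beyond the concave hull of cell centres.

    Parameters
    ----------
    ratio : float in [0, 1]
        Concavity of the hull (shapely's ``concave_hull`` ratio); 1 gives
        the convex hull. The default 0.2 traces the outer ring of centres
        on a regular lattice.
    """
    if len(polygons) < 4:
        return np.ones(len(polygons), dtype=bool)
    hull = concave_hull(MultiPoint([tuple(c) for c in centroids]), ratio=ratio)
    if hull.geom_type != "Polygon":
        warnings.warn(
            "degenerate (collinear) cell centres; falling back to convex hull",
            stacklevel=2,
        )
        hull = MultiPoint([tuple(c) for c in centroids]).convex_hull
        if hull.geom_type != "Polygon":
            return np.ones(len(polygons), dtype=bool)
    flags = np.empty(len(polygons), dtype=bool)
    for i, p in enumerate(polygons):
        pts = shapely.points(np.asarray(p.exterior.coords)[:-1])
        flags[i] = bool((shapely.distance(pts, hull) > 1e-9).any())
    return flags


def build_hex_lattice(
    n_rows: int,
    n_cols: int,
    cell_diameter: float = 30.0,
    jitter: float = 0.0,
    seed: int | None = None,
    hull_ratio: float = 0.2,
) -> TissueMap:
    """Build a hexagonally packed sheet of ``n_rows x n_cols`` cells.

    Cells are regular hexagons (pointy-top, odd rows offset) with
    ``cell_diameter`` the distance across flats in µm. ``jitter`` displaces
    each lattice *vertex* uniformly in [-jitter, jitter]² — vertices are
    shared between adjacent cells, so jitter deforms cell shapes without
    opening gaps, and structural adjacency is identical to the jitter-free
    lattice.
    """
    if n_rows < 3 or n_cols < 3:
        raise ValueError("n_rows and n_cols must be >= 3")
    if cell_diameter <= 0:
        raise ValueError("cell_diameter must be positive")
    if jitter < 0 or jitter >= cell_diameter / 4:
        if jitter < 0:
            raise ValueError("jitter must be >= 0")
        raise ValueError("jitter must be < cell_diameter / 4")

    d = float(cell_diameter)
    R = d / np.sqrt(3.0)  # circumradius
    rng = np.random.default_rng(seed)
    offsets: dict = {}

    def vertex(x: float, y: float) -> tuple:
        # vertex coords lie on a grid of (d/2, R/2) multiples: exact sharing
        key = (int(round(2 * x / d)), int(round(2 * y / R)))
        if key not in offsets:
            offsets[key] = (
                rng.uniform(-jitter, jitter, 2) if jitter > 0 else np.zeros(2)
            )
        ox, oy = offsets[key]
        return (x + ox, y + oy)

    ang = np.deg2rad(np.arange(6) * 60 - 30)
    vx, vy = R * np.cos(ang), R * np.sin(ang)
    polygons, centroids = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            cx = c * d + (r % 2) * d / 2
            cy = r * 1.5 * R
            polygons.append(Polygon([vertex(cx + dx, cy + dy)
                                     for dx, dy in zip(vx, vy)]))
            centroids.append((cx, cy))
    centroids = np.asarray(centroids)
    nbrs = neighbors_from_rois(polygons)
    flags = flag_boundary_cells(polygons, centroids, ratio=hull_ratio)
    return TissueMap(polygons=polygons, centroids=centroids,
                     neighbors=nbrs, is_boundary=flags)


def with_shortcuts(
    tissue: TissueMap,
    fraction: float,
    seed: int | None = None,
    min_hops: int = 3,
) -> TissueMap:
    """Give a fraction of cells one extra long-range link.

    Emulates the exceptionally long cellular processes that connect distant
    cells. Each selected cell is linked to a uniformly chosen cell at least
    ``min_hops`` lattice hops away (approximated by centroid distance >
    ``min_hops`` × mean neighbour spacing). Shortcut links are stored
    separately from the structural adjacency.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 0:
        return tissue
    rng = np.random.default_rng(seed)
    n = tissue.n_cells
    n_pick = int(round(fraction * n))
    sources = rng.choice(n, size=n_pick, replace=False)
    # mean neighbour spacing
    d0 = np.mean([
        np.linalg.norm(tissue.centroids[i] - tissue.centroids[j])
        for i in range(min(n, 50)) for j in tissue.neighbors[i]
    ])
    links = set(tissue.shortcuts)
    for s in sources:
        dist = np.linalg.norm(tissue.centroids - tissue.centroids[s], axis=1)
        far = np.flatnonzero(dist > min_hops * d0)
        if far.size == 0:
            continue
        t = int(rng.choice(far))
        links.add(frozenset((int(s), t)))
    return replace(tissue, shortcuts=frozenset(links))


def assign_sensitivity(
    tissue: TissueMap,
    fraction: float,
    mode: str = "clustered",
    mean_cluster_size: int = 5,
    seed: int | None = None,
    agonist_name: str = "agonist",
    min_separation: int = 0,
) -> SensitivityMap:
    """Mark a fraction of cells as sensitive to a named agonist.

    The target count is ``round(fraction * n_cells)`` drawn among
    non-boundary cells. In ``random`` mode cells are sampled uniformly; in
    ``clustered`` mode connected clusters are grown by seeded breadth-first
    accretion on the structural lattice, with per-cluster target sizes drawn
    from a Poisson distribution around ``mean_cluster_size`` (min 1), until
    the overall target is reached. Every planted cluster is connected in
    structural adjacency by construction. By default adjacent clusters may
    touch and hence merge into larger connected patches, as sensory clusters
    in tissue can. With ``min_separation=1`` clusters are instead grown with
    a one-cell buffer so distinct clusters are never structurally adjacent
    (discrete patches, useful for planting well-separated communities); the
    buffer is relaxed only if the lattice is too crowded to place the
    remaining cells otherwise.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if mean_cluster_size < 1:
        raise ValueError("mean_cluster_size must be >= 1")
    if mode not in ("clustered", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    if min_separation not in (0, 1):
        raise ValueError("min_separation must be 0 or 1")

    rng = np.random.default_rng(seed)
    n = tissue.n_cells
    pool = tissue.interior_ids
    target = int(round(fraction * n))
    if target > pool.size:
        raise ValueError(
            f"target of {target} sensitive cells exceeds the "
            f"{pool.size} non-boundary cells available"
        )
    if target < 1:
        raise ValueError("fraction too small: zero sensitive cells")

    sensitive = np.zeros(n, dtype=bool)
    cluster_id = np.full(n, -1, dtype=int)

    if mode == "random":
        chosen = rng.choice(pool, size=target, replace=False)
        sensitive[chosen] = True
        return SensitivityMap(sensitive, cluster_id, agonist_name,
                              is_initiator=sensitive.copy())

    pool_set = set(int(i) for i in pool)
    initiator = np.zeros(n, dtype=bool)
    # cells adjacent to an already-placed cluster; excluded from new
    # clusters while unbuffered space remains
    buffered = np.zeros(n, dtype=bool)
    assigned = 0
    cid = 0
    while assigned < target:
        taken_all = sensitive | buffered
        free = np.array(sorted(i for i in pool_set if not taken_all[i]))
        if free.size == 0:
            # lattice too crowded for separated clusters: relax the buffer
            free = np.array(sorted(i for i in pool_set if not sensitive[i]))
            if free.size == 0:  # pragma: no cover - guarded by target <= pool
                break
            taken_all = sensitive.copy()
        size = max(1, int(rng.poisson(mean_cluster_size)))
        size = min(size, target - assigned)
        start = int(rng.choice(free))
        # breadth-first accretion in randomized frontier order
        members = [start]
        frontier = [start]
        taken = {start}
        while len(members) < size and frontier:
            cur = frontier.pop(0)
            nbs = [j for j in tissue.neighbors[cur]
                   if j in pool_set and not taken_all[j] and j not in taken]
            rng.shuffle(nbs)
            for j in nbs:
                if len(members) >= size:
                    break
                members.append(j)
                taken.add(j)
                frontier.append(j)
        sensitive[members] = True
        cluster_id[members] = cid
        initiator[start] = True
        if min_separation:
            for m in members:
                for j in tissue.neighbors[m]:
                    buffered[j] = True
        cid += 1
        assigned += len(members)
    return SensitivityMap(sensitive, cluster_id, agonist_name,
                          is_initiator=initiator)
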