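"""Tissue geometry, adjacency, boundary flagging, sensitivity assignment."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from endonet.tissue import (assign_sensitivity, build_hex_lattice,
                            flag_boundary_cells, neighbors_from_rois,
                            with_shortcuts)


def perimeter_ring(n_rows, n_cols):
    """Cell ids in the outermost row/column ring of the lattice."""
    ids = set()
    for r in range(n_rows):
        for c in range(n_cols):
            if r in (0, n_rows - 1) or c in (0, n_cols - 1):
                ids.add(r * n_cols + c)
    return ids


class TestHexLattice:
    def test_interior_cells_have_degree_six(self, lattice10):
        interior = lattice10.interior_ids
        assert interior.size > 0
        degs = [lattice10.degree(i) for i in interior]
        assert all(d == 6 for d in degs)

    def test_adjacency_symmetric_and_irreflexive(self, lattice10):
        lattice10.validate()  # raises on violation

    def test_boundary_flags_match_perimeter_ring(self, lattice10):
        flagged = set(np.flatnonzero(lattice10.is_boundary).tolist())
        assert flagged == perimeter_ring(10, 10)

    def test_jitter_preserves_adjacency(self, lattice10, lattice10_jittered):
        assert lattice10.neighbors == lattice10_jittered.neighbors

    def test_jitter_moves_vertices(self, lattice10, lattice10_jittered):
        a = np.asarray(lattice10.polygons[0].exterior.coords)
        b = np.asarray(lattice10_jittered.polygons[0].exterior.coords)
        assert np.abs(a - b).max() > 0

    def test_cell_count_and_ids(self, lattice10):
        assert lattice10.n_cells == 100
        assert np.array_equal(lattice10.cell_ids, np.arange(100))

    @pytest.mark.parametrize("rows,cols", [(2, 5), (5, 2)])
    def test_too_small_lattice_rejected(self, rows, cols):
        with pytest.raises(ValueError):
            build_hex_lattice(rows, cols)

    def test_excessive_jitter_rejected(self):
        with pytest.raises(ValueError):
            build_hex_lattice(5, 5, cell_diameter=30.0, jitter=10.0)
        with pytest.raises(ValueError):
            build_hex_lattice(5, 5, jitter=-1.0)


class TestNeighborsFromRois:
    def test_zero_separation_rule(self):
        a = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        b = Polygon([(1, 0), (2, 0), (2, 1), (1, 1)])     # shares an edge
        c = Polygon([(5, 0), (6, 0), (6, 1), (5, 1)])     # distant
        nbrs = neighbors_from_rois([a, b, c])
        assert nbrs[0] == frozenset({1})
        assert nbrs[1] == frozenset({0})
        assert nbrs[2] == frozenset()

    def test_invalid_polygon_rejected(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValueError, match="invalid polygon"):
            neighbors_from_rois([bowtie])

    def test_tolerance_bridges_pixel_gaps(self):
        a = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        b = Polygon([(1.5, 0), (2.5, 0), (2.5, 1), (1.5, 1)])  # 0.5 apart
        assert neighbors_from_rois([a, b])[0] == frozenset()
        assert neighbors_from_rois([a, b], contact_tol=0.6)[0] == frozenset({1})


class TestBoundaryFlagging:
    def test_tiny_input_all_boundary(self):
        sq = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        flags = flag_boundary_cells([sq], np.array([[0.5, 0.5]]))
        assert flags.all()

    def test_interior_cell_not_flagged(self, lattice10):
        # centre cell of the 10x10 lattice
        assert not lattice10.is_boundary[45]


class TestShortcuts:
    def test_links_are_long_range_and_extra(self, lattice10):
        t = with_shortcuts(lattice10, 0.1, seed=3, min_hops=3)
        assert len(t.shortcuts) > 0
        for pair in t.shortcuts:
            i, j = sorted(pair)
            assert j not in t.neighbors[i]
            d = np.linalg.norm(t.centroids[i] - t.centroids[j])
            assert d > 3 * 26.0  # > 3 lattice spacings (spacing = 30 um flats)
            assert {i, j} <= set(t.links_for_propagation(i) | {i})

    def test_zero_fraction_identity(self, lattice10):
        assert with_shortcuts(lattice10, 0.0) is lattice10

    def test_bad_fraction_rejected(self, lattice10):
        with pytest.raises(ValueError):
            with_shortcuts(lattice10, 1.5)


class TestAssignSensitivity:
    def test_random_mode_exact_count(self, lattice10):
        sens = assign_sensitivity(lattice10, 0.25, mode="random", seed=3)
        assert sens.n_sensitive == 25
        assert not lattice10.is_boundary[sens.sensitive_ids].any()
        # in random mode every sensitive cell is its own initiator
        assert np.array_equal(sens.initiators, sens.sensitive)

    def test_clustered_mode_count_and_connectivity(self, lattice10, sens10):
        assert sens10.n_sensitive == 25
        n_clusters = sens10.cluster_id.max() + 1
        for cid in range(n_clusters):
            members = set(np.flatnonzero(sens10.cluster_id == cid).tolist())
            assert members, f"empty cluster {cid}"
            # connected by BFS over structural adjacency
            seen = {next(iter(members))}
            frontier = list(seen)
            while frontier:
                cur = frontier.pop()
                for nb in lattice10.neighbors[cur]:
                    if nb in members and nb not in seen:
                        seen.add(nb)
                        frontier.append(nb)
            assert seen == members, f"cluster {cid} is disconnected"

    def test_clusters_are_separated_with_buffer(self, lattice10):
        # with min_separation=1, distinct planted clusters must not be
        # structurally adjacent
        sens = assign_sensitivity(lattice10, 0.25, mode="clustered",
                                  mean_cluster_size=5, seed=7,
                                  min_separation=1)
        for i in sens.sensitive_ids:
            for j in lattice10.neighbors[i]:
                if sens.sensitive[j]:
                    assert sens.cluster_id[i] == sens.cluster_id[j]

    def test_bad_min_separation_rejected(self, lattice10):
        with pytest.raises(ValueError, match="min_separation"):
            assign_sensitivity(lattice10, 0.25, mode="clustered", seed=0,
                               min_separation=2)

    def test_one_initiator_per_cluster(self, sens10):
        n_clusters = sens10.cluster_id.max() + 1
        init = sens10.initiators
        for cid in range(n_clusters):
            members = np.flatnonzero(sens10.cluster_id == cid)
            assert init[members].sum() == 1

    def test_mean_cluster_size_near_request(self, lattice10):
        sizes = []
        for seed in range(150):
            s = assign_sensitivity(lattice10, 0.25, mode="clustered",
                                   mean_cluster_size=5, seed=seed)
            counts = np.bincount(s.cluster_id[s.cluster_id >= 0])
            sizes.extend(counts.tolist())
        mean = np.mean(sizes)
        assert 4.0 <= mean <= 6.0  # requested mean +-20%

    def test_clustered_exceeds_random_cells_per_cluster(self, lattice10):
        from endonet.clusters import active_subgraph, cluster_stats

        def mean_cpc(mode):
            vals = []
            for seed in range(120):
                s = assign_sensitivity(lattice10, 0.25, mode=mode, seed=seed)
                g = active_subgraph(lattice10, s.sensitive_ids)
                st = cluster_stats(g, lattice10.n_cells)
                if np.isfinite(st.cells_per_cluster):
                    vals.append(st.cells_per_cluster)
            return np.mean(vals)

        assert mean_cpc("clustered") > mean_cpc("random")

    def test_invalid_arguments(self, lattice10):
        with pytest.raises(ValueError):
            assign_sensitivity(lattice10, 0.0)
        with pytest.raises(ValueError):
            assign_sensitivity(lattice10, 1.0)
        with pytest.raises(ValueError):
            assign_sensitivity(lattice10, 0.5, mean_cluster_size=0)
        with pytest.raises(ValueError):
            assign_sensitivity(lattice10, 0.5, mode="banana")
        with pytest.raises(ValueError):
            # 90% of all cells cannot fit into the non-boundary pool
            assign_sensitivity(lattice10, 0.9)
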