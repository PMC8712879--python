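"""Activation solver tests: oracles, closed forms, invariants."""

import copy

import networkx as nx
import numpy as np
import pytest

from crtpredict import anatomy as an
from crtpredict import eikonal as ek


def ray_speed(u, f, v_f, v_t):
    c2 = float(np.dot(u, f)) ** 2
    return 1.0 / np.sqrt(c2 / v_f ** 2 + (1 - c2) / v_t ** 2)


def brute_force_graph(mesh, model, order=1):
    """Independent re-derivation of the propagation graph with plain loops."""
    v_f, v_t = model.element_speeds(mesh)
    g = nx.Graph()
    edge_elems = {}
    for e in range(mesh.n_elements):
        if mesh.tissue_class[e] == an.TISSUE_SCAR:
            continue
        tet = mesh.tets[e]
        for a in range(4):
            for b in range(a + 1, 4):
                key = (min(tet[a], tet[b]), max(tet[a], tet[b]))
                edge_elems.setdefault(key, []).append(e)
    for (i, j), elems in edge_elems.items():
        d = mesh.nodes[j] - mesh.nodes[i]
        L = np.linalg.norm(d)
        u = d / L
        # slowest incident element: the edge cannot shortcut slow tissue
        speed = min(ray_speed(u, mesh.fiber[e], v_f[e], v_t[e])
                    for e in elems)
        g.add_edge(int(i), int(j), weight=L / speed)
    assert order == 1
    return g


class TestSlabTrivialCases:
    """Planar fronts along/across fibers: distance over speed.

    The graph stage is exact on the axis-aligned lattice; the refined
    solver agrees with the continuum to well under a percent.
    """

    def test_along_fiber_distance_over_speed(self, slab_2mm):
        model = ek.ConductionModel(g=1.0, v0=1.0, anisotropy_ratio=4.0)
        x = slab_2mm.nodes[:, 0]
        src = [(int(i), 0.0) for i in np.flatnonzero(x == 0)]
        graph = ek.solve_activation(slab_2mm, model, src, refine=False)
        probe = np.flatnonzero(x == 30)
        np.testing.assert_allclose(graph.at[probe], 30.0, atol=1e-9)
        am = ek.solve_activation(slab_2mm, model, src)
        np.testing.assert_allclose(am.at[probe], 30.0, rtol=0.01)

    def test_across_fiber_half_speed(self, slab_2mm):
        model = ek.ConductionModel(g=1.0, v0=1.0, anisotropy_ratio=4.0)
        y = slab_2mm.nodes[:, 1]
        src = [(int(i), 0.0) for i in np.flatnonzero(y == 0)]
        graph = ek.solve_activation(slab_2mm, model, src, refine=False)
        probe = np.flatnonzero(y == 30)
        np.testing.assert_allclose(graph.at[probe], 60.0, atol=1e-9)
        am = ek.solve_activation(slab_2mm, model, src)
        np.testing.assert_allclose(am.at[probe], 60.0, rtol=0.01)


class TestDijkstraOracle:
    def test_graph_stage_equals_networkx_dijkstra(self, random_mesh_200):
        mesh = random_mesh_200
        model = ek.ConductionModel(g=1.3, v0=0.8, anisotropy_ratio=4.0)
        src = 0
        am = ek.solve_activation(mesh, model, [(src, 0.0)],
                                 order=1, refine=False)
        g = brute_force_graph(mesh, model)
        dist = nx.single_source_dijkstra_path_length(g, src)
        for node in range(mesh.n_nodes):
            expected = dist.get(node, np.inf)
            assert abs(am.at[node] - expected) < 1e-9 or \
                (np.isinf(am.at[node]) and np.isinf(expected))

    def test_oracle_agreement_with_scar_excluded(self, random_mesh_200):
        mesh = copy.copy(random_mesh_200)
        rng = np.random.default_rng(0)
        tissue = np.zeros(mesh.n_elements, dtype=np.int32)
        tissue[rng.random(mesh.n_elements) < 0.15] = an.TISSUE_SCAR
        tissue[rng.random(mesh.n_elements) < 0.10] = an.TISSUE_FIBROSIS
        mesh.tissue_class = tissue
        model = ek.ConductionModel()
        src = int(np.flatnonzero(~mesh.node_is_scar())[0])
        am = ek.solve_activation(mesh, model, [(src, 0.0)],
                                 order=1, refine=False)
        g = brute_force_graph(mesh, model)
        dist = nx.single_source_dijkstra_path_length(g, src)
        for node in range(mesh.n_nodes):
            expected = dist.get(node, np.inf)
            if np.isinf(expected):
                assert np.isinf(am.at[node])
            else:
                assert abs(am.at[node] - expected) < 1e-9

    def test_onset_offsets_respected(self, random_mesh_200):
        model = ek.ConductionModel()
        srcs = [(0, 5.0), (50, 1.0), (120, 9.0)]
        am = ek.solve_activation(random_mesh_200, model, srcs,
                                 order=1, refine=False)
        g = brute_force_graph(random_mesh_200, model)
        for node in (3, 40, 77, 150):
            expected = min(t0 + nx.dijkstra_path_length(g, s, node)
                           for s, t0 in srcs)
            assert abs(am.at[node] - expected) < 1e-9


class TestClosedForm:
    def test_elliptical_norm_within_3pct_at_2mm(self, slab_2mm):
        model = ek.ConductionModel(g=1.0, v0=1.0, anisotropy_ratio=4.0)
        center = np.array([20.0, 20.0, 10.0])
        ci = int(np.argmin(np.linalg.norm(slab_2mm.nodes - center, axis=1)))
        am = ek.solve_activation(slab_2mm, model, [(ci, 0.0)])
        d = slab_2mm.nodes - slab_2mm.nodes[ci]
        exact = np.sqrt(d[:, 0] ** 2 + 4 * (d[:, 1] ** 2 + d[:, 2] ** 2))
        sel = exact > 4 * slab_2mm.edge_length
        rel = np.abs(am.at[sel] - exact[sel]) / exact[sel]
        assert rel.max() < 0.03


class TestInvariants:
    def test_time_scaling_exact(self, slab_2mm):
        c = 2.0
        ci = 100
        m1 = ek.ConductionModel(g=1.0, v0=1.0, anisotropy_ratio=4.0)
        m4 = ek.ConductionModel(g=c ** 2, v0=1.0, anisotropy_ratio=4.0)
        a1 = ek.solve_activation(slab_2mm, m1, [(ci, 0.0)])
        a4 = ek.solve_activation(slab_2mm, m4, [(ci, 0.0)])
        assert np.max(np.abs(a4.at * c - a1.at)) < 1e-9

    def test_raising_speed_never_delays(self, random_mesh_200):
        """Graph-stage monotonicity: turning fibrosis back to normal tissue
        can only make nodes activate earlier."""
        mesh = copy.copy(random_mesh_200)
        rng = np.random.default_rng(1)
        tissue = np.zeros(mesh.n_elements, dtype=np.int32)
        tissue[rng.random(mesh.n_elements) < 0.3] = an.TISSUE_FIBROSIS
        mesh.tissue_class = tissue
        model = ek.ConductionModel()
        slow = ek.solve_activation(mesh, model, [(0, 0.0)],
                                   order=1, refine=False)
        mesh2 = copy.copy(mesh)
        tissue2 = tissue.copy()
        tissue2[np.flatnonzero(tissue == an.TISSUE_FIBROSIS)[:20]] = 0
        mesh2.tissue_class = tissue2
        fast = ek.solve_activation(mesh2, model, [(0, 0.0)],
                                   order=1, refine=False)
        assert np.all(fast.at <= slow.at + 1e-12)

    def test_source_nodes_keep_their_onsets(self, slab_2mm):
        model = ek.ConductionModel(v0=1.0)
        srcs = [(10, 0.0), (500, 3.0)]
        am = ek.solve_activation(slab_2mm, model, srcs)
        assert am.at[10] == pytest.approx(0.0, abs=1e-9)
        assert am.at[500] <= 3.0 + 1e-12
        assert am.at.min() >= -1e-12

    def test_all_scar_sources_rejected(self, random_mesh_200):
        mesh = copy.copy(random_mesh_200)
        tissue = np.full(mesh.n_elements, an.TISSUE_SCAR, dtype=np.int32)
        mesh.tissue_class = tissue
        with pytest.raises(ValueError):
            ek.solve_activation(mesh, ek.ConductionModel(), [(0, 0.0)])

    def test_order2_graph_no_slower_than_order1(self, random_mesh_200):
        model = ek.ConductionModel()
        a1 = ek.solve_activation(random_mesh_200, model, [(0, 0.0)],
                                 order=1, refine=False)
        a2 = ek.solve_activation(random_mesh_200, model, [(0, 0.0)],
                                 order=2, refine=False)
        assert np.all(a2.at <= a1.at + 1e-12)


class TestGeodesic:
    def test_distance_to_self_zero(self, slab_2mm):
        assert ek.geodesic_distance(slab_2mm, 0, [0]) == 0.0

    def test_straight_path_unit_speed(self, slab_2mm):
        x = slab_2mm.nodes[:, 0]
        i0 = int(np.flatnonzero((x == 0) & (slab_2mm.nodes[:, 1] == 20)
                                & (slab_2mm.nodes[:, 2] == 10))[0])
        i1 = int(np.flatnonzero((x == 36) & (slab_2mm.nodes[:, 1] == 20)
                                & (slab_2mm.nodes[:, 2] == 10))[0])
        d = ek.geodesic_distance(slab_2mm, i0, [i1])
        assert d == pytest.approx(36.0, abs=1e-9)

    def test_matches_edge_graph_dijkstra(self, random_mesh_200):
        mesh = random_mesh_200
        iso = ek.ConductionModel(g=1.0, v0=1.0, anisotropy_ratio=1.0)
        g = brute_force_graph(mesh, iso)
        d_oracle = nx.single_source_dijkstra_path_length(g, 5)
        targets = [20, 60, 150]
        d = ek.geodesic_distance(mesh, 5, targets)
        assert d == pytest.approx(min(d_oracle[t] for t in targets), abs=1e-9)

    def test_scar_included_by_default(self, lesioned_mesh):
        """Ruler distances ignore whether tissue is excitable."""
        mesh = lesioned_mesh
        clean = copy.copy(mesh)
        clean.tissue_class = np.zeros(mesh.n_elements, dtype=np.int32)
        f_scar = ek.geodesic_field(mesh, 0)
        f_clean = ek.geodesic_field(clean, 0)
        np.testing.assert_allclose(f_scar, f_clean)

    def test_empty_region_rejected(self, slab_2mm):
        with pytest.raises(ValueError):
            ek.geodesic_distance(slab_2mm, 0, [])


class TestLateActivationZone:
    def _ramp_map(self, mesh):
        at = mesh.nodes[:, 0].copy()
        at = 100 * (at - at.min()) / (at.max() - at.min())
        return ek.ActivationMap(at=at, sources=[(0, 0.0)])

    def test_linear_ramp_threshold(self, ventricle_mesh):
        amap = self._ramp_map(ventricle_mesh)
        zone = ek.late_activation_zone(amap, ventricle_mesh, fraction=0.9)
        lv = ventricle_mesh.wall_label_node != an.WALL_RV_FREE
        expected = np.flatnonzero(lv & (amap.at >= 90.0))
        np.testing.assert_array_equal(zone, expected)

    def test_uniform_map_returns_all_lv(self, ventricle_mesh):
        amap = ek.ActivationMap(at=np.full(ventricle_mesh.n_nodes, 7.0),
                                sources=[(0, 7.0)])
        zone = ek.late_activation_zone(amap, ventricle_mesh)
        lv = np.flatnonzero(ventricle_mesh.wall_label_node != an.WALL_RV_FREE)
        np.testing.assert_array_equal(zone, lv)

    def test_zone_shrinks_with_fraction(self, ventricle_mesh):
        amap = self._ramp_map(ventricle_mesh)
        sizes = []
        for frac in (0.8, 0.85, 0.9, 0.95):
            zone = ek.late_activation_zone(amap, ventricle_mesh, fraction=frac)
            # brute-force recount
            lv = ventricle_mesh.wall_label_node != an.WALL_RV_FREE
            thr = amap.at_min + frac * (amap.at_max - amap.at_min)
            assert len(zone) == int(np.sum(lv & (amap.at >= thr)))
            sizes.append(len(zone))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
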