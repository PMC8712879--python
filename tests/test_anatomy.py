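"""Geometry, labeling and fiber-rule tests for the synthetic anatomy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crtpredict import anatomy as an


class TestBuildVentricles:
    def test_all_51_lv_region_codes_present(self, ventricle_mesh):
        lv = ventricle_mesh.wall_label != an.WALL_RV_FREE
        codes = set(zip(ventricle_mesh.aha_segment[lv].tolist(),
                        ventricle_mesh.layer_label[lv].tolist()))
        assert len(codes) == 17 * 3

    def test_volume_matches_analytic_shell(self, ventricle_mesh):
        analytic = an.analytic_shell_volume(ventricle_mesh.shape)
        meshed = ventricle_mesh.element_volume.sum()
        assert abs(meshed - analytic) / analytic < 0.05

    def test_element_volumes_positive(self, ventricle_mesh):
        assert np.all(ventricle_mesh.element_volume > 0)

    def test_coarser_mesh_fewer_nodes_same_taxonomy(self, ventricle_mesh):
        coarse = an.build_ventricles(edge_length=8.0)
        assert coarse.n_nodes < ventricle_mesh.n_nodes
        assert set(np.unique(coarse.wall_label)) <= {0, 1, 2}
        assert set(np.unique(coarse.layer_label)) <= {0, 1, 2}
        lv = coarse.wall_label != an.WALL_RV_FREE
        assert set(np.unique(coarse.aha_segment[lv])) <= set(range(1, 18))

    def test_label_partition_complete(self, ventricle_mesh):
        m = ventricle_mesh
        assert np.all((m.wall_label >= 0) & (m.wall_label <= 2))
        assert np.all((m.layer_label >= 0) & (m.layer_label <= 2))
        assert np.all((m.tissue_class >= 0) & (m.tissue_class <= 2))
        lv = m.wall_label != an.WALL_RV_FREE
        assert np.all((m.aha_segment[lv] >= 1) & (m.aha_segment[lv] <= 17))
        assert np.all(m.aha_segment[~lv] == 0)

    def test_reproducible_for_fixed_inputs(self):
        a = an.build_ventricles(edge_length=7.0, seed=3)
        b = an.build_ventricles(edge_length=7.0, seed=3)
        np.testing.assert_array_equal(a.nodes, b.nodes)
        np.testing.assert_array_equal(a.tets, b.tets)
        np.testing.assert_array_equal(a.aha_segment, b.aha_segment)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            an.ShapeParams(lv_wall=-1.0)
        with pytest.raises(ValueError):
            an.build_ventricles(edge_length=0.0)

    def test_endocardial_surfaces_disjoint_and_on_boundary(self, ventricle_mesh):
        m = ventricle_mesh
        assert len(set(m.endo_surface_LV) & set(m.endo_surface_RV)) == 0
        assert len(m.endo_surface_LV) > 100
        assert len(m.endo_surface_RV) > 100


class TestAHASectors:
    @given(theta=st.floats(-180, 180, allow_nan=False),
           level=st.integers(0, 3))
    @settings(max_examples=200, deadline=None)
    def test_segment_in_level_range(self, theta, level):
        seg = int(an.aha_sector(np.array([theta]), np.array([level]))[0])
        expected = {0: range(1, 7), 1: range(7, 13),
                    2: range(13, 17), 3: range(17, 18)}[level]
        assert seg in expected

    def test_sector_widths_60_and_90_degrees(self):
        thetas = np.arange(-180.0, 180.0, 0.5)
        basal = an.aha_sector(thetas, np.zeros(len(thetas), dtype=int))
        apical = an.aha_sector(thetas, np.full(len(thetas), 2))
        w = 0.5
        for seg in range(1, 7):
            assert np.sum(basal == seg) * w == pytest.approx(60.0)
        for seg in range(13, 17):
            assert np.sum(apical == seg) * w == pytest.approx(90.0)

    def test_septal_segments_face_rv(self, ventricle_mesh):
        m = ventricle_mesh
        sept = m.wall_label == an.WALL_SEPTUM
        cent = m.element_centroids()
        assert cent[sept, 0].mean() > 0  # RV shifted toward +x


class TestFibers:
    def test_unit_norm(self, ventricle_mesh):
        norms = np.linalg.norm(ventricle_mesh.fiber, axis=1)
        assert np.all(np.abs(norms - 1) < 1e-9)

    def test_tangent_to_wall(self, ventricle_mesh):
        n = an.transmural_normals(ventricle_mesh)
        dot = np.abs(np.einsum("ij,ij->i", ventricle_mesh.fiber, n))
        assert dot.mean() < 0.1

    def test_helix_angle_interpolates_linearly(self, ventricle_mesh):
        """+60 deg at endo, 0 at mid-depth, -60 deg at epi: the fiber's
        longitudinal component tracks sin of the interpolated angle."""
        mesh = ventricle_mesh
        n = an.transmural_normals(mesh)
        zhat = np.array([0.0, 0.0, 1.0])
        t = zhat - n * n[:, 2:3]
        tn = np.linalg.norm(t, axis=1)
        ok = (tn > 1e-6) & ~mesh.fiber_flagged
        e_long = t[ok] / tn[ok, None]
        sin_alpha = np.einsum("ij,ij->i", mesh.fiber[ok], e_long)
        expected = np.sin(np.radians(60 - 120 * mesh.depth[ok]))
        np.testing.assert_allclose(sin_alpha, expected, atol=1e-9)
        mid = ok & (np.abs(mesh.depth - 0.5) < 0.02)
        assert np.abs(sin_alpha[np.abs(mesh.depth[ok] - 0.5) < 0.02]).max() < 0.05

    def test_custom_angles(self, ventricle_mesh):
        import copy
        mesh = copy.copy(ventricle_mesh)
        mesh.fiber = ventricle_mesh.fiber.copy()
        an.assign_fibers(mesh, alpha_endo=0.0, alpha_epi=0.0)
        n = an.transmural_normals(mesh)
        # all-circumferential: no longitudinal component anywhere
        zhat = np.array([0.0, 0.0, 1.0])
        t = zhat - n * n[:, 2:3]
        tn = np.linalg.norm(t, axis=1)
        ok = tn > 1e-6
        e_long = t[ok] / tn[ok, None]
        assert np.abs(np.einsum("ij,ij->i", mesh.fiber[ok], e_long)).max() < 1e-9
        an.assign_fibers(mesh)  # restore defaults for other tests


class TestLesions:
    def test_example_septal_fibrosis_map(self):
        mesh = an.build_ventricles(edge_length=6.0)
        spec = an.LesionSpec({(s, 1): "fibrosis" for s in (2, 3, 8, 9)})
        an.apply_lesions(mesh, spec)
        target = (np.isin(mesh.aha_segment, [2, 3, 8, 9])
                  & (mesh.layer_label == 1)
                  & (mesh.wall_label != an.WALL_RV_FREE))
        assert np.all(mesh.tissue_class[target] == an.TISSUE_FIBROSIS)
        assert np.all(mesh.tissue_class[~target] == an.TISSUE_NORMAL)

    def test_empty_spec_all_normal(self):
        mesh = an.build_ventricles(edge_length=8.0)
        an.apply_lesions(mesh, an.LesionSpec({}))
        assert np.all(mesh.tissue_class == an.TISSUE_NORMAL)

    def test_fibrosis_volume_brute_force(self, lesioned_mesh):
        mesh = lesioned_mesh
        fast = mesh.element_volume[mesh.tissue_class == an.TISSUE_FIBROSIS].sum()
        brute = sum(float(mesh.element_volume[e])
                    for e in range(mesh.n_elements)
                    if mesh.tissue_class[e] == an.TISSUE_FIBROSIS)
        assert fast == pytest.approx(brute, rel=1e-12)
        assert fast > 0

    def test_out_of_range_segment_rejected(self):
        with pytest.raises(ValueError):
            an.LesionSpec({(18, 0): "scar"})
        with pytest.raises(ValueError):
            an.LesionSpec({(3, "outer"): "scar"})

    def test_connected_after_scar_removal(self, lesioned_mesh):
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components
        mesh = lesioned_mesh
        keep = mesh.tissue_class != an.TISSUE_SCAR
        tets = mesh.tets[keep]
        n = mesh.n_nodes
        rows, cols = [], []
        for a, b in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)):
            rows.append(tets[:, a])
            cols.append(tets[:, b])
        g = csr_matrix((np.ones(6 * len(tets)),
                        (np.concatenate(rows), np.concatenate(cols))),
                       shape=(n, n))
        used = np.unique(tets)
        ncomp, labels = connected_components(g[used][:, used], directed=False)
        assert ncomp == 1


class TestPacingSites:
    def test_rv_apex_minimizes_long_axis(self, ventricle_mesh):
        pc = an.place_pacing_sites(ventricle_mesh)
        rv_endo = ventricle_mesh.endo_surface_RV
        assert (ventricle_mesh.nodes[pc.rv_site, 2]
                == ventricle_mesh.nodes[rv_endo, 2].min())

    def test_lv_site_in_lateral_segments(self, ventricle_mesh):
        for rule in ("posterolateral", "lateral", "anterolateral"):
            pc = an.place_pacing_sites(ventricle_mesh, lv_rule=rule)
            elems = np.flatnonzero(
                np.any(ventricle_mesh.tets == pc.lv_site, axis=1))
            segs = set(ventricle_mesh.aha_segment[elems].tolist())
            assert segs & {5, 6, 11, 12}, (rule, segs)

    def test_deterministic(self, ventricle_mesh):
        a = an.place_pacing_sites(ventricle_mesh, seed=5)
        b = an.place_pacing_sites(ventricle_mesh, seed=5)
        assert (a.rv_site, a.lv_site, a.rv_lv_delay) == \
               (b.rv_site, b.lv_site, b.rv_lv_delay)

    def test_biv_requires_both_sites(self):
        with pytest.raises(ValueError):
            an.PacingConfig(mode="biv", rv_site=3)
        an.PacingConfig(mode="lbbb")  # no sites needed


class TestTorso:
    def test_electrodes_outside_ventricles(self, ventricle_mesh, torso):
        coords = torso.coords()
        lo = ventricle_mesh.nodes.min(axis=0)
        hi = ventricle_mesh.nodes.max(axis=0)
        inside = np.all((coords > lo) & (coords < hi), axis=1)
        assert not inside.any()

    def test_missing_electrode_rejected(self):
        with pytest.raises(ValueError):
            an.TorsoModel(electrodes={"RA": (0, 0, 0)})

    def test_duplicate_positions_rejected(self, torso):
        bad = dict(torso.electrodes)
        bad["V2"] = bad["V1"]
        with pytest.raises(ValueError):
            an.TorsoModel(electrodes=bad)
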