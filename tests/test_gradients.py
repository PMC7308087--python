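"""Finite-element surface gradients, directional statistics, Rayleigh test,
and marching-triangles isocontours."""

import numpy as np
import pytest
from scipy import stats

from rtopmap.gradients import (
    GradientField,
    contour_length,
    directional_stats,
    isocontours,
    main_direction,
    mesh_gradient,
    rayleigh_test,
)
from rtopmap.synthetic import SurfaceMesh, make_surface_phantom

from conftest import sample_vmf


@pytest.fixture(scope="module")
def sheet():
    return make_surface_phantom(seed=0).meshes["L"]


class TestMeshGradient:
    def test_linear_field_exact(self, sheet):
        """grad(x) = (1,0,0) at every interior vertex of a planar sheet."""
        field = mesh_gradient(sheet, sheet.vertices[:, 0])
        g = field.vectors[field.valid]
        np.testing.assert_allclose(g, [[1.0, 0.0, 0.0]] * len(g), atol=1e-9)

    def test_constant_field_zero_gradient(self, sheet):
        field = mesh_gradient(sheet, np.full(sheet.vertices.shape[0], 2.5))
        np.testing.assert_allclose(field.vectors, 0.0, atol=1e-12)

    def test_linearity(self, sheet):
        rng = np.random.default_rng(0)
        f = rng.standard_normal(sheet.vertices.shape[0])
        g = rng.standard_normal(sheet.vertices.shape[0])
        lhs = mesh_gradient(sheet, 2.0 * f - 3.0 * g).vectors
        rhs = 2.0 * mesh_gradient(sheet, f).vectors \
            - 3.0 * mesh_gradient(sheet, g).vectors
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_tangency_to_vertex_normal(self, sheet):
        rng = np.random.default_rng(1)
        field = mesh_gradient(sheet, rng.standard_normal(
            sheet.vertices.shape[0]))
        # planar sheet: normal is +-z, so gradients have no z component
        np.testing.assert_allclose(field.vectors[:, 2], 0.0, atol=1e-9)

    def test_curved_sheet_matches_refined_estimate(self):
        """Gradient of a smooth field on a curved sheet is consistent with
        the same computation on a 2x refined mesh (interpolation oracle)."""
        def build(n):
            xs = np.linspace(0, 4, n)
            ys = np.linspace(0, 2, n // 2)
            X, Y = np.meshgrid(xs, ys, indexing="ij")
            Z = 0.3 * np.sin(X) * np.cos(Y)
            verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
            tris = []
            ny = n // 2
            for i in range(n - 1):
                for j in range(ny - 1):
                    a = i * ny + j
                    tris.append([a, a + ny, a + 1])
                    tris.append([a + ny, a + ny + 1, a + 1])
            return SurfaceMesh(verts, np.asarray(tris))

        f = lambda v: np.sin(v[:, 0]) + 0.5 * v[:, 1] ** 2
        coarse = build(40)
        fine = build(80)
        gc = mesh_gradient(coarse, f(coarse.vertices))
        gf = mesh_gradient(fine, f(fine.vertices))
        # compare at shared coordinates (coarse vertices with even indices)
        from scipy.spatial import cKDTree
        tree = cKDTree(fine.vertices)
        _, idx = tree.query(coarse.vertices)
        sel = gc.valid & gf.valid[idx]
        a = gc.vectors[sel]
        b = gf.vectors[idx][sel]
        rel = np.linalg.norm(a - b, axis=1) / np.linalg.norm(b, axis=1)
        assert np.median(rel) < 0.02

    def test_degenerate_triangles(self, sheet):
        tris = np.vstack([sheet.triangles, [[0, 0, 1]]])  # zero-area triangle
        bad = SurfaceMesh(sheet.vertices, tris)
        with pytest.warns(UserWarning, match="zero-area"):
            mesh_gradient(bad, sheet.vertices[:, 0])
        all_bad = SurfaceMesh(sheet.vertices,
                              np.array([[0, 0, 1], [2, 2, 3]]))
        with pytest.raises(ValueError, match="degenerate"):
            mesh_gradient(all_bad, sheet.vertices[:, 0])


class TestMainDirection:
    def test_parallel_gradients_recovered_exactly(self):
        v = np.array([0.6, 0.8, 0.0])
        field = GradientField(np.tile(v, (50, 1)), np.ones(50, dtype=bool))
        np.testing.assert_allclose(main_direction(field, np.ones(50, bool)),
                                   v, atol=1e-12)

    def test_opposite_clusters_degenerate(self):
        vecs = np.vstack([np.tile([1.0, 0, 0], (25, 1)),
                          np.tile([-1.0, 0, 0], (25, 1))])
        field = GradientField(vecs, np.ones(50, dtype=bool))
        with pytest.raises(ValueError, match="degenerate"):
            main_direction(field, np.ones(50, bool))

    def test_small_region_rejected(self):
        field = GradientField(np.tile([1.0, 0, 0], (5, 1)),
                              np.ones(5, dtype=bool))
        with pytest.raises(ValueError):
            main_direction(field, np.ones(5, bool))

    def test_phantom_recovery_within_5_degrees(self):
        """Planted +y gradient -> per-subdivision main direction within 5
        degrees.  Vertex noise is ~1% of the field's dynamic range, the
        smooth-map regime of a single subject's fitted RTOP surface;
        subject-level variability is exercised by the group-level test."""
        ph = make_surface_phantom(gradient_direction=(0.0, 1.0, 0.0),
                                  noise_sd=0.01, seed=3)
        for h in ("L", "R"):
            field = mesh_gradient(ph.meshes[h], ph.planted_field[h])
            for name in ("vAI", "dAI", "PI"):
                d = main_direction(field, ph.labels[h] == name)
                ang = np.degrees(np.arccos(np.clip(d @ [0, 1, 0], -1, 1)))
                assert ang < 5.0


class TestDirectionalStats:
    def test_identical_directions(self):
        d = np.tile([0.0, 0.0, 1.0], (30, 1))
        st = directional_stats(d, n_bootstrap=100, seed=0)
        assert st.dispersion == 0.0
        assert st.ci_halfwidth == 0.0
        np.testing.assert_allclose(st.mean_direction, [0, 0, 1])

    def test_zero_vector_rejected(self):
        d = np.vstack([np.eye(3), [[0.0, 0.0, 0.0]]])
        with pytest.raises(ValueError, match="zero"):
            directional_stats(d)

    def test_sem_scales_as_sqrt_n(self):
        """SEM halves (within 15%) when N quadruples at fixed concentration."""
        rng = np.random.default_rng(5)
        mu = np.array([1.0, 0, 0])
        sems = []
        for n in (200, 800):
            vals = [directional_stats(sample_vmf(rng, mu, 50.0, n),
                                      n_bootstrap=50, seed=1).sem
                    for _ in range(20)]
            sems.append(np.mean(vals))
        assert sems[0] / sems[1] == pytest.approx(2.0, rel=0.15)

    def test_bootstrap_ci_coverage(self):
        """The 95% bootstrap CI covers the true mean direction in >= 93% of
        von Mises-Fisher replicates (kappa=50, N=413)."""
        rng = np.random.default_rng(6)
        mu = np.array([0.0, 0.6, 0.8])
        hits = 0
        n_rep = 600
        for rep in range(n_rep):
            d = sample_vmf(rng, mu, 50.0, 413)
            st = directional_stats(d, n_bootstrap=400, seed=rep)
            ang = np.arccos(np.clip(st.mean_direction @ mu, -1, 1))
            hits += ang <= st.ci_halfwidth
        assert hits / n_rep >= 0.93


class TestRayleigh:
    def test_identical_directions_maximal_statistic(self):
        d = np.tile([1.0, 0, 0], (413, 1))
        S, df, p = rayleigh_test(d)
        assert S == pytest.approx(3 * 413)
        assert df == 3
        assert p < 1e-10

    def test_statistic_bounded_by_3n(self):
        rng = np.random.default_rng(7)
        for n in (10, 50, 413):
            d = sample_vmf(rng, [0, 0, 1.0], 5.0, n)
            S, _, _ = rayleigh_test(d)
            assert 0 <= S <= 3 * n + 1e-9

    def test_type_i_error_calibrated(self):
        """Rejection rate at alpha=0.05 on uniform spheres lies in
        [0.03, 0.07] over 1000 replicates of N=413."""
        rng = np.random.default_rng(8)
        d = rng.standard_normal((1000, 413, 3))
        d /= np.linalg.norm(d, axis=2, keepdims=True)
        rbar2 = (d.mean(axis=1) ** 2).sum(axis=1)
        S = 3 * 413 * rbar2
        rate = np.mean(stats.chi2.sf(S, 3) < 0.05)
        assert 0.03 <= rate <= 0.07

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(9)
        d = rng.standard_normal((1000, 100, 3))
        d /= np.linalg.norm(d, axis=2, keepdims=True)
        S = 3 * 100 * (d.mean(axis=1) ** 2).sum(axis=1)
        p = stats.chi2.sf(S, 3)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestEndToEnd:
    def test_planted_group_gradient_recovered(self):
        """50 synthetic subjects with a planted anterior-posterior +
        ventral-dorsal gradient: group mean direction within 5 degrees,
        Rayleigh p < 1e-6."""
        planted = np.array([0.8, 0.6, 0.0])
        dirs = []
        for s in range(50):
            ph = make_surface_phantom(gradient_direction=planted,
                                      noise_sd=0.05, seed=100 + s)
            field = mesh_gradient(ph.meshes["L"], ph.planted_field["L"])
            dirs.append(main_direction(field,
                                       ph.labels["L"] != "background"))
        st = directional_stats(np.asarray(dirs), n_bootstrap=200, seed=3)
        ang = np.degrees(np.arccos(np.clip(st.mean_direction @ planted,
                                           -1, 1)))
        assert ang < 5.0
        assert st.rayleigh_p < 1e-6


class TestIsocontours:
    def test_straight_contour_on_linear_field(self, sheet):
        f = sheet.vertices[:, 0]
        lv = float(np.median(f))
        segs = isocontours(sheet, f, [lv])[lv]
        assert len(segs) > 0
        pts = np.vstack(segs)
        np.testing.assert_allclose(pts[:, 0], lv, atol=1e-9)

    def test_level_outside_range_warns_empty(self, sheet):
        f = sheet.vertices[:, 0]
        with pytest.warns(UserWarning, match="outside"):
            out = isocontours(sheet, f, [f.max() + 10])
        assert out[f.max() + 10] == []

    def test_segments_within_triangles(self, sheet):
        """Each crossed triangle contributes exactly one segment whose
        endpoints lie on triangle edges."""
        rng = np.random.default_rng(10)
        f = sheet.vertices[:, 0] + 0.2 * rng.standard_normal(
            sheet.vertices.shape[0])
        lv = float(np.median(f))
        segs = isocontours(sheet, f, [lv])[lv]
        crossed = sum(
            1 for tri in sheet.triangles
            if (f[tri].min() < lv) and (f[tri].max() > lv)
        )
        assert len(segs) == crossed

    def test_length_stable_under_refinement(self):
        """Contour length of a smooth field changes < 2% under one mesh
        refinement step."""
        def build(nx, ny):
            xs = np.linspace(0, 4, nx)
            ys = np.linspace(0, 2, ny)
            X, Y = np.meshgrid(xs, ys, indexing="ij")
            verts = np.column_stack([X.ravel(), Y.ravel(),
                                     np.zeros(X.size)])
            tris = []
            for i in range(nx - 1):
                for j in range(ny - 1):
                    a = i * ny + j
                    tris.append([a, a + ny, a + 1])
                    tris.append([a + ny, a + ny + 1, a + 1])
            return SurfaceMesh(verts, np.asarray(tris))

        f = lambda v: np.sin(v[:, 0]) + 0.3 * v[:, 1]
        m1, m2 = build(40, 20), build(80, 40)
        l1 = contour_length(isocontours(m1, f(m1.vertices), [0.8])[0.8])
        l2 = contour_length(isocontours(m2, f(m2.vertices), [0.8])[0.8])
        assert abs(l1 - l2) / l2 < 0.02
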