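"""Synthetic-input generators: geometry, connectomes, distributions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from tacsnet import fixtures as fx
from tacsnet.efield import count_modes, group_by_region, project_normal, summarize


class TestGyrifiedMesh:
    def test_flat_sheet_has_constant_normal(self):
        mesh = fx.make_gyrified_mesh(n_gyri=0, fold_depth=0.0, resolution=16)
        assert np.allclose(mesh.normals, mesh.normals[0], atol=1e-9)
        assert mesh.normals[0] @ [0, 0, 1] < 0  # oriented toward the white side

    def test_normals_unit_length_and_labels_cover_triangles(self):
        mesh = fx.make_gyrified_mesh(4, 5.0, resolution=32, region_splits=6)
        assert np.allclose(np.linalg.norm(mesh.normals, axis=1), 1.0, atol=1e-9)
        assert len(mesh.region_labels) == mesh.n_triangles
        assert set(np.unique(mesh.region_labels)) == set(range(6))

    @staticmethod
    def _mean_angle_deg(n_gyri, depth, resolution, size=60.0):
        mesh = fx.make_gyrified_mesh(n_gyri, depth, sheet_size=size,
                                     resolution=resolution)
        cx = mesh.centroids()[:, 0]
        exact = fx.analytic_sheet_normal(cx, n_gyri, depth, size)
        cosang = np.clip(np.einsum("ij,ij->i", mesh.normals, exact), -1, 1)
        return np.degrees(np.arccos(cosang)).mean()

    def test_normals_match_analytic_surface_normal(self):
        """Mesh normals agree with the analytic sinusoid normal to <1 deg on
        average at resolution 64 (moderate folding, walls up to ~40 deg)."""
        assert self._mean_angle_deg(4, 2.0, 64) < 1.0

    def test_normal_error_converges_with_resolution(self):
        """Steep folds need proportionally finer grids: the angular error of
        the second-order slope estimate shrinks ~4x per resolution doubling."""
        coarse = self._mean_angle_deg(4, 4.0, 64)
        fine = self._mean_angle_deg(4, 4.0, 128)
        assert fine < coarse / 2.5

    def test_orientation_consistent_across_sheet(self):
        """Adjacent triangles sharing an edge have positively correlated
        normals on the smooth fixture (no sign flips)."""
        mesh = fx.make_gyrified_mesh(3, 4.0, resolution=32)
        edges = {}
        for t_idx, tri in enumerate(mesh.triangles):
            for a, b in ((0, 1), (1, 2), (2, 0)):
                key = tuple(sorted((tri[a], tri[b])))
                edges.setdefault(key, []).append(t_idx)
        for tris in edges.values():
            if len(tris) == 2:
                assert mesh.normals[tris[0]] @ mesh.normals[tris[1]] > 0

    def test_steep_folds_make_inplane_projection_bimodal(self):
        """Walls steeper than 45 deg split an in-plane field's normal
        component into two opposite-sign modes."""
        size = 60.0
        # slope = depth * 2 pi n / size > 1 -> depth > size / (2 pi n)
        depth = 1.8 * size / (2 * np.pi * 4)
        mesh = fx.make_gyrified_mesh(4, depth, sheet_size=size, resolution=64)
        comps = project_normal(fx.make_uniform_field(mesh, (1, 0, 0), 0.2), mesh)
        assert count_modes(comps) == 2
        assert comps.min() < 0 < comps.max()

    def test_deeper_folds_flatten_mean_and_widen_spread(self):
        """Increasing fold depth monotonically shrinks |mean| and widens the
        spread of the normal components under a fixed oblique field."""
        means, sds = [], []
        for depth in (0.5, 2.0, 4.0, 7.0):
            mesh = fx.make_gyrified_mesh(4, depth, resolution=48)
            comps = project_normal(
                fx.make_uniform_field(mesh, (1, 0, -0.3), 0.2), mesh
            )
            means.append(abs(comps.mean()))
            sds.append(comps.std())
        assert all(a > b for a, b in zip(means, means[1:]))
        assert all(a < b for a, b in zip(sds, sds[1:]))

    @pytest.mark.parametrize("kwargs", [
        dict(n_gyri=4, fold_depth=1, sheet_size=0),
        dict(n_gyri=4, fold_depth=1, resolution=3),
        dict(n_gyri=-1, fold_depth=1),
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            fx.make_gyrified_mesh(**{"resolution": 16, **kwargs})

    def test_off_round_trip(self, tmp_path):
        mesh = fx.make_gyrified_mesh(2, 3.0, resolution=16, region_splits=3)
        path = str(tmp_path / "mesh.off")
        fx.save_mesh(mesh, path)
        back = fx.load_mesh(path)
        assert np.allclose(back.vertices, mesh.vertices)
        assert np.array_equal(back.triangles, mesh.triangles)
        assert np.array_equal(back.region_labels, mesh.region_labels)


class TestUniformField:
    def test_zero_magnitude_and_direction_normalization(self):
        mesh = fx.make_gyrified_mesh(0, 0, resolution=8)
        assert np.all(fx.make_uniform_field(mesh, (0, 0, 1), 0.0).vectors == 0)
        a = fx.make_uniform_field(mesh, (0, 0, 1), 0.2).vectors
        b = fx.make_uniform_field(mesh, (0, 0, 2), 0.2).vectors
        assert np.allclose(a, b)
        assert np.allclose(a[0], [0, 0, 0.2])

    def test_zero_direction_rejected(self):
        mesh = fx.make_gyrified_mesh(0, 0, resolution=8)
        with pytest.raises(ValueError):
            fx.make_uniform_field(mesh, (0, 0, 0), 0.2)


class TestConnectome:
    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 30),
           density=st.floats(0.2, 1.0))
    def test_invariants_over_random_seeds(self, seed, n, density):
        conn = fx.make_connectome(n, density=density, seed=seed)
        assert np.allclose(conn.weights, conn.weights.T)
        assert np.all(np.diag(conn.weights) == 0)
        assert np.all(conn.weights >= 0)
        nz = conn.lengths[conn.lengths > 0]
        assert nz.min() >= 15.0 and nz.max() <= 180.0

    def test_full_density_edge_count(self):
        conn = fx.make_connectome(22, density=1.0, seed=0)
        iu = np.triu_indices(22, k=1)
        assert int((conn.weights[iu] > 0).sum()) == 231

    def test_log2_strength_less_skewed_than_raw(self):
        conn = fx.make_connectome(40, density=1.0, seed=3)
        strength = conn.weights.sum(axis=1)
        assert sstats.skew(strength) > sstats.skew(np.log2(strength))

    def test_seed_determinism(self):
        a = fx.make_connectome(10, seed=42)
        b = fx.make_connectome(10, seed=42)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.lengths, b.lengths)

    def test_length_range_outside_window_rejected(self):
        with pytest.raises(ValueError):
            fx.make_connectome(5, length_range=(10, 100))

    def test_csv_round_trip(self, tmp_path):
        conn = fx.make_connectome(6, seed=1)
        w, l = str(tmp_path / "w.csv"), str(tmp_path / "l.csv")
        fx.save_connectome(conn, w, l)
        back = fx.load_connectome(w, l)
        assert np.allclose(back.weights, conn.weights)
        assert np.allclose(back.lengths, conn.lengths)


class TestTheoreticalDistributions:
    def test_gaussian_mean(self):
        s = fx.make_theoretical_distribution("gaussian", 0.0, 100_000, seed=0)
        assert abs(s.mean()) < 3 * s.std() / np.sqrt(s.size)

    @pytest.mark.parametrize("kind,skew_bound", [
        ("bimodal_symmetric", ("lt", 0.1)),
        ("bimodal_asymmetric", ("gt", 0.2)),
    ])
    def test_bimodal_shapes(self, kind, skew_bound):
        s = fx.make_theoretical_distribution(kind, 0.0, 100_000, seed=1)
        assert count_modes(s) == 2
        op, bound = skew_bound
        skew = abs(sstats.skew(s))
        assert skew < bound if op == "lt" else skew > bound
        # the mixture mean is the target mean
        assert abs(s.mean()) < 3 * s.std() / np.sqrt(s.size)

    def test_shifted_versions_move_the_mean(self):
        for kind in fx.DISTRIBUTION_KINDS:
            s = fx.make_theoretical_distribution(kind, 0.05, 100_000, seed=2)
            assert abs(s.mean() - 0.05) < 3 * s.std() / np.sqrt(s.size)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            fx.make_theoretical_distribution("trimodal", 0.0, 10)

    def test_seed_determinism(self):
        a = fx.make_theoretical_distribution("gaussian", 0.0, 100, seed=9)
        b = fx.make_theoretical_distribution("gaussian", 0.0, 100, seed=9)
        assert np.array_equal(a, b)


class TestTargetFC:
    def test_equal_lengths_give_equal_plv_without_noise(self):
        conn = fx.make_connectome(4, seed=0)
        conn.lengths[:] = 0
        conn.lengths[0, 1] = conn.lengths[1, 0] = 50.0
        conn.lengths[2, 3] = conn.lengths[3, 2] = 50.0
        fc = fx.make_target_fc(conn, noise_sd=0.0)
        assert fc.plv[0, 1] == fc.plv[2, 3]

    def test_matrix_contract(self):
        fc = fx.make_target_fc(fx.make_connectome(8, seed=5), seed=5)
        assert np.all(fc.plv >= 0) and np.all(fc.plv <= 1)
        assert np.allclose(fc.plv, fc.plv.T)
        assert np.all(np.diag(fc.plv) == 1.0)

    def test_longer_decay_raises_mean_connectivity(self):
        conn = fx.make_connectome(10, seed=2)
        iu = np.triu_indices(10, k=1)
        short = fx.make_target_fc(conn, decay_length=30.0, noise_sd=0.0)
        long = fx.make_target_fc(conn, decay_length=120.0, noise_sd=0.0)
        assert long.plv[iu].mean() > short.plv[iu].mean()
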