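import numpy as np
import pytest
import scipy.io

from epmap.data_model import (
    EAMStudy,
    EAPoint,
    FormatError,
    ImportFieldError,
    Mesh,
    SurfaceECG,
    filter_points_by_force,
    import_openep,
    load_study,
    project_to_surface,
    save_study,
    studies_equal,
)
from epmap import synthetic

from conftest import random_tiny_study


# ---------------------------------------------------------------------------
# Mesh invariants
# ---------------------------------------------------------------------------


class TestMesh:
    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            Mesh(np.zeros((3, 3)), [[0, 1, 5]])

    def test_repeated_vertex(self):
        with pytest.raises(ValueError):
            Mesh(np.random.rand(4, 3), [[0, 1, 1]])

    def test_nonfinite_coordinates(self):
        v = np.random.rand(4, 3)
        v[2, 1] = np.nan
        with pytest.raises(ValueError):
            Mesh(v, [[0, 1, 2]])

    def test_edges_unique(self, sphere_mesh):
        e = sphere_mesh.edges()
        assert len(np.unique(e, axis=0)) == len(e)
        assert sphere_mesh.euler_characteristic() == 2


# ---------------------------------------------------------------------------
# save / load round-trip
# ---------------------------------------------------------------------------


class TestRoundTrip:
    def test_synthetic_study_roundtrip(self, tmp_path, small_study):
        study, _ = small_study
        p = tmp_path / "study.h5"
        save_study(study, p)
        assert studies_equal(study, load_study(p))

    def test_zero_point_study(self, tmp_path):
        rng = np.random.default_rng(0)
        study = random_tiny_study(rng)
        study.points = []
        p = tmp_path / "empty.h5"
        save_study(study, p)
        out = load_study(p)
        assert out.n_points == 0
        assert studies_equal(study, out)

    def test_randomized_roundtrip_100(self, tmp_path):
        rng = np.random.default_rng(42)
        for i in range(100):
            study = random_tiny_study(rng)
            p = tmp_path / f"s{i}.h5"
            save_study(study, p)
            assert studies_equal(study, load_study(p)), f"round-trip failed at {i}"

    def test_missing_group_error(self, tmp_path, small_study):
        import h5py

        study, _ = small_study
        p = tmp_path / "broken.h5"
        save_study(study, p)
        with h5py.File(p, "a") as f:
            del f["mesh/triangles"]
        with pytest.raises(FormatError, match="missing /mesh/triangles"):
            load_study(p)

    def test_version_mismatch(self, tmp_path, small_study):
        import h5py

        study, _ = small_study
        p = tmp_path / "vers.h5"
        save_study(study, p)
        with h5py.File(p, "a") as f:
            f.attrs["format_version"] = 999
        with pytest.raises(FormatError, match="format_version"):
            load_study(p)


# ---------------------------------------------------------------------------
# contact-force filter
# ---------------------------------------------------------------------------


def _force_study(forces):
    rng = np.random.default_rng(3)
    study = random_tiny_study(rng)
    study.points = [
        EAPoint(
            position=np.full(3, float(i)),
            surface_position=np.full(3, float(i)),
            unipolar=np.zeros(40),
            contact_force=f,
        )
        for i, f in enumerate(forces)
    ]
    return study


class TestForceFilter:
    def test_inclusive_bounds(self):
        study = _force_study([3.0, 5.0, 10.0, 25.0, 30.0])
        out = filter_points_by_force(study)
        assert [p.contact_force for p in out.points] == [5.0, 10.0, 25.0]

    def test_all_below_warns_empty(self):
        study = _force_study([2.0, 2.0, 2.0])
        with pytest.warns(UserWarning):
            out = filter_points_by_force(study)
        assert out.n_points == 0

    def test_missing_force_retained_flagged(self):
        study = _force_study([10.0, None, 30.0])
        out = filter_points_by_force(study)
        assert out.n_points == 2
        assert out.points[1].reason == "force_unknown"
        assert out.points[1].valid

    def test_min_greater_than_max(self):
        with pytest.raises(ValueError):
            filter_points_by_force(_force_study([10.0]), min_g=10, max_g=5)

    def test_idempotent_and_order_preserving(self):
        study = _force_study([6.0, 1.0, 24.0, 9.0, 26.0, 15.0])
        once = filter_points_by_force(study)
        twice = filter_points_by_force(once)
        assert studies_equal(once, twice)
        kept = [p.contact_force for p in once.points]
        assert kept == [6.0, 24.0, 9.0, 15.0]  # original order

    def test_original_untouched(self):
        study = _force_study([3.0, 10.0])
        n_before = study.n_points
        filter_points_by_force(study)
        assert study.n_points == n_before
        assert study.points[0].contact_force == 3.0


# ---------------------------------------------------------------------------
# surface projection
# ---------------------------------------------------------------------------


class TestProjectToSurface:
    triangle = Mesh(
        np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [0.0, 2.0, 0.0]]),
        np.array([[0, 1, 2]]),
    )

    def test_point_on_face_is_itself(self):
        p = np.array([[0.5, 0.5, 0.0]])
        out = project_to_surface(p, self.triangle)
        np.testing.assert_allclose(out, p, atol=1e-12)

    def test_orthogonal_foot_above_centroid(self):
        centroid = self.triangle.vertices.mean(axis=0)
        p = centroid + np.array([0.0, 0.0, 5.0])
        out = project_to_surface([p], self.triangle)
        np.testing.assert_allclose(out[0], centroid, atol=1e-12)

    def test_empty_mesh_error(self):
        mesh = Mesh(np.zeros((3, 3)), np.zeros((0, 3), dtype=np.int64))
        with pytest.raises(ValueError):
            project_to_surface(np.zeros((1, 3)), mesh)

    def test_brute_force_dense_sampling_oracle(self, sphere_mesh):
        # oracle: dense barycentric sampling of every triangle
        rng = np.random.default_rng(5)
        pts = rng.normal(scale=40.0, size=(10, 3))
        proj = project_to_surface(pts, sphere_mesh)

        a = sphere_mesh.vertices[sphere_mesh.triangles[:, 0]]
        b = sphere_mesh.vertices[sphere_mesh.triangles[:, 1]]
        c = sphere_mesh.vertices[sphere_mesh.triangles[:, 2]]
        k = 60
        u, v = np.meshgrid(np.linspace(0, 1, k), np.linspace(0, 1, k))
        u, v = u.ravel(), v.ravel()
        keep = u + v <= 1.0
        u, v = u[keep], v[keep]
        dense = (
            a[:, None, :] * (1 - u - v)[None, :, None]
            + b[:, None, :] * u[None, :, None]
            + c[:, None, :] * v[None, :, None]
        ).reshape(-1, 3)
        for p, q in zip(pts, proj):
            d_impl = np.linalg.norm(q - p)
            d_oracle = np.linalg.norm(dense - p, axis=1).min()
            assert d_impl <= d_oracle + 1e-6

    def test_output_on_mesh_barycentric(self, sphere_mesh):
        rng = np.random.default_rng(6)
        pts = rng.normal(scale=50.0, size=(20, 3))
        proj = project_to_surface(pts, sphere_mesh)
        a = sphere_mesh.vertices[sphere_mesh.triangles[:, 0]]
        b = sphere_mesh.vertices[sphere_mesh.triangles[:, 1]]
        c = sphere_mesh.vertices[sphere_mesh.triangles[:, 2]]
        for q in proj:
            # barycentric coordinates w.r.t. the nearest triangle plane
            found = False
            for ta, tb, tc in zip(a, b, c):
                m = np.column_stack([tb - ta, tc - ta])
                sol, *_ = np.linalg.lstsq(m, q - ta, rcond=None)
                u, v = sol
                resid = np.linalg.norm(ta + m @ sol - q)
                if resid < 1e-9 and -1e-9 <= u and -1e-9 <= v and u + v <= 1 + 1e-9:
                    found = True
                    break
            assert found, "projected point does not lie on any triangle"


# ---------------------------------------------------------------------------
# OpenEP-style MAT import
# ---------------------------------------------------------------------------


def _userdata_dict(n=5, t=60, with_surf=True):
    rng = np.random.default_rng(11)
    mesh, _ = synthetic.make_rv_mesh(0, 0.0, seed=0)
    pos = synthetic.sample_surface_points(mesh, n, rng)
    ud = {
        "surface": {
            "triRep": {
                "X": mesh.vertices,
                "Triangulation": mesh.triangles + 1,  # 1-based
            }
        },
        "electric": {
            "egmX": pos,
            "egm": rng.normal(size=(n, t)),
            "force": rng.uniform(0, 30, size=n),
            "ecg": rng.normal(size=(12, t)),
            "sampleFrequency": 1000.0,
            "annotations": {
                "referenceAnnotation": 30.0,
                "woi": np.array([-10.0, 10.0]),
            },
        },
    }
    if with_surf:
        ud["electric"]["egmSurfX"] = project_to_surface(pos, mesh)
    return ud


class TestImportOpenEP:
    def test_fixture_roundtrip(self, tmp_path):
        ud = _userdata_dict(n=6)
        p = tmp_path / "userdata.mat"
        scipy.io.savemat(p, {"userdata": ud})
        study = import_openep(p)
        assert study.n_points == 6
        assert study.mesh.n_triangles == 20
        np.testing.assert_allclose(study.positions, ud["electric"]["egmX"])
        np.testing.assert_allclose(
            study.surface_positions, ud["electric"]["egmSurfX"]
        )
        assert study.reference_annotation == 30.0
        assert study.woi == (-10.0, 10.0)
        assert "V2" in study.ecg.leads

    def test_missing_surfx_projects(self, tmp_path):
        ud = _userdata_dict(n=4, with_surf=False)
        p = tmp_path / "nosurf.mat"
        scipy.io.savemat(p, {"userdata": ud})
        study = import_openep(p)
        mesh = study.mesh
        expected = project_to_surface(study.positions, mesh)
        np.testing.assert_allclose(study.surface_positions, expected, atol=1e-9)

    def test_empty_mat_errors(self, tmp_path):
        p = tmp_path / "empty.mat"
        scipy.io.savemat(p, {"nothing": np.zeros(1)})
        with pytest.raises(ImportFieldError):
            import_openep(p)

    def test_missing_fields_listed(self, tmp_path):
        ud = _userdata_dict()
        del ud["electric"]["egm"]
        del ud["electric"]["annotations"]
        p = tmp_path / "partial.mat"
        scipy.io.savemat(p, {"userdata": ud})
        with pytest.raises(ImportFieldError) as exc:
            import_openep(p)
        assert "egm" in str(exc.value)
        assert "referenceAnnotation" in str(exc.value)

    def test_all_nan_trace_flagged_invalid(self, tmp_path):
        ud = _userdata_dict(n=3)
        ud["electric"]["egm"][1, :] = np.nan
        p = tmp_path / "nan.mat"
        scipy.io.savemat(p, {"userdata": ud})
        study = import_openep(p)
        assert not study.points[1].valid
        assert study.points[1].reason == "missing_trace"
        assert study.points[0].valid
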