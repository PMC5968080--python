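"""Mesh morphometry and replicate-measurement reliability statistics."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from disc3d.errors import InvalidInputError
from disc3d.morpho import (
    MeasurementSet,
    boundary_edge_count,
    load_beetle_measurement_summaries,
    mesh_surface_area,
    mesh_volume,
    read_measurement_table,
    reliability,
    reliability_from_summary,
    variance_ratio_test,
)


def _cube(edge_mm=10.0):
    return trimesh.creation.box(extents=(edge_mm,) * 3)


def _icosphere(r_mm=10.0, subdivisions=4):
    return trimesh.creation.icosphere(subdivisions=subdivisions, radius=r_mm)


class TestMeshMeasures:
    def test_cube_closed_forms(self):
        cube = _cube(10.0)
        assert mesh_surface_area(cube) == pytest.approx(6.00, abs=1e-9)
        assert mesh_volume(cube) == pytest.approx(1.000, abs=1e-9)

    def test_icosphere_against_analytic(self):
        sph = _icosphere(10.0, 4)
        assert mesh_surface_area(sph) == pytest.approx(4 * np.pi, rel=0.005)
        assert mesh_volume(sph) == pytest.approx(4 * np.pi / 3, rel=0.01)

    def test_matches_trimesh_oracle(self):
        """Cross-check our summations against trimesh's own properties."""
        mesh = _icosphere(7.3, 3)
        assert mesh_surface_area(mesh) == pytest.approx(mesh.area / 100.0, rel=1e-12)
        assert mesh_volume(mesh) == pytest.approx(mesh.volume / 1000.0, rel=1e-12)

    def test_zero_area_face_ignored(self):
        cube = _cube(10.0)
        v = np.vstack([cube.vertices, cube.vertices[0]])
        f = np.vstack([cube.faces, [0, 0, 8]])  # degenerate triangle
        assert mesh_surface_area((v, f)) == pytest.approx(6.00, abs=1e-9)

    def test_orientation_independent_volume(self):
        cube = _cube(10.0)
        flipped = (np.asarray(cube.vertices), np.asarray(cube.faces)[:, ::-1])
        assert mesh_volume(flipped) == pytest.approx(1.000, abs=1e-9)

    def test_rigid_motion_invariance(self):
        mesh = _icosphere(5.0, 3)
        a0, v0 = mesh_surface_area(mesh), mesh_volume(mesh)
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.2]).as_matrix()
        moved = (np.asarray(mesh.vertices) @ R.T + np.array([3.0, -7.0, 11.0]),
                 np.asarray(mesh.faces))
        assert mesh_surface_area(moved) == pytest.approx(a0, rel=1e-9)
        assert mesh_volume(moved) == pytest.approx(v0, rel=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(k=st.floats(min_value=0.1, max_value=10.0))
    def test_scaling_laws(self, k):
        """Area scales as k^2 and volume as k^3 under uniform scaling."""
        mesh = _icosphere(4.0, 2)
        a0, v0 = mesh_surface_area(mesh), mesh_volume(mesh)
        scaled = (np.asarray(mesh.vertices) * k, np.asarray(mesh.faces))
        assert mesh_surface_area(scaled) == pytest.approx(a0 * k**2, rel=1e-9)
        assert mesh_volume(scaled) == pytest.approx(v0 * k**3, rel=1e-9)

    def test_non_watertight_rejected_with_count(self):
        cube = _cube()
        open_mesh = (np.asarray(cube.vertices), np.asarray(cube.faces)[:-1])
        assert boundary_edge_count(open_mesh) == 3
        with pytest.raises(InvalidInputError, match="3"):
            mesh_volume(open_mesh)

    def test_empty_mesh_rejected(self):
        with pytest.raises(InvalidInputError):
            mesh_surface_area((np.zeros((0, 3)), np.zeros((0, 3), int)))


class TestReliability:
    def test_printed_summary_reproduces_cv(self):
        r = reliability_from_summary("ti_2d", 6.11, 0.51, 5.24, 6.88)
        assert round(r.cv_percent, 1) == 8.3

    def test_identical_replicates(self):
        r = reliability(MeasurementSet("x", (2.5, 2.5, 2.5)))
        assert r.cv_percent == 0.0
        assert r.max_rel_dev_percent == 0.0

    def test_hand_arithmetic(self):
        r = reliability(MeasurementSet("x", (1.0, 3.0)))
        assert r.mean_mm == pytest.approx(2.0)
        assert r.sd_mm == pytest.approx(np.sqrt(2.0))
        assert r.cv_percent == pytest.approx(70.7, abs=0.05)
        assert r.max_rel_dev_percent == pytest.approx(50.0)

    def test_requires_two_values(self):
        with pytest.raises(InvalidInputError):
            MeasurementSet("x", (1.0,))

    def test_beetle_summary_table(self):
        df = load_beetle_measurement_summaries()
        assert set(df.index) == {"sc_2d", "sc_3d", "ti_2d", "ti_3d"}
        cvs = {
            lbl: round(
                reliability_from_summary(lbl, row.mean_mm, row.sd_mm,
                                         row.min_mm, row.max_mm).cv_percent, 1)
            for lbl, row in df.iterrows()
        }
        assert cvs["sc_2d"] == 8.0
        assert cvs["ti_2d"] == 8.3
        assert cvs["ti_3d"] == 1.1

    def test_measurement_table_csv(self, tmp_path):
        p = tmp_path / "measures.csv"
        p.write_text(
            "label,observer,value_mm\nti,1,6.5\nti,2,6.7\nsc,1,2.6\nsc,2,2.8\n"
        )
        sets = read_measurement_table(p)
        assert [m.label for m in sets] == ["ti", "sc"]
        assert sets[0].values_mm == (6.5, 6.7)


class TestVarianceRatio:
    def test_identical_sets(self):
        a = MeasurementSet("a", (1.0, 2.0, 3.0))
        F, p = variance_ratio_test(a, a)
        assert F == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        a = MeasurementSet("a", (1e-9, 2.0, 4.0))  # variance 4 (values >0)
        b = MeasurementSet("b", (1.0, 2.0, 3.0))  # variance 1
        F, _ = variance_ratio_test(a, b)
        assert F == pytest.approx(4.0, rel=1e-6)

    def test_f_of_printed_magnitude_is_significant(self):
        """At n1 = n2 = 22, an F around 10 has p < 0.0001 (two-sided)."""
        from scipy import stats

        p = 2 * stats.f.sf(9.87, 21, 21)
        assert p < 1e-4
        # the test statistic itself is symmetric in its arguments
        rng = np.random.default_rng(0)
        a = MeasurementSet("a", tuple(2.63 + 0.21 * rng.standard_normal(22) + 3))
        b = MeasurementSet("b", tuple(2.72 + 0.07 * rng.standard_normal(22) + 3))
        F_ab, p_ab = variance_ratio_test(a, b)
        F_ba, p_ba = variance_ratio_test(b, a)
        assert F_ab == pytest.approx(F_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_zero_variance_rejected(self):
        a = MeasurementSet("a", (1.0, 1.0))
        b = MeasurementSet("b", (1.0, 2.0))
        with pytest.raises(InvalidInputError):
            variance_ratio_test(a, b)


def test_pipeline_closure_sphere_volume(sphere_scan_hull):
    """Scan -> EDOF masks -> hull -> volume agrees with the analytic sphere."""
    vol = mesh_volume(sphere_scan_hull["mesh"])
    analytic = 4 / 3 * np.pi * 27.0 / 1000.0
    assert vol == pytest.approx(analytic, rel=0.06)
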