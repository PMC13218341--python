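"""Jaccard overlap, surface error, length and section properties."""
import numpy as np
import pytest
import trimesh

from tibload.geometry import SurfaceMesh
from tibload.metrics import (GeometryError, HollowEllipseSection,
                             fit_distal_section, jaccard_index,
                             section_properties, surface_error,
                             tibial_length)
from tibload.phantom import PhantomSpec, build_surface, make_phantom


def _sphere(radius, center=(0, 0, 0), subdiv=3):
    m = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)
    return SurfaceMesh(np.asarray(m.vertices) + np.asarray(center),
                       np.asarray(m.faces))


class TestJaccard:
    def test_identical_meshes(self):
        s = _sphere(10.0)
        assert jaccard_index(s, s, voxel_mm=1.0) == 1.0

    def test_disjoint_meshes(self):
        a = _sphere(5.0)
        b = _sphere(5.0, center=(30.0, 0, 0))
        assert jaccard_index(a, b, voxel_mm=1.0) == 0.0

    def test_concentric_spheres_volume_ratio(self):
        a = _sphere(10.0, subdiv=4)
        b = _sphere(20.0, subdiv=4)
        assert jaccard_index(a, b, voxel_mm=0.5) == pytest.approx(0.125,
                                                                  abs=0.01)

    def test_symmetry_exact(self, default_phantom, rng):
        a = default_phantom.cortical
        b = SurfaceMesh(a.vertices * 1.03 + rng.normal(0, 0.5, 3),
                        a.faces.copy())
        assert jaccard_index(a, b, 2.0) == jaccard_index(b, a, 2.0)

    def test_grid_convergence(self, default_phantom):
        a = default_phantom.cortical
        b = SurfaceMesh(a.vertices * 1.05, a.faces.copy())
        j2 = jaccard_index(a, b, 2.0)
        j1 = jaccard_index(a, b, 1.0)
        assert abs(j1 - j2) < 0.02

    def test_invalid_inputs(self, default_phantom):
        with pytest.raises(ValueError):
            jaccard_index(default_phantom.cortical,
                          default_phantom.cortical, voxel_mm=0.0)
        open_mesh = SurfaceMesh(default_phantom.cortical.vertices,
                                default_phantom.cortical.faces[:-4])
        with pytest.raises(GeometryError):
            jaccard_index(open_mesh, default_phantom.cortical, 2.0)


class TestSurfaceError:
    def test_identity(self, default_phantom):
        mean, mx = surface_error(default_phantom.cortical,
                                 default_phantom.cortical)
        assert mean == 0.0 and mx == 0.0

    def test_rigid_translation_correspondence(self, default_phantom):
        moved = SurfaceMesh(default_phantom.cortical.vertices
                            + np.array([0, 0, 2.0]),
                            default_phantom.cortical.faces)
        mean, mx = surface_error(moved, default_phantom.cortical,
                                 mode="correspondence")
        assert mean == pytest.approx(2.0)
        assert mx == pytest.approx(2.0)

    def test_concentric_spheres_nearest(self):
        inner = _sphere(10.0, subdiv=4)
        outer = _sphere(11.0, subdiv=4)
        mean, mx = surface_error(inner, outer, mode="nearest")
        assert mean == pytest.approx(1.0, abs=0.05)
        assert mx == pytest.approx(1.0, abs=0.05)

    def test_count_mismatch_rejected(self, default_phantom):
        small = _sphere(5.0)
        with pytest.raises(ValueError):
            surface_error(small, default_phantom.cortical,
                          mode="correspondence")

    def test_triangle_inequality(self, default_phantom, rng):
        a = default_phantom.cortical
        b = SurfaceMesh(a.vertices + rng.normal(0, 1, a.vertices.shape),
                        a.faces)
        c = SurfaceMesh(a.vertices + rng.normal(0, 2, a.vertices.shape),
                        a.faces)
        ab = surface_error(a, b)[0]
        bc = surface_error(b, c)[0]
        ac = surface_error(a, c)[0]
        assert ac <= ab + bc + 1e-12


class TestTibialLength:
    def test_landmark_midpoints(self):
        lms = {"medial_condyle": np.array([5.0, -20, 400]),
               "lateral_condyle": np.array([-5.0, 20, 400]),
               "medial_malleolus": np.array([3.0, -15, 0]),
               "lateral_malleolus": np.array([-3.0, 15, 0])}
        assert tibial_length(lms) == pytest.approx(400.0)

    def test_rotation_invariance(self, rng):
        lms = {"medial_condyle": np.array([5.0, -20, 400]),
               "lateral_condyle": np.array([-5.0, 20, 400]),
               "medial_malleolus": np.array([3.0, -15, 0]),
               "lateral_malleolus": np.array([-3.0, 15, 0])}
        theta = 0.7
        R = np.array([[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
                      [-np.sin(theta), 0, np.cos(theta)]])
        rot = {k: R @ v for k, v in lms.items()}
        assert tibial_length(rot) == pytest.approx(tibial_length(lms),
                                                   abs=1e-9)

    def test_mesh_extent_matches_spec(self, default_phantom):
        assert tibial_length(default_phantom.cortical) == pytest.approx(
            default_phantom.spec.length)

    def test_missing_landmark(self):
        with pytest.raises(KeyError):
            tibial_length({"medial_condyle": np.zeros(3)})


class TestSection:
    def test_solid_circle(self):
        s = HollowEllipseSection(a_o=10.0, b_o=10.0)
        csa, i_ml, i_ap = section_properties(s)
        assert csa == pytest.approx(np.pi * 100.0)
        assert i_ml == pytest.approx(np.pi * 1e4 / 4.0)
        assert i_ap == pytest.approx(i_ml)

    def test_hand_computed_hollow_ellipse(self):
        s = HollowEllipseSection(a_o=15.0, b_o=12.0, a_i=10.0, b_i=8.0)
        csa, i_ml, i_ap = section_properties(s)
        assert csa == pytest.approx(np.pi * 100.0, rel=1e-9)     # 314.159
        assert i_ml == pytest.approx(25525.44, abs=0.01)

    def test_against_numerical_integration(self):
        """Closed forms vs a dense 2D quadrature over the annulus."""
        s = HollowEllipseSection(a_o=15.0, b_o=12.0, a_i=10.0, b_i=8.0)
        n = 1200
        x = np.linspace(-s.a_o, s.a_o, n)
        y = np.linspace(-s.b_o, s.b_o, n)
        X, Y = np.meshgrid(x, y, indexing="ij")
        dA = (x[1] - x[0]) * (y[1] - y[0])
        inside = ((X / s.a_o) ** 2 + (Y / s.b_o) ** 2 <= 1) \
            & ((X / s.a_i) ** 2 + (Y / s.b_i) ** 2 > 1)
        assert inside.sum() * dA == pytest.approx(s.csa_mm2, rel=2e-3)
        assert (X[inside] ** 2).sum() * dA == pytest.approx(s.i_ml_mm4,
                                                            rel=2e-3)
        assert (Y[inside] ** 2).sum() * dA == pytest.approx(s.i_ap_mm4,
                                                            rel=2e-3)

    def test_dimensional_scaling(self):
        s1 = HollowEllipseSection(15.0, 12.0, 10.0, 8.0)
        s2 = HollowEllipseSection(30.0, 24.0, 20.0, 16.0)
        assert s2.csa_mm2 == pytest.approx(4 * s1.csa_mm2)
        assert s2.i_ml_mm4 == pytest.approx(16 * s1.i_ml_mm4)

    def test_invalid_section(self):
        with pytest.raises(GeometryError):
            HollowEllipseSection(a_o=10.0, b_o=10.0, a_i=11.0, b_i=5.0)


class TestFitDistalSection:
    def test_phantom_ground_truth(self):
        spec = PhantomSpec(bow_mm=0.0)
        ph = make_phantom(spec)
        sec = fit_distal_section(ph.cortical, ph.endosteal)
        a_true, b_true = spec.semi_axes(np.array([1.0 / 3.0]))
        assert sec.a_o == pytest.approx(float(a_true[0]), rel=0.02)
        assert sec.b_o == pytest.approx(float(b_true[0]), rel=0.02)
        f = spec.endosteal_fraction
        assert sec.a_i == pytest.approx(f * float(a_true[0]), rel=0.02)

    def test_circular_shaft_symmetry(self):
        spec = PhantomSpec(ap_semi_axis=12.0, ml_semi_axis=12.0, bow_mm=0.0)
        sec = fit_distal_section(build_surface(spec))
        assert sec.a_o == pytest.approx(sec.b_o, rel=0.01)

    def test_solid_option(self):
        sec = fit_distal_section(build_surface(PhantomSpec()), None)
        assert sec.a_i == 0.0 and sec.b_i == 0.0
        assert sec.csa_mm2 > 0
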