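"""Cylinder-fit operations, sidechain spheres and the full helix model."""

import numpy as np
import pytest
from scipy import optimize

from helixforce import group_residues
from helixforce import helix_model as hm
from helixforce import synthetic_helix as sh
from helixforce.errors import DegenerateGeometryError, ValidationError

from conftest import model_from_spec


class TestBackboneCentroid:
    def test_mean_of_rows(self):
        m = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        np.testing.assert_allclose(hm.backbone_centroid(m), [1.0, 0.0, 0.0])

    def test_single_row_identity(self):
        np.testing.assert_allclose(
            hm.backbone_centroid(np.array([[5.0, -1.0, 2.0]])), [5.0, -1.0, 2.0]
        )

    def test_full_phase_coverage_centroid_on_axis(self):
        # 18 residues at 100 deg/residue cover all 18 distinct phases evenly,
        # so the centroid lies exactly on the true axis (y = z = 0).
        spec = sh.IdealHelixSpec(n_residues=18)
        atoms, _ = sh.generate_ideal_helix(spec)
        cas = np.array([a.position for a in atoms if a.atom_name == "CA"])
        centroid = hm.backbone_centroid(cas)
        np.testing.assert_allclose(centroid[1:], [0.0, 0.0], atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            hm.backbone_centroid(np.empty((0, 3)))


class TestPrincipalAxis:
    def test_collinear_points(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        direction, _ = hm.principal_axis(pts)
        np.testing.assert_allclose(direction, [1.0, 0.0, 0.0], atol=1e-12)

    def test_orientation_follows_row_order(self):
        pts = np.array([[3, 0, 0], [2, 0, 0], [1, 0, 0], [0, 0, 0]], dtype=float)
        direction, _ = hm.principal_axis(pts)
        np.testing.assert_allclose(direction, [-1.0, 0.0, 0.0], atol=1e-12)

    def test_decomposition_reconstructs_covariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        _, dec = hm.principal_axis(pts)
        recon = dec.left_singular_vectors @ np.diag(dec.singular_values) @ dec.right_singular_vectors
        np.testing.assert_allclose(recon, dec.covariance, atol=1e-12)
        assert np.all(np.diff(dec.singular_values) <= 1e-15)

    def test_oblique_axis_recovery_converges_with_length(self):
        # the SVD axis has a small systematic tilt from fractional turn
        # coverage; it shrinks as the helix grows
        axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
        errors = []
        for n in (18, 36, 72):
            spec = sh.IdealHelixSpec(n_residues=n, axis_direction=tuple(axis))
            atoms, _ = sh.generate_ideal_helix(spec)
            cas = np.array([a.position for a in atoms if a.atom_name == "CA"])
            direction, _ = hm.principal_axis(cas)
            errors.append(np.degrees(np.arccos(min(1.0, abs(np.dot(direction, axis))))))
        assert errors[0] < 3.0
        assert errors[2] < errors[1] < errors[0]
        assert errors[2] < 0.2

    def test_coincident_points_rejected(self):
        pts = np.ones((5, 3))
        with pytest.raises(DegenerateGeometryError):
            hm.principal_axis(pts)


class TestAxisEndpoints:
    def test_projection_onto_x_axis(self):
        start, end = hm.axis_endpoints(
            np.array([1.0, 0.0, 0.0]),
            np.array([1.0, 0.0, 0.0]),
            np.array([0.0, 1.0, 0.0]),
            np.array([2.0, -1.0, 0.0]),
        )
        np.testing.assert_allclose(start, [0.0, 0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(end, [2.0, 0.0, 0.0], atol=1e-12)

    def test_point_on_axis_is_fixed(self):
        start, _ = hm.axis_endpoints(
            np.zeros(3), np.array([1.0, 0.0, 0.0]), np.array([3.0, 0.0, 0.0]), np.ones(3)
        )
        np.testing.assert_allclose(start, [3.0, 0.0, 0.0], atol=1e-12)

    def test_axis_length_matches_rise(self, ideal_model):
        assert ideal_model.geometry.axis_length == pytest.approx(29 * 1.5, abs=0.1)

    def test_collinearity_invariant(self, ideal_model):
        geo = ideal_model.geometry
        span = geo.axis_end - geo.axis_start
        rel = geo.centroid - geo.axis_start
        cross = np.cross(span, rel)
        assert np.linalg.norm(cross) < 1e-6


class TestPointOnAxis:
    def test_simple_projection(self):
        foot, t = hm.point_on_axis(np.zeros(3), np.array([2.0, 0, 0]), np.array([1.0, 5, 0]))
        np.testing.assert_allclose(foot, [1.0, 0.0, 0.0])
        assert t == pytest.approx(0.5)

    def test_query_at_start(self):
        foot, t = hm.point_on_axis(np.zeros(3), np.array([2.0, 0, 0]), np.zeros(3))
        assert t == 0.0
        np.testing.assert_allclose(foot, np.zeros(3))

    def test_t_beyond_segment(self):
        foot, t = hm.point_on_axis(np.zeros(3), np.array([2.0, 0, 0]), np.array([3.0, 1, 0]))
        assert t == pytest.approx(1.5)
        np.testing.assert_allclose(foot, [3.0, 0.0, 0.0])

    def test_residual_perpendicular_to_axis(self):
        rng = np.random.default_rng(4)
        start, end = rng.normal(size=3), rng.normal(size=3)
        query = rng.normal(size=3)
        foot, _ = hm.point_on_axis(start, end, query)
        d_hat = (end - start) / np.linalg.norm(end - start)
        assert abs(np.dot(query - foot, d_hat)) < 1e-9

    def test_zero_length_axis_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            hm.point_on_axis(np.zeros(3), np.zeros(3), np.ones(3))


class TestBackboneRadius:
    def test_unit_distances(self):
        pts = np.array([[0, 1, 0], [1, -1, 0], [2, 0, 1], [3, 0, -1]], dtype=float)
        radius, dists = hm.backbone_radius(pts, np.zeros(3), np.array([3.0, 0, 0]))
        np.testing.assert_allclose(dists, np.ones(4))
        assert radius == 1.0

    def test_point_on_axis_zero_distance(self):
        pts = np.array([[1.5, 0.0, 0.0]])
        _, dists = hm.backbone_radius(pts, np.zeros(3), np.array([3.0, 0, 0]))
        assert dists[0] == pytest.approx(0.0, abs=1e-12)

    def test_ideal_helix_radius(self, ideal_model):
        assert ideal_model.geometry.radius == pytest.approx(2.3, abs=0.02)
        assert ideal_model.geometry.radius == pytest.approx(
            ideal_model.geometry.radial_distances.mean()
        )


class TestSidechainSphere:
    def test_two_atoms(self):
        sphere = hm.sidechain_sphere(
            np.array([[0.0, 0, 0], [2.0, 0, 0]]), np.zeros(3)
        )
        np.testing.assert_allclose(sphere.center, [1.0, 0.0, 0.0])
        assert sphere.sphere_radius == 1.0

    def test_single_atom_zero_radius(self):
        sphere = hm.sidechain_sphere(np.array([[4.0, 4, 4]]), np.zeros(3))
        np.testing.assert_allclose(sphere.center, [4.0, 4.0, 4.0])
        assert sphere.sphere_radius == 0.0

    def test_regular_tetrahedron_circumradius(self):
        verts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        verts *= 1.5 / np.sqrt(3.0)  # circumradius 1.5
        sphere = hm.sidechain_sphere(verts, np.zeros(3))
        np.testing.assert_allclose(sphere.center, np.zeros(3), atol=1e-12)
        assert sphere.sphere_radius == pytest.approx(1.5, abs=1e-12)

    def test_empty_is_glycine_case(self):
        ca = np.array([1.0, 2.0, 3.0])
        sphere = hm.sidechain_sphere(np.empty((0, 3)), ca, residue_name="GLY", residue_seq=7)
        np.testing.assert_allclose(sphere.center, ca)
        assert sphere.sphere_radius == 0.0
        assert sphere.atom_count == 0


class TestBuildHelixModel:
    def test_ideal_fixture(self, ideal_model):
        assert ideal_model.geometry.n_residues == 30
        assert len(ideal_model.sidechains) == 30
        assert ideal_model.geometry.radius == pytest.approx(2.3, abs=0.02)

    def test_glycine_first_skipped_as_frame_reference(self):
        seq = ("GLY",) + ("LEU",) * 9
        spec = sh.IdealHelixSpec(n_residues=10, sequence=seq)
        model = model_from_spec(spec)
        ref = hm.first_significant_sidechain(model.sidechains)
        assert ref.residue_name == "LEU"
        assert ref.residue_seq == 2

    def test_all_glycine_rejected(self):
        spec = sh.IdealHelixSpec(n_residues=6, sequence=("GLY",) * 6)
        atoms, ann = sh.generate_ideal_helix(spec)
        with pytest.raises(DegenerateGeometryError, match="significant"):
            hm.build_helix_model(group_residues(atoms, ann), 1)

    def test_too_few_residues_rejected(self):
        spec = sh.IdealHelixSpec(n_residues=4)
        atoms, ann = sh.generate_ideal_helix(spec)
        groups = group_residues(atoms, ann)[:3]
        with pytest.raises(ValidationError):
            hm.build_helix_model(groups, 1)

    def test_serialization_round_trip(self, tmp_path, ideal_model):
        path = tmp_path / "models.json"
        hm.save_models([ideal_model], path)
        (loaded,) = hm.load_models(path)
        np.testing.assert_allclose(
            loaded.geometry.backbone_positions, ideal_model.geometry.backbone_positions
        )
        np.testing.assert_allclose(loaded.geometry.direction, ideal_model.geometry.direction)
        assert loaded.geometry.radius == ideal_model.geometry.radius
        np.testing.assert_allclose(
            loaded.local_frame.matrix, ideal_model.local_frame.matrix
        )
        assert loaded.sidechains[0].residue_name == ideal_model.sidechains[0].residue_name


class TestEquivariance:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion(self, seed, random_rotation):
        spec = sh.IdealHelixSpec(n_residues=15, jitter_sd=0.15, seed=seed)
        atoms, ann = sh.generate_ideal_helix(spec)
        cas = np.array([a.position for a in atoms if a.atom_name == "CA"])
        rot = random_rotation(seed + 100)
        shift = np.array([5.0, -2.0, 9.0])
        geo = hm.fit_geometry(cas)
        geo_moved = hm.fit_geometry(cas @ rot.T + shift)
        np.testing.assert_allclose(
            geo_moved.centroid, rot @ geo.centroid + shift, atol=1e-9
        )
        np.testing.assert_allclose(geo_moved.direction, rot @ geo.direction, atol=1e-9)
        assert geo_moved.radius == pytest.approx(geo.radius, abs=1e-9)
        np.testing.assert_allclose(
            geo_moved.radial_distances, geo.radial_distances, atol=1e-9
        )

    def test_scale_equivariance(self):
        spec = sh.IdealHelixSpec(n_residues=12, jitter_sd=0.1, seed=3)
        atoms, _ = sh.generate_ideal_helix(spec)
        cas = np.array([a.position for a in atoms if a.atom_name == "CA"])
        geo = hm.fit_geometry(cas)
        geo_scaled = hm.fit_geometry(2.5 * cas)
        assert geo_scaled.radius == pytest.approx(2.5 * geo.radius, rel=1e-12)


def _brute_force_radius(points: np.ndarray) -> float:
    """Independent axis fit: dense direction search + local refinement.

    Minimises the perpendicular sum of squares over line directions through
    the centroid, never touching the SVD code path.
    """
    centered = points - points.mean(axis=0)

    def perp_ssq(angles):
        theta, phi = angles
        d = np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        perp = centered - np.outer(centered @ d, d)
        return float((perp**2).sum())

    thetas = np.linspace(0, np.pi, 60)
    phis = np.linspace(0, 2 * np.pi, 120, endpoint=False)
    best = min(
        ((perp_ssq((t, p)), (t, p)) for t in thetas for p in phis), key=lambda x: x[0]
    )
    result = optimize.minimize(perp_ssq, best[1], method="Nelder-Mead",
                               options={"xatol": 1e-12, "fatol": 1e-16})
    theta, phi = result.x
    d = np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    perp = centered - np.outer(centered @ d, d)
    return float(np.linalg.norm(perp, axis=1).mean())


@pytest.mark.parametrize("seed", [0, 7])
def test_radius_matches_brute_force_axis_search(seed):
    spec = sh.IdealHelixSpec(n_residues=12, jitter_sd=0.25, seed=seed)
    atoms, _ = sh.generate_ideal_helix(spec)
    cas = np.array([a.position for a in atoms if a.atom_name == "CA"])
    geo = hm.fit_geometry(cas)
    assert geo.radius == pytest.approx(_brute_force_radius(cas), abs=1e-6)
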