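"""Membrane forces: springs, area/volume constraints, curvature, bending."""

import numpy as np
import pytest

from platesim.config import PhysicalParams
from platesim.fixtures import make_sphere_mesh
from platesim.mesh import (
    PlateletMesh,
    make_platelet_mesh,
    mesh_volume,
    triangle_areas,
)
from platesim import mechanics
from platesim.mechanics import (
    ElasticParams,
    bending_forces,
    constraint_energy,
    constraint_forces,
    curvature_field,
    relax_mesh,
    spring_energy,
    spring_forces,
    total_nodal_forces,
)


@pytest.fixture(scope="module")
def platelet():
    return make_platelet_mesh(1.0e-6, 0.25, 258)


@pytest.fixture(scope="module")
def perturbed(platelet):
    rng = np.random.default_rng(3)
    return platelet.vertices + 15e-9 * rng.normal(size=platelet.vertices.shape)


class TestSpringForces:
    def test_zero_at_rest_state(self, platelet):
        f = spring_forces(platelet, 5e-4)
        scale = 5e-4 * platelet.rest_lengths.mean()
        assert np.abs(f).max() < 1e-12 * scale

    def test_two_vertex_hooke_law(self):
        # one edge, rest 75 nm stretched to 100 nm at k = E dx / 5 with
        # E = 25 kPa, dx = 0.1 um -> |F| = 12.5 pN attractive
        k = PhysicalParams().k_spring
        assert k == pytest.approx(5e-4)
        # use a degenerate two-triangle "sliver" sharing the stretched edge
        verts = np.array([[0, 0, 0], [100e-9, 0, 0], [50e-9, 40e-9, 0],
                          [50e-9, -40e-9, 0.0]])
        tris = np.array([[0, 1, 2], [1, 0, 3]])
        m = PlateletMesh(vertices=verts, triangles=tris)
        m.rest_lengths = m.rest_lengths.copy()
        edge01 = np.flatnonzero((m.edges == [0, 1]).all(axis=1))[0]
        m.rest_lengths[edge01] = 75e-9
        f = spring_forces(m, k)
        # vertex 0 pulled toward vertex 1 along +x
        assert f[0, 0] == pytest.approx(k * 25e-9, rel=1e-12)

    def test_momentum_conservation(self, platelet, perturbed):
        f = spring_forces(platelet, 5e-4, perturbed)
        assert np.abs(f.sum(axis=0)).max() < 1e-10 * np.abs(f).max()

    def test_degenerate_geometry_raises(self, platelet):
        bad = platelet.vertices.copy()
        bad[1] = bad[0]
        e0 = platelet.edges[0]
        if not ((e0 == [0, 1]).all() or (e0 == [1, 0]).all()):
            # make sure some edge actually collapses
            bad[platelet.edges[0, 1]] = bad[platelet.edges[0, 0]]
        with pytest.raises(ValueError, match="degenerate"):
            spring_forces(platelet, 5e-4, bad)


class TestConstraintForces:
    def test_zero_at_reference(self, platelet):
        f = constraint_forces(platelet, 1e-3, 1e-3, 1e3)
        ref_scale = 1e-3 * platelet.rest_lengths.mean()
        assert np.abs(f).max() < 1e-10 * ref_scale

    def test_inflated_sphere_pushed_inward(self):
        m = make_sphere_mesh(2, radius=1.0e-6)
        inflated = m.vertices * 1.01
        f = constraint_forces(m, 0.0, 0.0, 1e3, inflated)
        radial = np.einsum("ij,ij->i", f, inflated)
        assert np.all(radial < 0)

    def test_matches_energy_gradient(self, platelet, perturbed):
        ks, kt, kv = 2e-3, 1e-3, 2e3
        f = constraint_forces(platelet, ks, kt, kv, perturbed)
        rng = np.random.default_rng(11)
        d = 1e-12
        for vi in rng.choice(platelet.n_vertices, 4, replace=False):
            for ax in range(3):
                xp = perturbed.copy()
                xm = perturbed.copy()
                xp[vi, ax] += d
                xm[vi, ax] -= d
                fd = -(constraint_energy(platelet, ks, kt, kv, xp)
                       - constraint_energy(platelet, ks, kt, kv, xm)) / (2 * d)
                assert fd == pytest.approx(f[vi, ax], rel=1e-5, abs=1e-18)

    def test_spring_force_matches_energy_gradient(self, platelet, perturbed):
        k = 5e-4
        f = spring_forces(platelet, k, perturbed)
        rng = np.random.default_rng(12)
        d = 1e-12
        for vi in rng.choice(platelet.n_vertices, 4, replace=False):
            for ax in range(3):
                xp = perturbed.copy()
                xm = perturbed.copy()
                xp[vi, ax] += d
                xm[vi, ax] -= d
                fd = -(spring_energy(platelet, k, xp)
                       - spring_energy(platelet, k, xm)) / (2 * d)
                assert fd == pytest.approx(f[vi, ax], rel=1e-5, abs=1e-18)

    def test_zero_reference_rejected(self, platelet):
        bad = platelet.copy()
        bad.ref_volume = 0.0
        with pytest.raises(ValueError):
            constraint_forces(bad, 1e-3, 1e-3, 1e3)


class TestCurvature:
    def test_sphere_mean_curvature(self):
        m = make_sphere_mesh(4, radius=2.0e-6)  # 2562 vertices
        c = curvature_field(m)
        assert np.abs(c.K * 2.0e-6 - 1.0).max() < 0.03

    def test_flat_patch_zero_curvature(self):
        # planar triangulated square (open mesh; interior vertices only)
        n = 6
        xs, ys = np.meshgrid(np.arange(n), np.arange(n))
        verts = np.column_stack([xs.ravel(), ys.ravel(),
                                 np.zeros(n * n)]) * 1e-6
        tris = []
        for i in range(n - 1):
            for j in range(n - 1):
                v = i * n + j
                tris.append([v, v + 1, v + n])
                tris.append([v + 1, v + n + 1, v + n])
        m = PlateletMesh(vertices=verts, triangles=np.array(tris),
                         ref_volume=1.0)
        c = curvature_field(m)
        interior = ((xs.ravel() > 0) & (xs.ravel() < n - 1)
                    & (ys.ravel() > 0) & (ys.ravel() < n - 1))
        assert np.abs(c.K[interior]).max() < 1e-3 / 1e-6  # << 1/edge length

    def test_oblate_pole_against_analytic(self):
        # at the pole of the spheroid (a, a, c): kappa1 = kappa2 = c / a^2
        a, lam = 1.0e-6, 0.25
        m = make_platelet_mesh(a, lam, 958)
        c = curvature_field(m)
        ipole = np.argmax(m.vertices[:, 2])
        x, y = m.vertices[ipole, :2]
        # analytic mean curvature at that (near-pole) surface point
        K_ref = _ellipsoid_mean_curvature(a, lam * a, m.vertices[ipole])
        assert c.K[ipole] == pytest.approx(K_ref, rel=0.05)

    def test_principal_curvatures_average_to_mean(self):
        m = make_platelet_mesh(1.0e-6, 0.25, 258)
        c = curvature_field(m)
        assert np.allclose((c.kappa1 + c.kappa2) / 2.0, c.K, rtol=1e-10)
        assert np.allclose(np.linalg.norm(c.normals, axis=1), 1.0)


def _ellipsoid_mean_curvature(a: float, c: float, p: np.ndarray) -> float:
    """Mean curvature of x^2/a^2 + y^2/a^2 + z^2/c^2 = 1 at surface point p."""
    # implicit-surface formula K_mean = (grad.F normalization) using hessian
    g = np.array([2 * p[0] / a ** 2, 2 * p[1] / a ** 2, 2 * p[2] / c ** 2])
    H = np.diag([2 / a ** 2, 2 / a ** 2, 2 / c ** 2])
    ng = np.linalg.norm(g)
    div = (np.trace(H) - g @ H @ g / ng ** 2) / ng
    return div / 2.0


class TestBending:
    def test_sphere_force_uniform_and_radial(self):
        m = make_sphere_mesh(4, radius=2.0e-6)
        c = curvature_field(m)
        f = bending_forces(c, 1.0)
        mag = np.linalg.norm(f, axis=1) / c.vertex_area
        assert mag.std() / mag.mean() < 0.10
        outward = np.einsum("ij,ij->i", f, c.normals)
        assert np.all(outward > 0)

    def test_flat_patch_zero_force(self):
        n = 6
        xs, ys = np.meshgrid(np.arange(n), np.arange(n))
        verts = np.column_stack([xs.ravel(), ys.ravel(),
                                 np.zeros(n * n)]) * 1e-6
        tris = []
        for i in range(n - 1):
            for j in range(n - 1):
                v = i * n + j
                tris.append([v, v + 1, v + n])
                tris.append([v + 1, v + n + 1, v + n])
        m = PlateletMesh(vertices=verts, triangles=np.array(tris),
                         ref_volume=1.0)
        f = bending_forces(curvature_field(m), 1.0)
        interior = ((xs.ravel() > 0) & (xs.ravel() < n - 1)
                    & (ys.ravel() > 0) & (ys.ravel() < n - 1))
        assert np.abs(f[interior]).max() < 1e-12

    def test_radius_scaling_2K_cubed(self):
        # on a sphere Lap K = 0, so |F|/A = 2 k0 / R^3: halving R gives x8
        m1 = make_sphere_mesh(4, radius=2.0e-6)
        m2 = make_sphere_mesh(4, radius=4.0e-6)
        c1, c2 = curvature_field(m1), curvature_field(m2)
        d1 = (np.linalg.norm(bending_forces(c1, 1.0), axis=1)
              / c1.vertex_area).mean()
        d2 = (np.linalg.norm(bending_forces(c2, 1.0), axis=1)
              / c2.vertex_area).mean()
        assert d1 / d2 == pytest.approx(8.0, rel=0.02)


class TestTotals:
    def test_rest_state_force_free(self, platelet):
        params = ElasticParams(k_spring=5e-4, k_s=1e-3, k_t=1e-3, k_v=1e3,
                               k0_bend=0.0)
        total, terms = total_nodal_forces(platelet, params)
        scale = 5e-4 * platelet.rest_lengths.mean()
        assert np.abs(total).max() < 1e-9 * scale

    def test_additivity_of_terms(self, platelet, perturbed):
        params = ElasticParams(k_spring=5e-4, k_s=1e-3, k_t=1e-3, k_v=1e3,
                               k0_bend=1e-19)
        total, terms = total_nodal_forces(platelet, params, perturbed)
        assert np.allclose(total, sum(terms.values()))

    def test_internal_forces_conserve_momentum(self, platelet, perturbed):
        params = ElasticParams(k_spring=5e-4, k_s=1e-3, k_t=1e-3, k_v=1e3,
                               k0_bend=0.0)
        total, _ = total_nodal_forces(platelet, params, perturbed)
        assert np.abs(total.sum(axis=0)).max() < 1e-10 * np.abs(total).max()

    def test_internal_forces_conserve_angular_momentum(self, platelet,
                                                       perturbed):
        params = ElasticParams(k_spring=5e-4, k_s=1e-3, k_t=1e-3, k_v=1e3,
                               k0_bend=0.0)
        total, _ = total_nodal_forces(platelet, params, perturbed)
        torque = np.cross(perturbed, total).sum(axis=0)
        assert np.abs(torque).max() < 1e-10 * np.abs(
            np.cross(perturbed, total)).max()


def test_relaxation_restores_reference_area_volume(platelet):
    params = ElasticParams.from_physical(PhysicalParams())
    m = platelet.copy()
    rng = np.random.default_rng(5)
    m.vertices = m.vertices * 1.03 + 10e-9 * rng.normal(size=m.vertices.shape)
    x = relax_mesh(m, params, n_steps=400)
    area = triangle_areas(x, m.triangles).sum()
    vol = mesh_volume(x, m.triangles)
    assert area == pytest.approx(platelet.ref_area, rel=0.01)
    assert vol == pytest.approx(platelet.ref_volume, rel=0.01)
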