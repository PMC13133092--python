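"""Cross-polytope construction, hulls, and geometric descriptors."""

import math

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from sigpolytope import (
    PipelineConfig,
    anisotropy,
    barycenter,
    barycenter_distance,
    build_dual_polytope,
    compute_hull,
    crosspolytope_volume_closed_form,
    generate_vertices,
    volume_asymmetry,
)
from sigpolytope.errors import DegenerateGeometryError, DomainError, ShapeError
from sigpolytope.geometry import perturbation_deltas
from sigpolytope.records import CircuitryRecord

from conftest import make_side


def octahedron(deltas=(1.0, 1.0, 1.0)):
    pts = []
    for i, d in enumerate(deltas):
        for s in (+1, -1):
            p = [0.0, 0.0, 0.0]
            p[i] = s * d
            pts.append(p)
    return np.array(pts)


class TestVertexGeneration:
    def test_count_and_symmetry(self, rng):
        x = rng.normal(size=18)
        V = generate_vertices(x, alpha=1.0, epsilon=0.05)
        assert V.shape == (36, 18)
        np.testing.assert_allclose(V.mean(axis=0), x, rtol=1e-12, atol=1e-14)

    def test_epsilon_safeguard_dominates_at_zero(self):
        V = generate_vertices(np.zeros(18), alpha=1.0, epsilon=0.05)
        # an epsilon cross-polytope: every vertex is +/-0.05 along one axis
        norms = np.linalg.norm(V, axis=1)
        np.testing.assert_allclose(norms, 0.05)
        assert np.all(np.count_nonzero(V, axis=1) == 1)

    def test_deltas_rule(self):
        x = np.array([0.0, 0.5, -2.0])
        d = perturbation_deltas(x, alpha=1.0, epsilon=0.05)
        np.testing.assert_allclose(d, [0.05, 0.5, 2.0])

    def test_positive_parameters_required(self):
        with pytest.raises(DomainError):
            generate_vertices(np.zeros(3), alpha=0.0, epsilon=0.05)
        with pytest.raises(DomainError):
            generate_vertices(np.zeros(3), alpha=1.0, epsilon=0.0)


class TestClosedFormVolume:
    @pytest.mark.parametrize(
        "deltas,expected",
        [
            ((1.0, 1.0, 1.0), 4.0 / 3.0),
            ((1.0, 1.0), 2.0),
            (tuple([1.0] * 18), 2.0**18 / math.factorial(18)),
        ],
    )
    def test_known_volumes(self, deltas, expected):
        assert crosspolytope_volume_closed_form(deltas) == pytest.approx(expected, rel=1e-12)

    def test_positive_deltas_required(self):
        with pytest.raises(DomainError):
            crosspolytope_volume_closed_form([1.0, -0.1, 1.0])

    def test_monte_carlo_cross_check(self, rng):
        # rejection sampling in the bounding box of a random 3-D cross-polytope
        deltas = rng.uniform(0.5, 2.0, size=3)
        expected = crosspolytope_volume_closed_form(deltas)
        n = 200_000
        pts = rng.uniform(-deltas, deltas, size=(n, 3))
        inside = np.sum(np.abs(pts) / deltas, axis=1) <= 1.0
        box = float(np.prod(2 * deltas))
        p_hat = inside.mean()
        estimate = box * p_hat
        se = box * math.sqrt(p_hat * (1 - p_hat) / n)
        assert abs(estimate - expected) < 3 * se


class TestHull:
    def test_unit_octahedron_volume(self):
        hull = compute_hull(octahedron())
        assert hull.volume == pytest.approx(4.0 / 3.0, rel=1e-10)
        assert hull.n_hull_vertices == 6
        assert len(hull.facets) == 8

    def test_unit_cube_volume(self):
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
        )
        assert compute_hull(corners).volume == pytest.approx(1.0, rel=1e-10)

    def test_hull_volume_monotone_in_point_set(self, rng):
        pts = rng.normal(size=(12, 3))
        full = compute_hull(pts).volume
        # hull of any subset (with enough points) is no larger
        for _ in range(10):
            idx = rng.choice(12, size=8, replace=False)
            try:
                sub = compute_hull(pts[idx]).volume
            except DegenerateGeometryError:
                continue
            assert sub <= full + 1e-12
        # matches the 3-D closed form on a generated cross-polytope
        x = rng.normal(size=3)
        V = generate_vertices(x, alpha=1.0, epsilon=0.05)
        deltas = perturbation_deltas(x, alpha=1.0, epsilon=0.05)
        assert compute_hull(V).volume == pytest.approx(
            crosspolytope_volume_closed_form(deltas), rel=1e-6
        )

    def test_coplanar_points_raise_with_rank(self):
        pts = np.column_stack([np.random.default_rng(0).normal(size=(10, 2)), np.zeros(10)])
        with pytest.raises(DegenerateGeometryError) as err:
            compute_hull(pts)
        assert err.value.rank == 2

    def test_scaling_law(self, rng):
        x = rng.normal(size=3)
        base = compute_hull(generate_vertices(x, 1.0, 0.05)).volume
        scaled_vertices = x + 2.5 * (generate_vertices(x, 1.0, 0.05) - x)
        assert compute_hull(scaled_vertices).volume == pytest.approx(
            2.5**3 * base, rel=1e-9
        )


class TestDescriptors:
    def test_barycenter_basics(self):
        assert np.allclose(barycenter(octahedron() + 3.0), [3.0, 3.0, 3.0])
        np.testing.assert_array_equal(barycenter(np.array([[1.0, 2.0]])), [1.0, 2.0])
        with pytest.raises(DomainError):
            barycenter(np.empty((0, 3)))

    def test_barycenter_distance_345(self):
        assert barycenter_distance([0, 0, 0], [3, 4, 0]) == 5.0
        assert barycenter_distance([1, 1, 1], [1, 1, 1]) == 0.0
        with pytest.raises(ShapeError):
            barycenter_distance([0, 0], [0, 0, 0])

    def test_barycenter_distance_rotation_invariant(self, rng):
        a, b = rng.normal(size=3), rng.normal(size=3)
        d = barycenter_distance(a, b)
        for _ in range(5):
            R = special_ortho_group.rvs(3, random_state=rng)
            assert barycenter_distance(R @ a, R @ b) == pytest.approx(d, rel=1e-10)

    def test_volume_asymmetry(self):
        assert volume_asymmetry(8.0, 2.0) == (4.0, 4.0)
        assert volume_asymmetry(2.0, 8.0) == (0.25, 4.0)
        assert volume_asymmetry(3.0, 3.0) == (1.0, 1.0)
        with pytest.raises(DegenerateGeometryError):
            volume_asymmetry(0.0, 1.0)

    def test_anisotropy_stretch_and_rotation(self, rng):
        cloud = rng.normal(size=(2000, 3))
        stretched = cloud * np.array([10.0, 1.0, 1.0])
        a = anisotropy(stretched)
        assert a == pytest.approx(10.0, rel=0.15)
        R = special_ortho_group.rvs(3, random_state=rng)
        assert anisotropy(stretched @ R.T) == pytest.approx(a, rel=1e-8)
        assert anisotropy(cloud) == pytest.approx(1.0, rel=0.15)


class TestDualPolytope:
    def test_identical_sides_give_zero_distance(self, small_model, config, small_atlas):
        table, _ = small_atlas
        _, model = small_model
        side = make_side()
        rec = CircuitryRecord(id="twin", cancer_type="CT00", sig=side, int_=side)
        poly = build_dual_polytope(rec, model, config)
        assert poly.dbary == pytest.approx(0.0, abs=1e-10)
        assert poly.asym_ratio == pytest.approx(1.0, rel=1e-9)
        assert poly.proj_sig.shape == (36, 3)
        assert poly.proj_int.shape == (36, 3)

    def test_barycenter_equals_projected_latent_point(self, small_model, config):
        """Projection is affine, so the vertex-cloud barycenter must land on
        the projected latent vector (commutation)."""
        from sigpolytope import build_latent_vector

        _, model = small_model
        side = make_side(rho=-0.4, micro_score=1.2)
        rec = CircuitryRecord(id="c", cancer_type="CT00", sig=side, int_=make_side())
        poly = build_dual_polytope(rec, model, config)
        direct = model.project(build_latent_vector(side, config), n_components=3)
        np.testing.assert_allclose(poly.barycenter_sig, direct, atol=1e-10)

    def test_latent18_volume_mode_uses_closed_form(self, small_model):
        from sigpolytope import build_latent_vector

        _, model = small_model
        cfg = PipelineConfig(volume_space="latent18")
        side = make_side()
        rec = CircuitryRecord(id="c18", cancer_type="CT00", sig=side, int_=side)
        poly = build_dual_polytope(rec, model, cfg)
        deltas = perturbation_deltas(build_latent_vector(side, cfg), cfg.alpha, cfg.epsilon)
        assert poly.vol_sig == pytest.approx(
            crosspolytope_volume_closed_form(deltas), rel=1e-12
        )

    def test_monte_carlo_agreement_on_random_polytopes(self, small_model, rng):
        """3-D hull volumes agree with rejection-sampling estimates within 3 SE."""
        _, model = small_model
        n = 40_000
        failures = 0
        for _ in range(20):
            x = rng.normal(size=18)
            V = generate_vertices(x, 1.0, 0.05)
            proj = model.project(V, n_components=3)
            hull = compute_hull(proj)
            lo, hi = proj.min(axis=0), proj.max(axis=0)
            pts = rng.uniform(lo, hi, size=(n, 3))
            # inside test via hull facet equations
            from scipy.spatial import ConvexHull

            H = ConvexHull(proj)
            inside = np.all(pts @ H.equations[:, :3].T + H.equations[:, 3] <= 1e-12, axis=1)
            box = float(np.prod(hi - lo))
            p_hat = inside.mean()
            est = box * p_hat
            se = box * math.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n)
            if abs(est - hull.volume) >= 3 * se:
                failures += 1
        # 3-SE bands fail by chance very rarely; tolerate one outlier in 20
        assert failures <= 1
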