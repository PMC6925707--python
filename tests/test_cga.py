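"""Blade arithmetic, entity construction, duality, meets and oriented angles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neuroarm import cga
from neuroarm.cga import (
    DegenerateEntityError,
    GeometricEntity,
    ImaginaryEntityError,
    OrientedAngleFrame,
    blade,
    circle_params,
    dual,
    e0,
    e1,
    e2,
    e3,
    einf,
    embed_point,
    extract_euclidean,
    line_direction,
    make_entity,
    make_sphere,
    meet,
    oriented_angle,
    plane_normal,
    point_pair_points,
    product,
    scalar,
    sphere_params,
    undual,
)

coords = st.floats(-100.0, 100.0, allow_nan=False)


class TestProducts:
    def test_euclidean_metric(self):
        assert (e1 * e1).scalar_part == pytest.approx(1.0)
        assert (e2 * e2).scalar_part == pytest.approx(1.0)
        assert (e0 * e0).norm() == pytest.approx(0.0, abs=1e-12)
        assert (einf * einf).norm() == pytest.approx(0.0, abs=1e-12)
        assert (e0 | einf).scalar_part == pytest.approx(-1.0)

    def test_orthogonal_vectors_outer_and_inner(self):
        assert product(e1 * 3, e2 * 4, "outer").close_to(
            (e1 ^ e2) * 12), "3e1 ^ 4e2 = 12 e1^e2"
        assert product(e1 * 3, e2 * 4, "inner").norm() == pytest.approx(0.0)

    def test_conformal_point_inner_product_is_half_sq_distance(self):
        P0, P1 = embed_point([0, 0, 0]), embed_point([1, 0, 0])
        assert (P0.mv | P1.mv).scalar_part == pytest.approx(-0.5)

    def test_geometric_equals_inner_plus_outer_on_vectors(self, rng):
        for _ in range(20):
            a = cga.euclidean_vector(rng.uniform(-5, 5, 3)) + e0 * rng.uniform(-2, 2)
            b = cga.euclidean_vector(rng.uniform(-5, 5, 3)) + einf * rng.uniform(-2, 2)
            assert (a * b).close_to((a | b) + (a ^ b))

    def test_geometric_product_is_associative(self, rng):
        for _ in range(10):
            a, b, c = (cga.Multivector(rng.uniform(-1, 1, 32)) for _ in range(3))
            assert ((a * b) * c).close_to(a * (b * c), tol=1e-8)

    @given(st.lists(coords, min_size=3, max_size=3),
           st.lists(coords, min_size=3, max_size=3))
    def test_distance_identity(self, a, b):
        A, B = embed_point(a), embed_point(b)
        d2 = float(np.sum((np.array(a) - np.array(b)) ** 2))
        lhs = -2.0 * (A.mv | B.mv).scalar_part
        assert lhs == pytest.approx(d2, rel=1e-9, abs=1e-9)


class TestDual:
    def test_dual_of_scalar_is_inverse_pseudoscalar(self):
        d = dual(scalar(1.0))
        # e0^e3^e2^e1^einf = -(e0^e1^e2^e3^einf)
        assert d.close_to(blade(31, -1.0))

    def test_dual_of_pseudoscalar_inverse_roundtrip(self):
        assert dual(undual(scalar(1.0))).close_to(scalar(1.0))

    def test_dual_of_dual_sign_table_by_enumeration(self):
        """Brute-force oracle: multiply each basis blade by Ic^-1 twice."""
        ic_inv = dual(scalar(1.0))
        for m in range(32):
            expected = (blade(m) * ic_inv) * ic_inv
            got = dual(dual(blade(m)))
            assert got.close_to(expected)
            # and the sign is uniformly -1 in G(4,1)
            assert got.close_to(blade(m, -1.0))

    def test_dual_is_linear(self, rng):
        a = cga.Multivector(rng.uniform(-1, 1, 32))
        b = cga.Multivector(rng.uniform(-1, 1, 32))
        assert dual(a + b).close_to(dual(a) + dual(b))


class TestPointEmbedding:
    def test_origin_embeds_to_e0(self):
        assert embed_point([0, 0, 0]).mv.close_to(e0)

    def test_unit_x_embedding(self):
        assert embed_point([1, 0, 0]).mv.close_to(e1 + einf * 0.5 + e0)

    @given(st.lists(coords, min_size=3, max_size=3))
    def test_embedded_points_are_null(self, x):
        P = embed_point(x).mv
        assert abs((P | P).scalar_part) < 1e-12 * max(P.norm() ** 2, 1.0)

    def test_extract_roundtrip_and_scale_invariance(self):
        assert np.allclose(extract_euclidean(embed_point([1, 2, 3])), [1, 2, 3])
        assert np.allclose(extract_euclidean(embed_point([1, 2, 3]).mv * 2.0), [1, 2, 3])

    def test_point_at_infinity_rejected(self):
        with pytest.raises(DegenerateEntityError, match="infinity"):
            extract_euclidean(einf)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            embed_point([np.nan, 0, 0])


class TestSphere:
    def test_unit_sphere_formula(self):
        assert make_sphere([0, 0, 0], 1.0).mv.close_to(e0 - einf * 0.5)

    def test_zero_radius_sphere_is_point(self):
        assert make_sphere([3, -2, 5], 0.0).mv.close_to(embed_point([3, -2, 5]).mv)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            make_sphere([0, 0, 0], -1.0)

    def test_wedge_of_four_points_is_dual_unit_sphere(self):
        w = make_entity([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, 0, 1]], "sphere")
        ds = dual(make_sphere([0, 0, 0], 1.0).mv)
        nz = np.abs(ds.coeffs) > 1e-12
        ratios = w.mv.coeffs[nz] / ds.coeffs[nz]
        assert np.allclose(ratios, ratios[0])
        assert np.allclose(w.mv.coeffs[~nz], 0.0, atol=1e-9)


class TestMakeEntity:
    def test_line_contains_collinear_point(self):
        l = make_entity([[0, 0, 0], [0, 0, 1]], "line")
        assert l.contains(np.array([0.0, 0.0, 5.0]))
        assert not l.contains(np.array([1.0, 0.0, 0.0]))

    def test_plane_through_z_axis_contains_yz_samples(self):
        pi = make_entity([[0, 0, 0], [0, 0, 1], [0, 1, 0]], "plane")
        for y, z in [(2.0, 5.0), (-7.0, 0.1), (0.0, -3.0)]:
            assert pi.contains(np.array([0.0, y, z]))
        assert not pi.contains(np.array([1.0, 0.0, 0.0]))

    def test_degenerate_circle_rejected(self):
        with pytest.raises(DegenerateEntityError, match="degenerate"):
            make_entity([[1, 1, 1]] * 3, "circle")

    def test_entity_json_roundtrip(self):
        c = make_entity([[1, 0, 0], [0, 1, 0], [-1, 0, 0]], "circle")
        c2 = GeometricEntity.from_json_dict(c.to_json_dict())
        assert c2.kind == "circle" and c2.representation == "dual"
        assert c2.mv.close_to(c.mv)


class TestMeet:
    def test_two_unit_spheres_closed_form(self):
        c = meet(make_sphere([0, 0, 0], 1.0), make_sphere([1, 0, 0], 1.0))
        center, r, n = circle_params(c)
        assert np.allclose(center, [0.5, 0, 0], atol=1e-12)
        assert r == pytest.approx(np.sqrt(3) / 2, abs=1e-12)
        assert abs(n @ [1, 0, 0]) == pytest.approx(1.0)

    def test_tangent_plane_gives_single_point(self):
        c = meet(make_sphere([0, 0, 0], 1.0), cga.make_plane([0, 0, 1], 1.0))
        center, r, _ = circle_params(c)
        assert np.allclose(center, [0, 0, 1], atol=1e-9)
        assert r == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_spheres_flagged_imaginary(self):
        with pytest.raises(ImaginaryEntityError):
            meet(make_sphere([0, 0, 0], 1.0), make_sphere([5, 0, 0], 1.0))

    def test_random_sphere_pairs_against_closed_form(self, rng):
        for _ in range(200):
            c1, c2 = rng.uniform(-100, 100, 3), rng.uniform(-100, 100, 3)
            d = np.linalg.norm(c2 - c1)
            r1 = rng.uniform(0.6 * d, 1.5 * d)
            r2 = rng.uniform(abs(r1 - d) + 0.05 * d, r1 + 0.95 * d)
            circle = meet(make_sphere(c1, r1), make_sphere(c2, r2))
            center, r, n = circle_params(circle)
            a = (d * d + r1 * r1 - r2 * r2) / (2 * d)
            assert np.allclose(center, c1 + a * (c2 - c1) / d, atol=1e-9 * max(d, 1))
            assert r == pytest.approx(np.sqrt(r1 * r1 - a * a), rel=1e-9)
            assert abs(n @ ((c2 - c1) / d)) == pytest.approx(1.0, abs=1e-9)

    def test_unsupported_pair_rejected(self):
        P = embed_point([0, 0, 0])
        with pytest.raises(ValueError, match="unsupported"):
            meet(P, P)


class TestPointPair:
    def test_wedge_roundtrip_recovers_both_points(self):
        pp = make_entity([[1, 2, 3], [4, 5, 6]], "point_pair")
        a, b = point_pair_points(pp)
        got = sorted([tuple(np.round(a, 9)), tuple(np.round(b, 9))])
        assert np.allclose(got, [(1, 2, 3), (4, 5, 6)])

    def test_branch_order_higher_z_first(self):
        pp = make_entity([[0, 0, -1], [0, 0, 7]], "point_pair")
        a, b = point_pair_points(pp)
        assert a[2] > b[2]

    def test_tangent_pair_collapses(self):
        circle = meet(make_sphere([0, 0, 0], 1.0), cga.make_plane([0, 0, 1], 0.0))
        pp = meet(circle, cga.make_plane([1, 0, 0], 1.0))  # tangent cut at x=1
        a, b = point_pair_points(pp)
        assert np.allclose(a, b, atol=1e-6)
        assert np.allclose(a, [1, 0, 0], atol=1e-6)

    def test_imaginary_pair_rejected(self):
        circle = meet(make_sphere([0, 0, 0], 1.0), cga.make_plane([0, 0, 1], 0.0))
        with pytest.raises(ImaginaryEntityError):
            pp = meet(circle, cga.make_plane([1, 0, 0], 2.0))
            point_pair_points(pp)


class TestDirections:
    def test_line_direction_examples(self):
        l = make_entity([[0, 0, 0], [0, 0, 1]], "line")
        assert np.allclose(line_direction(l), [0, 0, 1])
        l2 = make_entity([[1, 1, 0], [2, 2, 0]], "line")
        assert np.allclose(line_direction(l2), np.array([1, 1, 0]) / np.sqrt(2))

    def test_line_direction_antisymmetric_in_point_order(self):
        fwd = line_direction(make_entity([[1, 2, 3], [4, 5, 6]], "line"))
        rev = line_direction(make_entity([[4, 5, 6], [1, 2, 3]], "line"))
        assert np.allclose(fwd, -rev)

    def test_base_plane_normal_sign_convention(self):
        pb = GeometricEntity(((e0 ^ e1) ^ e2) ^ einf, "plane", "dual")
        assert np.allclose(plane_normal(pb), [0, 0, 1])

    def test_plane_normal_orthogonal_to_plane(self, rng):
        for _ in range(20):
            pts = rng.uniform(-50, 50, (3, 3))
            try:
                pi = make_entity(pts, "plane")
            except DegenerateEntityError:
                continue
            n = plane_normal(pi)
            for i, j in [(0, 1), (0, 2)]:
                v = pts[j] - pts[i]
                assert abs(n @ v) < 1e-7 * max(np.linalg.norm(v), 1.0)


class TestOrientedAngle:
    @pytest.mark.parametrize("alpha,beta,expected", [
        ([1, 0, 0], [0, 1, 0], np.pi / 2),
        ([1, 0, 0], [-1, 0, 0], np.pi),
        ([1, 0, 0], [-np.sqrt(2) / 2, -np.sqrt(2) / 2, 0], -3 * np.pi / 4),
        ([1, 0, 0], [2, 0, 0], 0.0),
    ])
    def test_known_angles_in_xy_plane(self, alpha, beta, expected):
        th = oriented_angle(OrientedAngleFrame(alpha, beta, e1 ^ e2))
        assert th == pytest.approx(expected, abs=1e-12)

    def test_reversed_orientation_flips_sign(self):
        f = OrientedAngleFrame([1, 0, 0], [0, 1, 0], e2 ^ e1)
        assert oriented_angle(f) == pytest.approx(-np.pi / 2)

    def test_against_componentwise_atan2_oracle(self, rng):
        for _ in range(1000):
            a = rng.uniform(-3, 3, 2)
            b = rng.uniform(-3, 3, 2)
            if np.linalg.norm(a) < 1e-3 or np.linalg.norm(b) < 1e-3:
                continue
            th = oriented_angle(OrientedAngleFrame([a[0], a[1], 0],
                                                   [b[0], b[1], 0], e1 ^ e2))
            oracle = np.arctan2(b[1], b[0]) - np.arctan2(a[1], a[0])
            oracle = np.arctan2(np.sin(oracle), np.cos(oracle))
            if oracle == -np.pi:
                oracle = np.pi
            assert th == pytest.approx(oracle, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateEntityError):
            oriented_angle(OrientedAngleFrame([0, 0, 0], [1, 0, 0], e1 ^ e2))


def test_sphere_params_roundtrip(rng):
    for _ in range(20):
        c = rng.uniform(-100, 100, 3)
        r = rng.uniform(0.1, 50)
        center, radius = sphere_params(make_sphere(c, r))
        assert np.allclose(center, c) and radius == pytest.approx(r)
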