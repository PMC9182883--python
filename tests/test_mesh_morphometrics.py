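"""3D trait operations against analytic solids, oracles and invariants."""

import numpy as np
import pytest

from olivemorph import (
    SyntheticSpec,
    TriangleMesh,
    compute_appendage_length_3d,
    compute_center_of_gravity,
    compute_dimensions,
    compute_shadow_area,
    compute_skin_areas,
    compute_total_area,
    compute_volume,
    extract_mesh_traits,
    make_body,
    principal_frame,
)
from olivemorph.errors import MeshPreconditionError, ParameterError

from conftest import monte_carlo_volume, random_superellipsoid_spec

SPHERE_VOL = 4.0 * np.pi / 3.0
SPHERE_AREA = 4.0 * np.pi
CAP_45 = 2.0 * np.pi * (1.0 - np.cos(np.radians(45.0)))  # ~1.84030


def _rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class TestVolume:
    def test_unit_cube_exact(self, unit_cube):
        assert compute_volume(unit_cube) == pytest.approx(1.0, abs=1e-12)

    def test_icosphere_within_half_percent(self, icosphere):
        assert compute_volume(icosphere) == pytest.approx(SPHERE_VOL, rel=5e-3)

    def test_superellipsoid_matches_monte_carlo(self):
        spec = SyntheticSpec(semi_axes=(1.0, 0.7, 0.5), exponents=(0.5, 0.5),
                             mesh_subdivisions=5)
        mc, se = monte_carlo_volume(spec)
        vol = compute_volume(make_body(spec))
        assert abs(vol - mc) < 3.0 * se + 0.01 * mc  # 3 SE + discretization margin

    def test_open_mesh_rejected_with_edge_count(self, unit_cube):
        broken = TriangleMesh(unit_cube.vertices, unit_cube.faces[:-1])
        with pytest.raises(MeshPreconditionError, match=r"\d+ edge"):
            compute_volume(broken)

    def test_rigid_motion_invariance(self, icosphere):
        rng = np.random.default_rng(7)
        rot = _rotation(rng)
        moved = TriangleMesh(icosphere.vertices @ rot.T + [3.0, -2.0, 5.0], icosphere.faces)
        assert compute_volume(moved) == pytest.approx(compute_volume(icosphere), rel=1e-6)

    def test_flipped_orientation_same_magnitude(self, unit_cube):
        flipped = TriangleMesh(unit_cube.vertices, unit_cube.faces[:, ::-1])
        assert compute_volume(flipped) == pytest.approx(1.0, abs=1e-12)


class TestTotalArea:
    def test_unit_cube_exact(self, unit_cube):
        assert compute_total_area(unit_cube) == pytest.approx(6.0, abs=1e-12)

    def test_icosphere_within_half_percent(self, icosphere):
        assert compute_total_area(icosphere) == pytest.approx(SPHERE_AREA, rel=5e-3)

    def test_scaling_law_quadratic(self, icosphere):
        scaled = TriangleMesh(icosphere.vertices * 2.0, icosphere.faces)
        assert compute_total_area(scaled) == pytest.approx(
            4.0 * compute_total_area(icosphere), rel=1e-12
        )


class TestSkinAreas:
    def test_cube_partition(self, unit_cube):
        part = compute_skin_areas(unit_cube)
        assert part.up_skin_area == pytest.approx(1.0, abs=1e-12)
        assert part.down_skin_area == pytest.approx(1.0, abs=1e-12)
        assert part.lateral_area == pytest.approx(4.0, abs=1e-12)

    def test_exact_45_tie_is_inclusive(self, unit_cube):
        t = np.radians(45.0)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]]
        )
        tilted = TriangleMesh(unit_cube.vertices @ rot.T, unit_cube.faces)
        part = compute_skin_areas(tilted)
        assert part.up_skin_area == pytest.approx(2.0, abs=1e-9)
        assert part.down_skin_area == pytest.approx(2.0, abs=1e-9)
        assert part.lateral_area == pytest.approx(2.0, abs=1e-9)

    def test_sphere_caps_match_analytic(self, icosphere):
        part = compute_skin_areas(icosphere)
        assert part.up_skin_area == pytest.approx(CAP_45, rel=1e-2)
        assert part.down_skin_area == pytest.approx(part.up_skin_area, rel=1e-9)

    def test_partition_conserves_total_area(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            mesh = make_body(random_superellipsoid_spec(rng))
            thr = rng.uniform(5.0, 85.0)
            part = compute_skin_areas(mesh, angle_threshold=thr)
            assert part.total == pytest.approx(compute_total_area(mesh), rel=1e-9)

    def test_zero_axis_rejected(self, unit_cube):
        with pytest.raises(ParameterError):
            compute_skin_areas(unit_cube, up_axis=(0, 0, 0))


class TestCenterOfGravity:
    def test_unit_cube_center(self, unit_cube):
        assert compute_center_of_gravity(unit_cube) == pytest.approx((0.5, 0.5, 0.5), abs=1e-12)

    def test_translated_sphere(self, icosphere):
        moved = TriangleMesh(icosphere.vertices + [1.0, 2.0, 3.0], icosphere.faces)
        assert compute_center_of_gravity(moved) == pytest.approx((1.0, 2.0, 3.0), abs=1e-6)

    def test_two_cube_bar_solid(self):
        # [0,1]^3 union [1,2]x[0,1]^2 meshed as one closed bar: the
        # mass-weighted average of the two cube centroids is (1, .5, .5)
        import trimesh

        bar = trimesh.creation.box(extents=(2.0, 1.0, 1.0))
        mesh = TriangleMesh(bar.vertices + [1.0, 0.5, 0.5], bar.faces)
        assert compute_center_of_gravity(mesh) == pytest.approx((1.0, 0.5, 0.5), abs=1e-12)

    def test_open_mesh_rejected(self, unit_cube):
        broken = TriangleMesh(unit_cube.vertices, unit_cube.faces[:-1])
        with pytest.raises(MeshPreconditionError):
            compute_center_of_gravity(broken)


class TestPrincipalFrameAndDimensions:
    def test_ellipsoid_extents(self, ellipsoid_312):
        assert compute_dimensions(ellipsoid_312) == pytest.approx((3.0, 2.0, 1.0), rel=1e-2)

    def test_rotation_invariance_of_extents(self, ellipsoid_312):
        rng = np.random.default_rng(3)
        rot = _rotation(rng)
        moved = TriangleMesh(ellipsoid_312.vertices @ rot.T + 2.0, ellipsoid_312.faces)
        assert compute_dimensions(moved) == pytest.approx(
            compute_dimensions(ellipsoid_312), rel=1e-6
        )

    def test_frame_is_orthonormal_right_handed(self, ellipsoid_312):
        frame = principal_frame(ellipsoid_312)
        r = frame.rotation
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-10)
        assert frame.axis_extents[0] >= frame.axis_extents[1] >= frame.axis_extents[2]

    def test_cube_isotropic_tie_break(self, unit_cube):
        frame = principal_frame(unit_cube)
        assert frame.axis_extents == pytest.approx((1.0, 1.0, 1.0), abs=1e-12)
        assert np.allclose(np.abs(frame.rotation), np.eye(3), atol=1e-12)

    def test_scaling_law_linear(self, ellipsoid_312):
        scaled = TriangleMesh(ellipsoid_312.vertices * 2.5, ellipsoid_312.faces)
        assert compute_dimensions(scaled) == pytest.approx(
            tuple(2.5 * np.array(compute_dimensions(ellipsoid_312))), rel=1e-12
        )

    def test_generated_endocarp_length_recovered(self):
        # longest endocarp of the survey: 3.38 cm
        spec = SyntheticSpec(semi_axes=(1.69, 0.6, 0.55), mesh_subdivisions=3)
        length = compute_dimensions(make_body(spec))[0]
        assert length == pytest.approx(3.38, rel=2e-2)


class TestShadowArea:
    def test_unit_cube_along_z(self, unit_cube):
        area = compute_shadow_area(unit_cube, direction=(0, 0, 1))
        assert area == pytest.approx(1.0, abs=201 * 0.005**2)  # one pixel row

    def test_sphere_profile_is_a_disc(self, icosphere):
        assert compute_shadow_area(icosphere, direction=(0, 0, 1)) == pytest.approx(
            np.pi, rel=1e-2
        )

    def test_stacked_cubes_union_not_sum(self, unit_cube):
        import trimesh

        top = trimesh.creation.box(extents=(1, 1, 1))
        shifted = TriangleMesh(
            np.vstack([unit_cube.vertices, top.vertices + [0.5, 0.5, 1.5]]),
            np.vstack([unit_cube.faces, top.faces + unit_cube.n_vertices]),
        )
        area = compute_shadow_area(shifted, direction=(0, 0, 1))
        assert area == pytest.approx(1.0, abs=300 * 0.005**2)

    def test_default_direction_gives_length_width_profile(self, ellipsoid_312):
        # third principal axis projection shows the 3x2 face: pi*1.5*1.0
        assert compute_shadow_area(ellipsoid_312) == pytest.approx(np.pi * 1.5, rel=1e-2)

    def test_degenerate_direction_rejected(self, unit_cube):
        with pytest.raises(ParameterError):
            compute_shadow_area(unit_cube, direction=(0.0, 0.0, 0.0))


class TestAppendage3D:
    def test_pure_ellipsoid_zero(self, ellipsoid_312):
        assert compute_appendage_length_3d(ellipsoid_312) == 0.0

    def test_known_appendage_recovered(self):
        spec = SyntheticSpec(
            semi_axes=(1.5, 0.8, 0.75), appendage_length=0.25, mesh_subdivisions=4
        )
        est = compute_appendage_length_3d(make_body(spec))
        assert abs(est - 0.25) <= max(0.05 * 0.25, 2 * 0.005)

    def test_sub_threshold_appendage_called_zero(self):
        spec = SyntheticSpec(
            semi_axes=(1.5, 0.8, 0.75), appendage_length=0.005,
            appendage_base_radius=0.1, mesh_subdivisions=4,
        )
        assert compute_appendage_length_3d(make_body(spec)) == 0.0


class TestExtractMeshTraits:
    def test_icosphere_full_vector(self, icosphere):
        traits = extract_mesh_traits(icosphere)
        assert traits.volume == pytest.approx(SPHERE_VOL, rel=5e-3)
        assert traits.total_area == pytest.approx(SPHERE_AREA, rel=5e-3)
        assert traits.shadow_area == pytest.approx(np.pi, rel=1e-2)
        assert traits.up_skin_area == pytest.approx(CAP_45, rel=1e-2)
        assert traits.center_of_gravity == pytest.approx((0, 0, 0), abs=1e-6)
        assert traits.length == pytest.approx(2.0, rel=1e-2)
        assert traits.appendage_length == 0.0
        assert traits.missing == ()

    def test_largest_fruit_volume_recovered(self):
        # 11.28 cm^3, the largest fruit volume in the survey
        b = np.sqrt(11.28 / (4.0 * np.pi / 3.0 * 1.915))
        spec = SyntheticSpec(semi_axes=(1.915, b, b), mesh_subdivisions=4)
        traits = extract_mesh_traits(make_body(spec))
        assert traits.volume == pytest.approx(11.28, rel=2e-2)

    def test_open_mesh_partial_failure(self, icosphere):
        open_mesh = TriangleMesh(icosphere.vertices, icosphere.faces[:-1])
        traits = extract_mesh_traits(open_mesh)
        assert np.isnan(traits.volume)
        assert "volume" in traits.missing
        assert traits.total_area > 0
        assert traits.length > 0


def test_refinement_converges_to_sphere():
    """Volume, area, shadow and cap errors all shrink with subdivision."""
    import trimesh

    errors = []
    for level in (2, 3, 4):
        ball = trimesh.creation.icosphere(subdivisions=level, radius=1.0)
        mesh = TriangleMesh(ball.vertices, ball.faces)
        errors.append(
            (
                abs(compute_volume(mesh) - SPHERE_VOL),
                abs(compute_total_area(mesh) - SPHERE_AREA),
                abs(compute_shadow_area(mesh, direction=(0, 0, 1)) - np.pi),
                abs(compute_skin_areas(mesh).up_skin_area - CAP_45),
            )
        )
    errors = np.array(errors)
    assert np.all(errors[1:, :2] < errors[:-1, :2])  # exact quantities decrease
    assert errors[-1, 2] <= errors[0, 2] + 1e-3  # rasterized ones within noise
    assert errors[-1, 3] <= errors[0, 3]
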