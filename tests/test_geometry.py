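"""Mesh construction, assembly, morphing, normalization, UV projection."""

import math

import numpy as np
import pytest
import trimesh as _trimesh

from quaddle import (
    BodyProfile,
    assemble,
    build_appendage,
    build_body,
    build_from_params,
    default_catalogue,
    full_default_spec,
    morph,
    normalize,
    params_from_spec,
    planar_uv,
    random_spec,
    ObjectSpec,
)
from quaddle.geometry import BODY_PROFILES, MeshError


def to_trimesh(mesh):
    return _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)


class TestBuildBody:
    def test_cylinder_rings_equidistant_from_axis(self):
        mesh = build_body(BodyProfile(0.4, 0.4), segments=32, rings=8)
        wall = mesh.vertices[np.hypot(mesh.vertices[:, 0], mesh.vertices[:, 1]) > 1e-9]
        radii = np.hypot(wall[:, 0], wall[:, 1])
        assert np.allclose(radii, 0.4, atol=1e-12)

    def test_cone_top_collapses_to_apex(self):
        mesh = build_body(BodyProfile(0.5, 0.0), segments=16, rings=4)
        top = mesh.vertices[mesh.vertices[:, 2] == 0.5]
        assert len(top) == 1
        assert np.allclose(top[0], [0, 0, 0.5])

    def test_cylinder_volume_matches_analytic(self):
        mesh = build_body(BodyProfile(0.5, 0.5, 2.0, 1.0), segments=64, rings=32)
        tm = to_trimesh(mesh)
        assert tm.is_watertight
        analytic = math.pi * 0.5 ** 2 * 1.0
        assert abs(tm.volume - analytic) / analytic < 0.02

    def test_sphere_volume_matches_analytic(self):
        mesh = build_body(BodyProfile(0.5, 0.5, 2.0, 1.0, "arc"), segments=64, rings=64)
        tm = to_trimesh(mesh)
        analytic = 4.0 / 3.0 * math.pi * 0.5 ** 3
        assert abs(tm.volume - analytic) / analytic < 0.02

    def test_cube_profile_near_square_cross_section(self):
        mesh = build_body(BodyProfile(0.5, 0.5, 8.0), segments=64, rings=4)
        wall = mesh.vertices[np.hypot(mesh.vertices[:, 0], mesh.vertices[:, 1]) > 1e-9]
        # superellipse exponent 8: max |x| approaches the half-width
        assert np.abs(wall[:, 0]).max() == pytest.approx(0.5, abs=1e-9)
        assert np.abs(wall[:, :2]).max() <= 0.5 + 1e-9

    def test_degenerate_profile_rejected(self):
        with pytest.raises(ValueError):
            BodyProfile(0.0, 0.0)

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError):
            build_body(BODY_PROFILES["sphere"], segments=4)

    def test_no_zero_area_faces_at_default_resolution(self):
        for name, profile in BODY_PROFILES.items():
            build_body(profile).validate()


class TestBuildAppendage:
    def test_straight_endpoint_distance_equals_length(self):
        mesh = build_appendage("straight", "regular", "pointy", base_length=0.5)
        assert mesh.vertices[:, 0].max() == pytest.approx(0.5, abs=1e-12)
        base_center = mesh.vertices[np.linalg.norm(mesh.vertices, axis=1) < 1e-12]
        assert len(base_center) == 1

    @pytest.mark.parametrize("length, scale", [("short", 0.7), ("regular", 1.0),
                                               ("long", 1.3)])
    def test_length_classes(self, length, scale):
        mesh = build_appendage("straight", length, "pointy", base_length=0.5)
        assert mesh.vertices[:, 0].max() == pytest.approx(0.5 * scale, abs=1e-12)

    def test_up_down_are_mirror_images(self):
        up = build_appendage("up", "regular", "blunt")
        down = build_appendage("down", "regular", "blunt")
        mirrored = up.vertices * np.array([1.0, 1.0, -1.0])
        assert np.allclose(down.vertices, mirrored, atol=1e-12)
        assert np.array_equal(down.faces, up.faces)

    def test_pointy_tip_has_unique_apex(self):
        mesh = build_appendage("straight", "regular", "pointy")
        xmax = mesh.vertices[:, 0].max()
        assert (mesh.vertices[:, 0] == xmax).sum() == 1

    def test_flat_tip_ends_in_disc(self):
        mesh = build_appendage("straight", "regular", "flat", base_length=0.5)
        end = mesh.vertices[np.isclose(mesh.vertices[:, 0], 0.5)]
        assert len(end) > 2  # a ring plus its center, not an apex

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            build_appendage("up", "regular", "pointy", radius=0.0)

    def test_unknown_tip_rejected(self):
        with pytest.raises(ValueError):
            build_appendage("up", "regular", "spiky")


class TestAssemble:
    def test_body_only_spec(self, catalogue):
        spec = ObjectSpec.from_features(catalogue)
        mesh = assemble(spec, catalogue)
        assert set(mesh.part_labels) == {"body", "head"}

    def test_full_spec_has_all_part_labels(self, catalogue, full_spec):
        mesh = assemble(full_spec, catalogue)
        assert set(mesh.part_labels) == {"body", "head", "arm", "ear", "beak"}
        mesh.validate()

    def test_at_most_two_arms(self, catalogue):
        for i in range(100):
            spec = random_spec(catalogue, seed=13, index=i)
            mesh = assemble(spec, catalogue, segments=12, rings=6)
            arm_faces = mesh.part_labels == "arm"
            # arms appear as at most two connected components
            if arm_faces.any():
                sub = to_trimesh(mesh)
                arm = sub.submesh([np.nonzero(arm_faces)[0]], append=True)
                assert len(arm.split(only_watertight=False)) <= 2

    def test_assembly_is_deterministic(self, catalogue, full_spec):
        a = assemble(full_spec, catalogue, segments=16, rings=8)
        b = assemble(full_spec, catalogue, segments=16, rings=8)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)


class TestMorph:
    def test_endpoints_reproduce_inputs_exactly(self, catalogue):
        a = full_default_spec(catalogue, "a")
        b = a.replace(catalogue, body_shape="cone", left_arm_angle="down")
        assert morph(a, b, 0.0, catalogue).continuous == \
            params_from_spec(a, catalogue).continuous
        assert morph(a, b, 1.0, catalogue).continuous == \
            params_from_spec(b, catalogue).continuous

    def test_cone_to_inverted_cone_midpoint_is_cylinder(self, catalogue):
        a = full_default_spec(catalogue).replace(catalogue, body_shape="cone")
        b = a.replace(catalogue, body_shape="inverted_cone")
        mid = morph(a, b, 0.5, catalogue)
        profile = mid.body_profile()
        assert profile.r_bottom == pytest.approx(profile.r_top)
        assert profile.r_bottom > 0

    def test_interpolation_is_monotonic_per_parameter(self, catalogue):
        a = full_default_spec(catalogue).replace(
            catalogue, body_shape="cone", left_arm_angle="down")
        b = a.replace(catalogue, body_shape="inverted_cone", left_arm_angle="up")
        ts = np.linspace(0, 1, 9)
        rb = [morph(a, b, t, catalogue).continuous["body_r_bottom"] for t in ts]
        ang = [morph(a, b, t, catalogue).continuous["left_arm_angle_deg"] for t in ts]
        assert np.all(np.diff(rb) <= 0)
        assert np.all(np.diff(ang) >= 0)

    def test_categorical_switches_at_midpoint(self, catalogue):
        a = full_default_spec(catalogue).replace(catalogue, head_shape="sphere")
        b = a.replace(catalogue, head_shape="cube")
        assert morph(a, b, 0.25, catalogue).categorical["head_shape"] == "sphere"
        assert morph(a, b, 0.75, catalogue).categorical["head_shape"] == "cube"

    def test_t_out_of_range_rejected(self, catalogue, full_spec):
        with pytest.raises(ValueError):
            morph(full_spec, full_spec, 1.5, catalogue)

    def test_morphed_params_build_a_valid_mesh(self, catalogue):
        a = full_default_spec(catalogue).replace(catalogue, body_shape="cone")
        b = a.replace(catalogue, body_shape="inverted_cone")
        mesh = build_from_params(morph(a, b, 0.5, catalogue), segments=16, rings=8)
        mesh.validate()


class TestNormalize:
    def test_bbox_centered_and_scaled(self, catalogue, full_spec):
        mesh = normalize(assemble(full_spec, catalogue, segments=16, rings=8))
        lo, hi = mesh.bounds()
        assert np.allclose((lo + hi) / 2, 0, atol=1e-9)
        assert (hi - lo).max() == pytest.approx(2.0, abs=1e-9)

    def test_scale_invariance(self, catalogue, full_spec):
        mesh = assemble(full_spec, catalogue, segments=16, rings=8)
        scaled = mesh.transformed(scale=5.0)
        assert np.allclose(normalize(mesh).vertices, normalize(scaled).vertices,
                           atol=1e-12)

    def test_max_extent_over_random_objects(self, catalogue):
        for i in range(25):
            spec = random_spec(catalogue, seed=21, index=i)
            mesh = normalize(assemble(spec, catalogue, segments=12, rings=6))
            lo, hi = mesh.bounds()
            assert (hi - lo).max() == pytest.approx(2.0, abs=1e-9)

    def test_idempotent(self, catalogue, full_spec):
        once = normalize(assemble(full_spec, catalogue, segments=16, rings=8))
        twice = normalize(once)
        assert np.allclose(once.vertices, twice.vertices, atol=1e-12)

    def test_empty_mesh_rejected(self):
        from quaddle.geometry import TriMesh
        with pytest.raises(MeshError):
            normalize(TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int)))


class TestPlanarUV:
    def test_front_back_mirror_identical_uvs(self):
        # lathe bodies contain exact y-mirrored vertex pairs
        mesh = planar_uv(normalize(build_body(BODY_PROFILES["cylinder"],
                                              segments=16, rings=8)))
        v = mesh.vertices
        for front in (np.argmax(v[:, 1]), np.argmin(v[:, 1])):
            target = v[front] * np.array([1, -1, 1])
            dists = np.linalg.norm(v - target, axis=1)
            mirrored = np.argmin(dists)
            assert dists[mirrored] < 1e-9
            assert np.allclose(mesh.uvs[front], mesh.uvs[mirrored], atol=1e-9)

    def test_corner_mapping(self):
        from quaddle.geometry import TriMesh
        mesh = TriMesh(np.array([[-1, 0, -1], [1, 0, 1], [0, 0, 0]]),
                       np.array([[0, 1, 2]]))
        uv = planar_uv(mesh).uvs
        assert np.allclose(uv[0], [0, 0])
        assert np.allclose(uv[1], [1, 1])
        assert np.allclose(uv[2], [0.5, 0.5])

    def test_uv_range_over_random_objects(self, catalogue):
        for i in range(10):
            spec = random_spec(catalogue, seed=31, index=i)
            mesh = planar_uv(normalize(assemble(spec, catalogue, segments=12, rings=6)))
            assert mesh.uvs.min() >= 0.0 and mesh.uvs.max() <= 1.0
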