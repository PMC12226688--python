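"""Feature catalogue, object specs, sub-dimension expansion, table format."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quaddle import (
    ObjectSpec,
    SpecValidationError,
    TableParseError,
    default_catalogue,
    expand_subdimensions,
    full_default_spec,
    parse_object_table,
    random_spec,
    write_object_table,
)


class TestCatalogue:
    def test_ten_user_facing_dimensions(self, catalogue):
        assert len(catalogue.dimensions) == 10

    def test_arm_has_three_preconfigured_angles(self, catalogue):
        assert catalogue.dimension("arm_angle").values == ("up", "down", "straight")

    def test_ear_length_classes(self, catalogue):
        assert catalogue.dimension("ear_length").values == ("regular", "long", "short")

    def test_ear_shape_classes(self, catalogue):
        assert catalogue.dimension("ear_shape").values == ("straight", "pointy", "blunt")

    def test_twentyfour_scored_subdimensions_sum_to_max_score(self, catalogue):
        subs = catalogue.scored_subdimensions
        assert len(subs) == 24
        assert catalogue.max_score == pytest.approx(11.75)

    def test_group_weights(self, catalogue):
        for dim in catalogue.dimensions:
            if dim.group == "primary":
                assert dim.weight in (2.0, 1.5)
            elif dim.group == "secondary":
                assert dim.weight == 0.75
            else:
                assert dim.weight == 0.25

    def test_every_subdimension_maps_to_one_dimension(self, catalogue):
        names = [n for n, _ in catalogue.scored_subdimensions]
        assert len(set(names)) == len(names)
        for sub in names:
            part = catalogue.subdimension_part(sub)
            assert part in catalogue.dimensions

    def test_unknown_dimension_lookup(self, catalogue):
        with pytest.raises(KeyError):
            catalogue.dimension("tail_shape")


class TestObjectSpec:
    def test_shorthand_sets_both_sides(self, catalogue):
        spec = ObjectSpec.from_features(catalogue, arm_angle="up", arm_length="long",
                                        arm_tip="pointy")
        assert spec["left_arm_angle"] == "up"
        assert spec["right_arm_angle"] == "up"

    def test_side_specific_overrides(self, catalogue):
        spec = ObjectSpec.from_features(
            catalogue, arm_length="regular", arm_tip="blunt",
            left_arm_angle="up", right_arm_angle="down")
        vec = dict(zip(catalogue.subdimension_names,
                       expand_subdimensions(spec, catalogue)))
        assert vec["left_arm_angle"] == "up"
        assert vec["right_arm_angle"] == "down"

    def test_absent_part_expands_to_none_everywhere(self, catalogue):
        spec = ObjectSpec.from_features(catalogue, arm="none")
        vec = dict(zip(catalogue.subdimension_names,
                       expand_subdimensions(spec, catalogue)))
        arm_subs = [s for s in catalogue.subdimension_names if "arm" in s]
        assert len(arm_subs) == 6
        assert all(vec[s] == "none" for s in arm_subs)

    def test_expansion_is_deterministic_in_the_mapping(self, catalogue, full_spec):
        clone = ObjectSpec(object_id="other", values=dict(full_spec.values))
        assert expand_subdimensions(full_spec, catalogue) == \
            expand_subdimensions(clone, catalogue)

    def test_expansion_length_and_order(self, catalogue, full_spec):
        vec = expand_subdimensions(full_spec, catalogue)
        assert len(vec) == 24

    def test_unknown_value_rejected(self, catalogue):
        with pytest.raises(SpecValidationError, match="body_shape"):
            ObjectSpec.from_features(catalogue, body_shape="dodecahedron")

    def test_none_forbidden_for_required_dimension(self, catalogue, full_spec):
        with pytest.raises(SpecValidationError):
            full_spec.replace(catalogue, body_shape="none")

    def test_partially_absent_part_rejected(self, catalogue, full_spec):
        with pytest.raises(SpecValidationError, match="partially absent"):
            full_spec.replace(catalogue, left_arm_angle="none")


class TestRandomSpec:
    def test_same_seed_identical(self, catalogue):
        a = random_spec(catalogue, seed=42)
        b = random_spec(catalogue, seed=42)
        assert a.values == b.values

    def test_body_only_when_optional_parts_inactive(self, catalogue):
        spec = random_spec(catalogue, seed=0, active_dims=set())
        for sub in catalogue.subdimension_names:
            dim = catalogue.subdimension_part(sub)
            if dim.optional_part:
                assert spec[sub] == "none"
            else:
                assert spec[sub] == dim.values[0]

    def test_unknown_active_dimension(self, catalogue):
        with pytest.raises(KeyError):
            random_spec(catalogue, seed=0, active_dims={"wings"})

    def test_body_pattern_draw_is_uniform(self, catalogue):
        counts = {}
        for i in range(10_000):
            spec = random_spec(catalogue, seed=1, index=i,
                               active_dims={"body_pattern"})
            counts[spec["body_pattern"]] = counts.get(spec["body_pattern"], 0) + 1
        freqs = np.array(list(counts.values())) / 10_000
        assert len(counts) == 5
        assert np.all(np.abs(freqs - 0.2) <= 0.02)

    def test_batch_streams_are_order_independent(self, catalogue):
        fifth = random_spec(catalogue, seed=9, index=5)
        again = random_spec(catalogue, seed=9, index=5)
        other = random_spec(catalogue, seed=9, index=6)
        assert fifth.values == again.values
        assert fifth.values != other.values


class TestObjectTable:
    def test_single_row_parses(self, catalogue):
        text = "object_id\tbody_shape\nq1\tcone\n"
        specs = parse_object_table(text, catalogue)
        assert len(specs) == 1
        assert specs[0]["body_shape"] == "cone"
        assert specs[0].object_id == "q1"

    def test_header_only_is_empty_list(self, catalogue):
        assert parse_object_table("object_id\tbody_shape\n", catalogue) == []

    def test_missing_optional_columns_become_none(self, catalogue):
        specs = parse_object_table("body_shape\ncube\n", catalogue)
        assert specs[0]["left_arm_angle"] == "none"
        assert specs[0]["beak_shape"] == "none"

    def test_comment_lines_ignored(self, catalogue):
        text = "# a comment\nbody_shape\n# another\ncone\n"
        assert parse_object_table(text, catalogue)[0]["body_shape"] == "cone"

    def test_unknown_value_names_dimension(self, catalogue):
        with pytest.raises(SpecValidationError, match="body_shape"):
            parse_object_table("body_shape\ndodecahedron\n", catalogue)

    def test_unknown_column_rejected(self, catalogue):
        with pytest.raises(TableParseError, match="wingspan"):
            parse_object_table("wingspan\n3\n", catalogue)

    def test_ragged_row_reports_row_number(self, catalogue):
        with pytest.raises(TableParseError, match="row 3"):
            parse_object_table("object_id\tbody_shape\na\tcone\nb\n", catalogue)

    def test_empty_spec_list_writes_header_only(self, catalogue):
        text = write_object_table([], catalogue)
        assert text.count("\n") == 1
        assert text.startswith("object_id\t")

    def test_round_trip_identity_random_specs(self, catalogue):
        specs = [random_spec(catalogue, seed=7, index=i, object_id=f"q{i}")
                 for i in range(100)]
        back = parse_object_table(write_object_table(specs, catalogue), catalogue)
        assert [(s.object_id, s.values) for s in back] == \
            [(s.object_id, s.values) for s in specs]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_round_trip_property(self, seed):
        catalogue = default_catalogue()
        spec = random_spec(catalogue, seed=seed, object_id="x")
        back, = parse_object_table(write_object_table([spec], catalogue), catalogue)
        assert back.values == spec.values

    def test_full_spec_round_trip(self, catalogue, full_spec):
        back, = parse_object_table(write_object_table([full_spec], catalogue), catalogue)
        assert back.values == full_spec.values
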