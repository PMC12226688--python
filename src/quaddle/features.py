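"""Feature vocabulary, object specifications, and the object-table text format.

A Quaddle object is described by ten user-facing feature dimensions: three
body-related primary dimensions (shape, color, pattern), three head-related
secondary dimensions, and four accessory parts (arm, ear, beak, fractal) that
may be absent.  For similarity scoring this vocabulary is expanded into 24
finer-grained *scored sub-dimensions*: accessory parts contribute one
sub-dimension per attribute and per side (left/right arm and ear), so that the
per-sub-dimension weights (2.0 / 1.5 / 0.75 / 0.25) sum to the documented
maximum similarity score of 11.75.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

NONE = "none"

#: groups a dimension can belong to
GROUPS = ("primary", "secondary", "minor")


@dataclass(frozen=True)
class DimensionSpec:
    """One user-facing feature dimension (or a resolved attribute of one).

    ``weight`` is the similarity weight of each scored sub-dimension this
    dimension contributes (score units).  Composite accessory dimensions
    (arm, ear, beak, fractal) carry ``attributes`` mapping attribute name to
    its value list; ``sided`` marks parts instantiated on both left and right.
    """

    name: str
    group: str
    weight: float
    values: tuple[str, ...] = ()
    attributes: tuple[tuple[str, tuple[str, ...]], ...] = ()
    sided: bool = False
    optional_part: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if not self.values and not self.attributes:
            raise ValueError(f"dimension {self.name!r} has no values")

    @property
    def is_composite(self) -> bool:
        return bool(self.attributes)

    def attribute_names(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.attributes)

    def attribute_values(self, attr: str) -> tuple[str, ...]:
        for a, vals in self.attributes:
            if a == attr:
                return vals
        raise KeyError(f"dimension {self.name!r} has no attribute {attr!r}")


def _hue_names() -> tuple[str, ...]:
    return tuple(f"hue{h:03d}" for h in range(0, 360, 30))


#: default color vocabulary: neutral gray plus 12 hues at 30 deg spacing
COLOR_VALUES = ("gray",) + _hue_names()
PATTERN_VALUES = ("solid", "horizontal", "diagonal", "vertical", "grid")
FRACTAL_IDS = tuple(f"f{i:02d}" for i in range(10))


@dataclass(frozen=True)
class FeatureCatalogue:
    """The dimension/value vocabulary plus the scored sub-dimension table."""

    dimensions: tuple[DimensionSpec, ...]
    version: str = "1.0"

    def __post_init__(self) -> None:
        names = [d.name for d in self.dimensions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate dimension names")
        sub = [n for n, _ in self.scored_subdimensions]
        if len(set(sub)) != len(sub):
            raise ValueError("duplicate sub-dimension names")

    @property
    def scored_subdimensions(self) -> tuple[tuple[str, float], ...]:
        """Ordered (name, weight) pairs over which similarity is scored."""
        out: list[tuple[str, float]] = []
        for dim in self.dimensions:
            if not dim.is_composite:
                out.append((dim.name, dim.weight))
            else:
                sides = ("left", "right") if dim.sided else (None,)
                for side in sides:
                    for attr, _ in dim.attributes:
                        name = f"{side}_{dim.name}_{attr}" if side else f"{dim.name}_{attr}"
                        out.append((name, dim.weight))
        return tuple(out)

    @property
    def subdimension_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.scored_subdimensions)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.scored_subdimensions], dtype=float)

    @property
    def max_score(self) -> float:
        return float(self.weights.sum())

    def dimension(self, name: str) -> DimensionSpec:
        """Resolve a dimension name or a composite attribute name.

        ``dimension("arm")`` returns the composite arm dimension;
        ``dimension("arm_angle")`` resolves to a view of its angle attribute.
        """
        for dim in self.dimensions:
            if dim.name == name:
                return dim
        for dim in self.dimensions:
            if dim.is_composite and name.startswith(dim.name + "_"):
                attr = name[len(dim.name) + 1:]
                if attr in dim.attribute_names():
                    return DimensionSpec(
                        name=name, group=dim.group, weight=dim.weight,
                        values=dim.attribute_values(attr),
                        optional_part=dim.optional_part,
                    )
        raise KeyError(f"unknown dimension {name!r}")

    def subdimension_values(self, subdim: str) -> tuple[str, ...]:
        """Legal categorical values of one scored sub-dimension."""
        dim, attr, _ = self._locate(subdim)
        if attr is None:
            return dim.values
        return dim.attribute_values(attr)

    def subdimension_part(self, subdim: str) -> DimensionSpec:
        """The user-facing dimension a scored sub-dimension belongs to."""
        return self._locate(subdim)[0]

    def _locate(self, subdim: str) -> tuple[DimensionSpec, str | None, str | None]:
        parts = subdim.split("_")
        side = parts[0] if parts[0] in ("left", "right") else None
        rest = "_".join(parts[1:]) if side else subdim
        for dim in self.dimensions:
            if not dim.is_composite:
                if side is None and dim.name == subdim:
                    return dim, None, None
                continue
            if rest.startswith(dim.name + "_"):
                attr = rest[len(dim.name) + 1:]
                if attr in dim.attribute_names():
                    return dim, attr, side
        raise KeyError(f"unknown sub-dimension {subdim!r}")


def default_catalogue() -> FeatureCatalogue:
    """The preconfigured catalogue: 10 dimensions, 24 scored sub-dimensions.

    Primary (body) weights 2.0 / 1.5 / 1.5, secondary (head) 0.75 each,
    accessory sub-dimensions 0.25 each; the weights sum to 11.75.
    """
    dims = (
        DimensionSpec("body_shape", "primary", 2.0,
                      ("sphere", "cube", "cone", "cylinder", "inverted_cone")),
        DimensionSpec("body_color", "primary", 1.5, COLOR_VALUES),
        DimensionSpec("body_pattern", "primary", 1.5, PATTERN_VALUES),
        DimensionSpec("head_shape", "secondary", 0.75, ("sphere", "cube", "cone")),
        DimensionSpec("head_color", "secondary", 0.75, COLOR_VALUES),
        DimensionSpec("head_pattern", "secondary", 0.75, PATTERN_VALUES),
        DimensionSpec(
            "arm", "minor", 0.25, sided=True, optional_part=True,
            attributes=(
                ("angle", ("up", "down", "straight")),
                ("length", ("regular", "long", "short")),
                ("tip", ("pointy", "blunt", "flat")),
            ),
        ),
        DimensionSpec(
            "ear", "minor", 0.25, sided=True, optional_part=True,
            attributes=(
                ("shape", ("straight", "pointy", "blunt")),
                ("length", ("regular", "long", "short")),
                ("angle", ("up", "down", "straight")),
            ),
        ),
        DimensionSpec(
            "beak", "minor", 0.25, optional_part=True,
            attributes=(
                ("shape", ("pointy", "blunt")),
                ("length", ("regular", "long", "short")),
                ("angle", ("up", "down", "straight")),
            ),
        ),
        DimensionSpec(
            "fractal", "minor", 0.25, optional_part=True,
            attributes=(
                ("identity", FRACTAL_IDS),
                ("size", ("small", "regular", "large")),
                ("position", ("center", "upper", "lower")),
            ),
        ),
    )
    return FeatureCatalogue(dimensions=dims)


class SpecValidationError(ValueError):
    """An object specification violates the catalogue vocabulary."""


class TableParseError(ValueError):
    """An object table is malformed."""


@dataclass(frozen=True)
class ObjectSpec:
    """One object as a mapping of scored sub-dimension to value.

    Values are categorical identifiers from the catalogue, or the sentinel
    ``"none"`` for every sub-dimension of an absent optional part.  Use
    :meth:`from_features` to build specs from user-facing shorthand
    (``arm_angle="up"`` sets both sides; ``arm="none"`` removes the part).
    """

    object_id: str
    values: Mapping[str, str] = field(default_factory=dict)

    @staticmethod
    def from_features(catalogue: FeatureCatalogue, object_id: str = "",
                      **features: str) -> "ObjectSpec":
        values: dict[str, str] = {}
        subnames = catalogue.subdimension_names
        # part-level presence flags, e.g. arm="none"
        part_absent: dict[str, bool] = {}
        for dim in catalogue.dimensions:
            if dim.is_composite and dim.name in features:
                if features[dim.name] != NONE:
                    raise SpecValidationError(
                        f"dimension {dim.name!r}: set attributes such as "
                        f"'{dim.name}_{dim.attribute_names()[0]}', or 'none' to omit the part")
                part_absent[dim.name] = True
                features.pop(dim.name)
        for sub in subnames:
            dim, attr, side = catalogue._locate(sub)
            if part_absent.get(dim.name):
                values[sub] = NONE
            elif sub in features:
                values[sub] = features[sub]
            elif attr is not None and f"{dim.name}_{attr}" in features:
                values[sub] = features[f"{dim.name}_{attr}"]
            elif dim.optional_part:
                values[sub] = NONE
            else:
                values[sub] = dim.values[0]
        known = set(subnames)
        for dim in catalogue.dimensions:
            if dim.is_composite:
                known.update(f"{dim.name}_{a}" for a in dim.attribute_names())
                known.add(dim.name)
        unknown = set(features) - known
        if unknown:
            raise SpecValidationError(f"unknown feature(s): {sorted(unknown)}")
        spec = ObjectSpec(object_id=object_id, values=values)
        validate_spec(spec, catalogue)
        return spec

    def replace(self, catalogue: FeatureCatalogue, **subvalues: str) -> "ObjectSpec":
        """A copy with the given scored sub-dimensions replaced."""
        values = dict(self.values)
        for k, v in subvalues.items():
            if k not in values:
                raise SpecValidationError(f"unknown sub-dimension {k!r}")
            values[k] = v
        spec = ObjectSpec(object_id=self.object_id, values=values)
        validate_spec(spec, catalogue)
        return spec

    def __getitem__(self, key: str) -> str:
        return self.values[key]


def full_default_spec(catalogue: FeatureCatalogue, object_id: str = "") -> ObjectSpec:
    """A complete object: every part present at its first catalogue value."""
    values = {}
    for sub in catalogue.subdimension_names:
        values[sub] = catalogue.subdimension_values(sub)[0]
    spec = ObjectSpec(object_id=object_id, values=values)
    validate_spec(spec, catalogue)
    return spec


def validate_spec(spec: ObjectSpec, catalogue: FeatureCatalogue) -> None:
    """Check a spec against the catalogue vocabulary and part consistency."""
    subnames = catalogue.subdimension_names
    missing = set(subnames) - set(spec.values)
    if missing:
        raise SpecValidationError(f"missing sub-dimension(s): {sorted(missing)}")
    extra = set(spec.values) - set(subnames)
    if extra:
        raise SpecValidationError(f"unknown sub-dimension(s): {sorted(extra)}")
    for sub in subnames:
        v = spec.values[sub]
        dim, _, _ = catalogue._locate(sub)
        if v == NONE:
            if not dim.optional_part:
                raise SpecValidationError(
                    f"dimension {dim.name!r}: 'none' only allowed for optional parts")
            continue
        legal = catalogue.subdimension_values(sub)
        if v not in legal:
            raise SpecValidationError(
                f"dimension {dim.name!r}: unknown value {v!r} for {sub!r}")
    # a sided part must be consistently present or absent per side
    for dim in catalogue.dimensions:
        if not (dim.is_composite and dim.optional_part):
            continue
        sides = ("left", "right") if dim.sided else (None,)
        for side in sides:
            prefix = f"{side}_{dim.name}_" if side else f"{dim.name}_"
            states = {spec.values[s] == NONE
                      for s in subnames if s.startswith(prefix)}
            if len(states) > 1:
                raise SpecValidationError(
                    f"part {dim.name!r} ({side or 'single'}) is partially absent")


def expand_subdimensions(spec: ObjectSpec, catalogue: FeatureCatalogue) -> tuple[str, ...]:
    """The spec's values as an ordered vector over the scored sub-dimensions."""
    validate_spec(spec, catalogue)
    return tuple(spec.values[s] for s in catalogue.subdimension_names)


def _rng_for(seed: int, index: int | None = None) -> np.random.Generator:
    """Per-object random stream derived from (master seed, object index)."""
    entropy = (int(seed),) if index is None else (int(seed), int(index))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def random_spec(catalogue: FeatureCatalogue, seed: int,
                active_dims: Iterable[str] | None = None,
                index: int | None = None, object_id: str = "") -> ObjectSpec:
    """Uniform independent draw per active dimension.

    ``active_dims`` are user-facing dimension names; inactive optional parts
    are set to "none", inactive required dimensions to their default (first)
    value.  Deterministic in (catalogue, seed, active_dims, index); ``index``
    selects an order-independent per-object stream within a batch.
    """
    if active_dims is None:
        active = {d.name for d in catalogue.dimensions}
    else:
        active = set(active_dims)
        known = {d.name for d in catalogue.dimensions}
        bad = active - known
        if bad:
            raise KeyError(f"unknown dimension(s): {sorted(bad)}")
    rng = _rng_for(seed, index)
    values: dict[str, str] = {}
    for sub in catalogue.subdimension_names:
        dim, _, _ = catalogue._locate(sub)
        legal = catalogue.subdimension_values(sub)
        if dim.name in active:
            values[sub] = legal[int(rng.integers(len(legal)))]
        elif dim.optional_part:
            values[sub] = NONE
        else:
            values[sub] = legal[0]
    spec = ObjectSpec(object_id=object_id, values=values)
    validate_spec(spec, catalogue)
    return spec


# ---------------------------------------------------------------------------
# Object-table TSV dialect: UTF-8, header row, "#" comment lines, "none"
# sentinel for absent parts.  Columns are object_id plus the 24 scored
# sub-dimensions; parsing also accepts shorthand attribute columns
# (e.g. "arm_angle" applies to both sides) and fills absent columns with
# defaults ("none" for optional parts).
# ---------------------------------------------------------------------------

def parse_object_table(text: str, catalogue: FeatureCatalogue | None = None
                       ) -> list[ObjectSpec]:
    """Parse a TSV object table into validated specs."""
    catalogue = catalogue or default_catalogue()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise TableParseError("empty table: missing header row")
    reader = csv.reader(io.StringIO("\n".join(lines)), delimiter="\t")
    rows = list(reader)
    header = [h.strip() for h in rows[0]]
    subnames = set(catalogue.subdimension_names)
    shorthand = set()
    for dim in catalogue.dimensions:
        if dim.is_composite:
            shorthand.update(f"{dim.name}_{a}" for a in dim.attribute_names())
            shorthand.add(dim.name)
        else:
            shorthand.add(dim.name)
    known = subnames | shorthand | {"object_id"}
    unknown = [h for h in header if h not in known]
    if unknown:
        raise TableParseError(f"unknown column(s): {unknown}")
    specs = []
    for rownum, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise TableParseError(
                f"row {rownum}: expected {len(header)} cells, got {len(row)}")
        cells = dict(zip(header, (c.strip() for c in row)))
        object_id = cells.pop("object_id", "")
        features = {k: v for k, v in cells.items() if v != ""}
        try:
            specs.append(ObjectSpec.from_features(catalogue, object_id, **features))
        except SpecValidationError as exc:
            raise SpecValidationError(f"row {rownum}: {exc}") from exc
    return specs


def write_object_table(specs: Sequence[ObjectSpec],
                       catalogue: FeatureCatalogue | None = None) -> str:
    """Serialize specs as TSV; ``parse_object_table`` round-trips bit-exactly."""
    catalogue = catalogue or default_catalogue()
    subnames = catalogue.subdimension_names
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(("object_id",) + subnames)
    for spec in specs:
        validate_spec(spec, catalogue)
        writer.writerow((spec.object_id,) + tuple(spec.values[s] for s in subnames))
    return out.getvalue()
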