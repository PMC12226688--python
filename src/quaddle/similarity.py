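"""Weighted binary-match similarity and similarity-constrained set sampling.

Two objects ``Q1``, ``Q2`` are compared over the catalogue's scored
sub-dimensions.  A binary match vector ``B`` holds ``b_i = 1`` iff the two
values in sub-dimension ``i`` are equal (the "none" sentinel matches itself),
and the similarity score is the weighted sum ``S = W^T B``.  Under the default
weight table S ranges from 0 (no shared feature) to 11.75 (identical objects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import (
    NONE,
    FeatureCatalogue,
    ObjectSpec,
    default_catalogue,
    expand_subdimensions,
    random_spec,
    _rng_for,
)

#: candidate mutations per object before declaring a constraint infeasible
ITERATION_CAP = 10_000


class InfeasibleConstraintError(RuntimeError):
    """A similarity constraint could not be satisfied within the iteration cap."""


@dataclass(frozen=True)
class WeightTable:
    """Per-sub-dimension weights aligned with the catalogue order."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    @staticmethod
    def default(catalogue: FeatureCatalogue | None = None) -> "WeightTable":
        catalogue = catalogue or default_catalogue()
        return WeightTable(catalogue.weights)


def match_vector(a: ObjectSpec, b: ObjectSpec,
                 catalogue: FeatureCatalogue | None = None) -> np.ndarray:
    """Binary vector b_i = 1 iff the expanded values agree in sub-dimension i.

    "none" == "none" counts as a match (a part absent from both objects);
    a part absent from only one object mismatches in all its sub-dimensions.
    """
    catalogue = catalogue or default_catalogue()
    va = expand_subdimensions(a, catalogue)
    vb = expand_subdimensions(b, catalogue)
    return np.array([1 if x == y else 0 for x, y in zip(va, vb)], dtype=int)


def similarity_score(a: ObjectSpec, b: ObjectSpec,
                     weights: WeightTable | None = None,
                     catalogue: FeatureCatalogue | None = None) -> float:
    """S = sum_i w_i b_i; symmetric, bounded by [0, sum(w)]."""
    catalogue = catalogue or default_catalogue()
    weights = weights or WeightTable.default(catalogue)
    bits = match_vector(a, b, catalogue)
    if len(weights.weights) != len(bits):
        raise ValueError("weight table does not align with the catalogue")
    return float(np.dot(weights.weights, bits))


def normalized_score(a: ObjectSpec, b: ObjectSpec,
                     weights: WeightTable | None = None,
                     catalogue: FeatureCatalogue | None = None) -> float:
    """S divided by the maximum attainable score, in [0, 1]."""
    catalogue = catalogue or default_catalogue()
    weights = weights or WeightTable.default(catalogue)
    if weights.total == 0:
        raise ValueError("all-zero weight table cannot be normalized")
    return similarity_score(a, b, weights, catalogue) / weights.total


def pairwise_matrix(specs: list[ObjectSpec],
                    weights: WeightTable | None = None,
                    catalogue: FeatureCatalogue | None = None) -> np.ndarray:
    """Symmetric matrix of pairwise similarity scores."""
    if not specs:
        raise ValueError("need at least one spec")
    catalogue = catalogue or default_catalogue()
    weights = weights or WeightTable.default(catalogue)
    n = len(specs)
    vecs = [expand_subdimensions(s, catalogue) for s in specs]
    w = weights.weights
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            bits = np.array([x == y for x, y in zip(vecs[i], vecs[j])])
            m[i, j] = m[j, i] = float(w[bits].sum())
    return m


def _off_diagonal(m: np.ndarray) -> np.ndarray:
    return m[~np.eye(len(m), dtype=bool)]


def _mutate_subdim(spec: ObjectSpec, catalogue: FeatureCatalogue, sub: str,
                   rng: np.random.Generator, avoid: str | None = None) -> ObjectSpec:
    """Replace one sub-dimension with a different random legal value."""
    legal = [v for v in catalogue.subdimension_values(sub)
             if v != spec.values[sub] and v != avoid]
    if not legal:
        return spec
    return spec.replace(catalogue, **{sub: legal[int(rng.integers(len(legal)))]})


def _minor_subdims(catalogue: FeatureCatalogue) -> list[str]:
    return [s for s, _ in catalogue.scored_subdimensions
            if catalogue.subdimension_part(s).group == "minor"]


def generate_set(n: int, constraint: dict, catalogue: FeatureCatalogue | None = None,
                 seed: int = 0, weights: WeightTable | None = None) -> list[ObjectSpec]:
    """Sample ``n`` objects whose pairwise scores satisfy the constraint.

    ``constraint`` is ``{"min_pairwise": s}`` (high-similarity mode: clone a
    seed object and perturb only low-weight sub-dimensions within a per-object
    budget of ``(S_max - s) / 2`` so every pair stays at or above ``s``) or
    ``{"max_pairwise": s}`` (low-similarity mode: rejection sampling that
    re-draws the sub-dimension contributing most to a violating pair).
    Deterministic given ``seed``; raises :class:`InfeasibleConstraintError`
    after the iteration cap instead of returning a near-miss.
    """
    catalogue = catalogue or default_catalogue()
    weights = weights or WeightTable.default(catalogue)
    if n < 1:
        raise ValueError("n must be >= 1")
    if set(constraint) == {"min_pairwise"}:
        mode, bound = "min", float(constraint["min_pairwise"])
    elif set(constraint) == {"max_pairwise"}:
        mode, bound = "max", float(constraint["max_pairwise"])
    else:
        raise ValueError("constraint must be {'min_pairwise': s} or {'max_pairwise': s}")

    if n == 1:
        return [random_spec(catalogue, seed, index=0, object_id="obj000")]

    if mode == "min":
        specs = _generate_similar(n, bound, catalogue, seed, weights)
    else:
        specs = _generate_dissimilar(n, bound, catalogue, seed, weights)

    m = pairwise_matrix(specs, weights, catalogue)
    off = _off_diagonal(m)
    ok = off.min() >= bound if mode == "min" else off.max() <= bound
    if not ok:  # pragma: no cover - construction guarantees the bound
        raise InfeasibleConstraintError("constraint violated after construction")
    return specs


def _generate_similar(n: int, bound: float, catalogue: FeatureCatalogue,
                      seed: int, weights: WeightTable) -> list[ObjectSpec]:
    smax = weights.total
    budget = (smax - bound) / 2.0
    if budget < 0:
        raise InfeasibleConstraintError(
            f"min_pairwise={bound} exceeds the maximum score {smax}")
    base = random_spec(catalogue, seed, index=0, object_id="obj000")
    subnames = list(catalogue.subdimension_names)
    w = dict(catalogue.scored_subdimensions)
    specs = [base]
    for i in range(1, n):
        rng = _rng_for(seed, i)
        for _ in range(ITERATION_CAP):
            # perturb lowest-weight sub-dimensions first, within the budget
            cand = base
            spend = 0.0
            order = list(subnames)
            rng.shuffle(order)
            order.sort(key=lambda s: w[s])  # stable: random within weight tier
            k = int(rng.integers(1, len(order) + 1))
            for sub in order[:k]:
                if spend + w[sub] > budget:
                    break
                mutated = _mutate_subdim(cand, catalogue, sub, rng)
                if mutated is not cand:
                    cand = mutated
                    spend += w[sub]
            if all(similarity_score(cand, s, weights, catalogue) >= bound for s in specs) \
                    and all(cand.values != s.values for s in specs):
                specs.append(ObjectSpec(object_id=f"obj{i:03d}", values=cand.values))
                break
        else:
            raise InfeasibleConstraintError(
                f"could not place object {i} with min_pairwise={bound} "
                f"after {ITERATION_CAP} attempts")
    return specs


def _generate_dissimilar(n: int, bound: float, catalogue: FeatureCatalogue,
                         seed: int, weights: WeightTable) -> list[ObjectSpec]:
    w = dict(catalogue.scored_subdimensions)
    specs: list[ObjectSpec] = []
    for i in range(n):
        rng = _rng_for(seed, i)
        cand = random_spec(catalogue, seed, index=i, object_id=f"obj{i:03d}")
        for _ in range(ITERATION_CAP):
            violating = [s for s in specs
                         if similarity_score(cand, s, weights, catalogue) > bound]
            if not violating:
                break
            # re-draw a sub-dimension of the worst pair, preferring the ones
            # contributing most (weight-proportional draw avoids deadlocks
            # when a heavy dimension's few values are all taken)
            other = max(violating,
                        key=lambda s: similarity_score(cand, s, weights, catalogue))
            matches = [sub for sub in catalogue.subdimension_names
                       if cand.values[sub] == other.values[sub] and w[sub] > 0]
            probs = np.array([w[s] for s in matches])
            sub = matches[int(rng.choice(len(matches), p=probs / probs.sum()))]
            if cand.values[sub] == NONE:
                # both parts absent: add the part on the candidate side
                part = catalogue.subdimension_part(sub)
                prefix = sub.rsplit("_", 1)[0]
                updates = {}
                for s2 in catalogue.subdimension_names:
                    if s2.startswith(prefix + "_") or s2 == sub:
                        if catalogue.subdimension_part(s2) is part or \
                                catalogue.subdimension_part(s2).name == part.name:
                            legal = catalogue.subdimension_values(s2)
                            updates[s2] = legal[int(rng.integers(len(legal)))]
                cand = cand.replace(catalogue, **updates)
            else:
                cand = _mutate_subdim(cand, catalogue, sub, rng,
                                      avoid=other.values[sub])
        else:
            raise InfeasibleConstraintError(
                f"could not place object {i} with max_pairwise={bound} "
                f"after {ITERATION_CAP} attempts")
        specs.append(cand)
    return specs


@dataclass(frozen=True)
class SequenceDesign:
    """Five sequence objects plus one distractor tied to a target position."""

    sequence: list[ObjectSpec]
    distractor: ObjectSpec
    distractor_target: int  # 1-based serial position (2 or 4)
    scores_to_distractor: np.ndarray = field(repr=False, default=None)

    @property
    def all_objects(self) -> list[ObjectSpec]:
        return self.sequence + [self.distractor]


def design_sequence_stimuli(catalogue: FeatureCatalogue | None = None,
                            seed: int = 0, distractor_target: int = 2,
                            max_pairwise: float = 3.0,
                            weights: WeightTable | None = None) -> SequenceDesign:
    """Design a 6-object sequence-learning stimulus set.

    Five mutually dissimilar objects (pairwise score <= ``max_pairwise``) form
    the sequence; a sixth distractor shares features with the object at serial
    position ``distractor_target`` (2 or 4) so that its similarity to that
    object strictly exceeds its similarity to every other sequence object.
    """
    if distractor_target not in (2, 4):
        raise ValueError("distractor_target must be 2 or 4")
    catalogue = catalogue or default_catalogue()
    weights = weights or WeightTable.default(catalogue)
    sequence = generate_set(5, {"max_pairwise": max_pairwise}, catalogue, seed, weights)
    target = sequence[distractor_target - 1]
    rng = _rng_for(seed, 1_000_003)
    minor = _minor_subdims(catalogue)
    for _ in range(ITERATION_CAP):
        # clone the target, then perturb minor sub-dimensions to sit between
        # "identical" and the dissimilarity floor of the rest of the set
        cand = target
        k = int(rng.integers(6, len(minor) + 1))
        order = list(minor)
        rng.shuffle(order)
        for sub in order[:k]:
            cand = _mutate_subdim(cand, catalogue, sub, rng)
        s_target = similarity_score(cand, target, weights, catalogue)
        others = [similarity_score(cand, s, weights, catalogue)
                  for i, s in enumerate(sequence) if i != distractor_target - 1]
        if s_target > max(others) and cand.values != target.values:
            distractor = ObjectSpec(object_id="distractor", values=cand.values)
            scores = np.array([similarity_score(distractor, s, weights, catalogue)
                               for s in sequence])
            return SequenceDesign(sequence=sequence, distractor=distractor,
                                  distractor_target=distractor_target,
                                  scores_to_distractor=scores)
    raise InfeasibleConstraintError(
        "could not design a distractor for the requested position")
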