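"""Score object pairs with the weighted feature-overlap similarity score.

Builds a complete reference object, then probes how the score responds when
objects share all, none, or exactly one scored sub-dimension.
"""

import quaddle as q

catalogue = q.default_catalogue()
full = q.full_default_spec(catalogue, "reference")
twin = q.ObjectSpec(object_id="twin", values=dict(full.values))

print(f"maximum score (identical objects): {q.similarity_score(full, twin):.2f}")

# flip every sub-dimension to a different value -> nothing shared
other = {sub: next(v for v in catalogue.subdimension_values(sub)
                   if v != full.values[sub])
         for sub in catalogue.subdimension_names}
disjoint = q.ObjectSpec(object_id="disjoint", values=other)
print(f"minimum score (nothing shared):    {q.similarity_score(full, disjoint):.2f}")

for sub in ("body_shape", "body_color", "head_shape", "beak_shape"):
    probe = q.ObjectSpec(object_id=sub, values={**other, sub: full.values[sub]})
    s = q.similarity_score(full, probe)
    print(f"sharing only {sub:<12s} scores {s:.2f} (that dimension's weight)")

norm = q.normalized_score(full, disjoint)
print(f"normalized score of the disjoint pair: {norm:.3f} (fraction of the 11.75 max)")
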