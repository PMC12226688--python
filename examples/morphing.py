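"""Morph gradually between two objects by interpolating continuous parameters.

A cone-bodied object with downward arms transitions to an inverted-cone body
with upward arms; at the midpoint the body profile passes through a cylinder.
"""

import quaddle as q

catalogue = q.default_catalogue()
a = q.full_default_spec(catalogue).replace(
    catalogue, body_shape="cone", left_arm_angle="down", right_arm_angle="down")
b = a.replace(catalogue, body_shape="inverted_cone",
              left_arm_angle="up", right_arm_angle="up")

print("t     r_bottom  r_top   arm_angle(deg)")
for t in (0.0, 0.25, 0.5, 0.75, 1.0):
    p = q.morph(a, b, t, catalogue)
    c = p.continuous
    print(f"{t:<5.2f} {c['body_r_bottom']:.3f}    {c['body_r_top']:.3f}  "
          f"{c['left_arm_angle_deg']:+.1f}")

mid = q.morph(a, b, 0.5, catalogue)
mesh = q.build_from_params(mid)
print(f"\nmidpoint body profile is a cylinder "
      f"(r_bottom == r_top == {mid.continuous['body_r_bottom']:.3f}); "
      f"realized mesh has {mesh.n_faces} triangles")
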