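"""Generate surface patterns, paired colors, and a point-symmetric fractal.

Writes PNGs under scratch/ and prints the color coordinates and symmetry
checks that characterize the texture design.
"""

from pathlib import Path

import numpy as np

import quaddle as q

out = Path("scratch/textures")
out.mkdir(parents=True, exist_ok=True)

base, partner = q.hue_pair(q.ColorLCh(60, 40, 120))
print(f"paired colors: hue {base.h:.0f} and {partner.h:.0f} deg "
      f"(delta 30, same L*={base.L:.0f}, c*={base.c:.0f})")
print(f"as sRGB: {q.lch_to_srgb(base)} and {q.lch_to_srgb(partner)}")

for kind in ("solid", "horizontal", "diagonal", "vertical", "grid"):
    img = q.make_pattern(kind, base)
    img.save(out / f"pattern_{kind}.png")
print(f"wrote 5 patterns, each {img.width}x{img.height} px with 150-px bands")

fractal = q.make_fractal(seed=3)
fractal.save(out / "fractal_seed3.png")
symmetric = np.array_equal(fractal.pixels, fractal.pixels[::-1, ::-1])
print(f"fractal is 180-degree rotation invariant: {symmetric}")

body = q.composite_body_texture(q.make_pattern("diagonal", base), fractal)
body.save(out / "body_composite.png")
print(f"composited body texture written to {out}/body_composite.png")
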