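"""Sample object sets under pairwise similarity constraints.

High-similarity sets (every pairwise score >= 8) make objects hard to tell
apart; low-similarity sets (<= 3) make them easy to distinguish.  The
pairwise matrix is recomputed independently to verify the constraint.
"""

import numpy as np

import quaddle as q

catalogue = q.default_catalogue()

similar = q.generate_set(6, {"min_pairwise": 8}, catalogue, seed=2)
m = q.pairwise_matrix(similar)
off = m[~np.eye(6, dtype=bool)]
print(f"high-similarity set: min pairwise score {off.min():.2f}, "
      f"max {off.max():.2f} (constraint: >= 8)")

dissimilar = q.generate_set(6, {"max_pairwise": 3}, catalogue, seed=11)
m = q.pairwise_matrix(dissimilar)
off = m[~np.eye(6, dtype=bool)]
print(f"low-similarity set:  max pairwise score {off.max():.2f}, "
      f"min {off.min():.2f} (constraint: <= 3)")

print("\nlow-similarity set as an object table:")
print(q.write_object_table(dissimilar, catalogue))
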