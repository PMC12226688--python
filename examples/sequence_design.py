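"""Design sequence-learning stimuli: five objects plus a matched distractor.

The five sequence objects are mutually dissimilar (pairwise score <= 3); the
distractor shares features with the object at serial position 2 (or 4), so it
is confusable specifically with that object.
"""

import numpy as np

import quaddle as q

catalogue = q.default_catalogue()
design = q.design_sequence_stimuli(catalogue, seed=0, distractor_target=2)

print("similarity of the distractor to each sequence position:")
for pos, score in enumerate(design.scores_to_distractor, start=1):
    marker = "  <- designated target" if pos == design.distractor_target else ""
    print(f"  position {pos}: {score:5.2f}{marker}")

margin = design.scores_to_distractor[design.distractor_target - 1] - \
    np.delete(design.scores_to_distractor, design.distractor_target - 1).max()
print(f"margin over the best non-target: {margin:.2f} "
      "(positive: the distractor resembles only the designated object)")
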