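"""Relate the feature-similarity score to image similarity of rendered views.

Draws random objects, renders front-view previews, and regresses the SSIM of
image pairs on their normalized feature-similarity score.  The weighted
feature overlap is expected to correlate positively — but only moderately —
with pixel-level similarity.
"""

import numpy as np

import quaddle as q

result = q.similarity_vs_ssim_study(n_objects=30, n_pairs=150, seed=5)
corr = np.corrcoef(result.scores, result.metric)[0, 1]
fit = result.fit

print(f"pairs analysed: {len(result.pairs)}")
print(f"mean normalized score: {result.scores.mean():.3f}  "
      f"mean SSIM: {result.metric.mean():.3f}")
print(f"regression: SSIM = {fit.slope:.3f} x score + {fit.intercept:.3f}, "
      f"r^2 = {fit.r_squared:.3f}")
print(f"Pearson correlation: {corr:.3f} "
      "(positive: shared features -> more similar images)")
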