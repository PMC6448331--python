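"""Distance-matrix weighting of patch scores.

Patches whose feature vectors sit close to the rest of the image's
patches get larger weights: weight_k is proportional to the reciprocal
of patch k's mean Euclidean distance to all patches. An outlier patch
(e.g. one that mostly shows background) is down-weighted, unlike in a
plain mean of scores.
"""

import numpy as np

from lymphopatch import dmw_image_score, dmw_weights, mean_score

# three colinear feature vectors at 0, 1 and 3: the middle one is the
# most central, the far one the least
feats = np.array([[0.0], [1.0], [3.0]])
w = dmw_weights(feats)
print("colinear features at 0, 1, 3 -> weights", np.round(w, 4))
print("exact fractions: 15/47, 20/47, 12/47")

# an image with 4 consistent patches and 1 outlier
rng = np.random.default_rng(0)
feats = np.vstack([rng.normal(0, 0.1, (4, 5)), [[8.0] * 5]])
scores = np.vstack([np.tile([0.8, 0.1, 0.1], (4, 1)), [[0.0, 0.0, 1.0]]])
w = dmw_weights(feats)
print("\noutlier weight:", round(w[-1], 4), "vs consistent patches ~", round(w[0], 4))
print("mean score:     ", np.round(mean_score(scores), 3))
print("DMW image score:", np.round(dmw_image_score(scores, w), 3))
print("DMW suppresses the outlier patch's vote; the mean does not.")
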