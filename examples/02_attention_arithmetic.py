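"""The affinity-attention arithmetic on a tiny hand-checkable instance.

Q and K are projected pixel features (columns = pixels).  The affinity
W = Q^T K scores every pixel pair; a row-softmax turns each row into
attention weights; the weighted feature mixes value features of all
pixels into each output pixel.
"""

import numpy as np

from isletseg.model import affinity, normalize_affinity, weighted_feature

q = k = np.array([[1.0, 2.0]])        # one channel, two pixels
w = affinity(q, k)
a = normalize_affinity(w)
v = np.array([[10.0, 20.0]])
h = weighted_feature(a, v)

print("affinity W = Q^T K:\n", w)
print("row-softmax A (rows sum to 1):\n", a.round(4))
print("weighted feature H' (each pixel a convex mix of values):\n",
      h.round(3))
# Pixel 2 has the stronger self-affinity (4), so its output leans
# further toward its own value feature.
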