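"""Nonlocal-regularized fuzzy c-means on a noisy two-region image.

Builds a 24x24 image with true intensities 50 and 200 plus Gaussian noise
(sigma 5), clusters it with c = 2, and prints the recovered centers, the
monotone objective trace, and the label accuracy.
"""

import numpy as np

from btseg import nlfcm

rng = np.random.default_rng(0)
img = np.full((24, 24), 50.0)
img[:, 12:] = 200.0
truth = img >= 200
img = np.clip(np.rint(img + rng.normal(0, 5, img.shape)), 0, 255).astype(int)

state, labels = nlfcm.segment(img, nlfcm.FCMConfig(c=2, seed=0))
v = np.sort(state.v)
print(f"recovered centers: {v[0]:.2f}, {v[1]:.2f}  (true: 50, 200)")
print(f"converged after {state.n_iter} iterations")
print("objective trace (first 5):",
      [f"{j:.1f}" for j in state.objective_trace[:5]])
bright = int(np.argmax(state.v))
acc = float(np.mean((labels == bright) == truth))
print(f"pixel label accuracy vs truth: {acc:.4f}")
# Centers land within a fraction of a gray level of the true intensities and
# the objective decreases monotonically, as the alternating updates guarantee.
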