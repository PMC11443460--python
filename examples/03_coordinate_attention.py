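"""Run the Coordinate Attention block forward pass on a toy feature map.

With all transform weights zero both attention maps are logistic(0) = 0.5
everywhere, so the output is exactly 0.25x the input — a useful sanity
anchor.  With random weights the attention maps stay in [0, 1] and gate
the input elementwise.
"""

import numpy as np

from germkit.ca_attention import CAWeights, coordinate_attention

x = np.random.default_rng(0).normal(size=(8, 6, 10))  # (C, H, W)

out = coordinate_attention(x, CAWeights.zeros(channels=8, r=4))
print("zero weights: max |out - 0.25 x| =", np.abs(out - 0.25 * x).max())

w = CAWeights.random(channels=8, r=4, seed=1, scale=0.5)
out, a_h, a_w = coordinate_attention(x, w, return_maps=True)
print(f"random weights: output shape {out.shape} (equals input)")
print(f"a_h in [{a_h.min():.3f}, {a_h.max():.3f}] per (channel, row)")
print(f"a_w in [{a_w.min():.3f}, {a_w.max():.3f}] per (channel, column)")
print("gating bound |out| <= |x| holds:", bool(np.all(np.abs(out) <= np.abs(x) + 1e-12)))
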