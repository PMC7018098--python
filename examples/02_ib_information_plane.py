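"""Trace the Information Bottleneck trade-off for the oddball observer.

For a memory window of N = 11 trials, solves the IB fixed-point
equations along an ascending beta ladder and prints the information
plane: compression I(X;M) against predictive information I(M;Y).
Low beta = strong compression (few bits kept about the count), high
beta approaches the lossless limit log2(N+1).
"""

import numpy as np

from ibsurprise import build_joint, effective_capacity_noc, ib_info_curve, mutual_information

N = 11
joint = build_joint(N)
print(f"joint over count x in 0..{N} and next tone y; I(X;Y) = "
      f"{mutual_information(joint.p_xy):.4f} bits")

betas = np.geomspace(0.5, 100, 10)
print("\n  beta    I(X;M) bits   I(M;Y) bits")
for sol in ib_info_curve(joint, betas, seed=0):
    print(f"{sol.beta:7.2f}   {sol.I_xm:10.4f}   {sol.I_my:10.4f}")

print(f"\nlossless count memory would need log2(N+1) = "
      f"{effective_capacity_noc(N):.2f} bits")
print("I(X;M) is the observer's effective memory capacity: the bits of the")
print("recent-count representation actually kept; I(M;Y) is how much of that")
print("helps predict the next tone (bounded by I(X;Y)).")
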