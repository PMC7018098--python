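"""Build an oddball sequence and compute its count-based predictors.

Draws a 5-block session (oddball probabilities 0.1-0.5, 240 trials per
block), then prints the first valid trials of each predictor: the
oddball count in the last N trials, the opposite-tone (NOC) predictor,
the running probability n/N, and the distance-from-last-oddball
baseline.
"""

import numpy as np

from ibsurprise import (
    distance_from_last_oddball,
    generate_sequence,
    noc_predictor,
    oddball_count,
    running_probability,
)

N = 11
seq = generate_sequence([0.1, 0.2, 0.3, 0.4, 0.5], 240, seed=1)
counts = oddball_count(seq, N)
noc = noc_predictor(seq, N)
rp = running_probability(seq, N)
dist = distance_from_last_oddball(seq)

print(f"{seq.n_trials} trials in {seq.n_blocks} blocks; "
      f"{seq.tones.sum()} oddballs overall")
first = np.flatnonzero(counts.valid)[:8]
print("trial  tone  count  noc  run_prob")
for t in first:
    print(f"{t:5d}  {seq.tones[t]:4d}  {counts.values[t]:5.0f}"
          f"  {noc.values[t]:3.0f}  {rp.values[t]:8.3f}")
odd = np.flatnonzero(dist.valid)[:5]
print("first oddball distances (trials since previous oddball):",
      dist.values[odd].astype(int).tolist())
print("\nThe NOC predictor counts opposite tones in the last N trials: a high")
print("value means the current tone is rare in recent memory, so the P300")
print("response to it is modeled as large.")
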