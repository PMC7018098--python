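"""Fit both surprise models to one synthetic subject at the study regime.

The subject is an Information Bottleneck observer (N = 11,
beta = 48.33) whose P300 AUC is linear in the IB surprise
(0.93 uV*s/bit) with noise calibrated so the single-trial weighted R^2
is about 0.23.  The grid search recovers the memory parameters; the
within-block max-statistic permutation test gives the significance.
"""

import warnings
from dataclasses import replace

import numpy as np

# a few near-critical grid points converge slowly and are flagged;
# the cache counts them (see cache.n_unconverged)
warnings.filterwarnings("ignore", message="IB solver did not converge")

from ibsurprise import IBCache, SubjectSpec, calibrate_noise_sd, generate_auc_subject
from ibsurprise.fitting import grid_search, permutation_test

N_GRID = np.arange(2, 21)
BETA_GRID = np.geomspace(0.5, 100, 20)

cache = IBCache()
spec = SubjectSpec(seed=0)
spec = replace(spec, noise_sd=calibrate_noise_sd(spec, 0.23, cache))
print(f"calibrated AUC noise sd: {spec.noise_sd:.3f} uV*s")
subject = generate_auc_subject(spec, cache)

ib_fit, _ = grid_search(subject.auc, subject.seq, "ib", N_GRID, BETA_GRID, cache=cache)
noc_fit, _ = grid_search(subject.auc, subject.seq, "noc", N_GRID, cache=cache)
p, _, _ = permutation_test(subject.auc, subject.seq, "ib", N_GRID, BETA_GRID,
                           n_perm=200, seed=5, cache=cache)

print(f"\nIB  fit: N = {ib_fit.N}, beta = {ib_fit.beta:.2f}, "
      f"weighted R2 = {ib_fit.weighted_r2:.3f}, slope = {ib_fit.slope:.2f} uV*s/bit,"
      f" capacity = {ib_fit.capacity_bits:.2f} bits, p = {p:.4f}")
print(f"NOC fit: N = {noc_fit.N}, weighted R2 = {noc_fit.weighted_r2:.3f}, "
      f"slope = {noc_fit.slope:.3f} uV*s, capacity = {noc_fit.capacity_bits:.2f} bits")
print("\nBoth models detect the linear surprise signal; the IB account uses far")
print("fewer bits of memory than exact counting (its I(X;M) vs log2(N+1)).")
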