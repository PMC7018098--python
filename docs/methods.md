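# Methods

## Observer models

The stimulus is a block-structured Bernoulli sequence; within a block
every trial is an independent draw with that block's oddball
probability θ. The observer is assumed to summarize the last `N`
trials by the oddball count `x` — the minimal sufficient statistic for
θ, so nothing predictive is lost by forgetting the order — and to hold
a (possibly compressed) representation `m` of that count from which it
predicts the next tone `y`.

With a uniform prior on θ the count-and-next-tone joint is

    p(y=1, x=n) = ∫ C(N,n) θ^(n+1) (1−θ)^(N−n) dθ = (n+1)/((N+1)(N+2)),

with uniform count marginal `p(x=n) = 1/(N+1)` and the Laplace
succession rule `p(y=1|x=n) = (n+1)/(N+2)` as its predictive. The
joint is treated as stationary; no online updating across blocks.

The **NOC** model keeps `x` exactly. Its per-trial predictor is the
opposite-tone count (`N−n` on oddballs, `n` on standards): a tone that
contradicts recent experience is modelled as evoking a larger
response. Its memory cost is `log2(N+1)` bits. For pooling across
subjects with different fitted `N` the predictor is normalised to the
running probability `n/N`.

The **IB** model compresses `x` into `m` by minimising
`I(X;M) − β·I(M;Y)`. The optimum satisfies the self-consistent
equations

    p(m|x) ∝ p(m) exp(−β · KL[p(y|x) ‖ p(y|m)])
    p(m)   = Σ_x p(x) p(m|x)
    p(y|m) = Σ_x p(y|x) p(x|m)

The KL divergence in the exponent is taken in nats, so β follows the
natural-log convention; all reported informations and surprises are in
bits. Because fitted β values are convention-dependent, β estimates
are comparable within this package but not directly against other
implementations using a different log base. The per-trial predictor is
the subjective surprise `S(y|x) = −Σ_m p(m|x) log2 p(y|m)` and the
effective capacity is `I(X;M)`.

The representation alphabet defaults to `|M| = N+1`: IB optima are
achievable without a larger alphabet, and compression is expressed
through soft, low-information encoders rather than reduced cardinality.

## Solving the IB fixed point

The equations are iterated to a fixed point. Numerical choices:

- **Initialisation.** A slightly perturbed identity encoder iterated
  directly at the target β. The collapsed encoder (all rows equal) is
  a fixed point at *every* β, so an ascending warm-start ladder that
  passes through the fully compressed regime can stay trapped on that
  saddle; the direct identity start avoids this. At low β the
  iteration contracts to the collapsed optimum anyway; at high β the
  identity is already near the optimum. `solve_ib` adds seeded random
  restarts (default 2) and keeps the candidate with the smallest
  objective. `ib_info_curve` provides the annealed ascending ladder
  (with small per-rung jitter re-injected so symmetry can break) for
  tracing the information plane; both `I(X;M)` and `I(M;Y)` are
  non-decreasing along it.
- **Acceleration.** Successive substitution is accelerated with
  SQUAREM-style extrapolation (two base steps, an extrapolated step,
  one stabilising base step). Convergence is only ever declared when a
  *plain* update moves the encoder by less than `tol` in max absolute
  value, so accepted fixed points satisfy the unaccelerated criterion.
- **Tolerances.** `tol = 1e-8`, `max_iter = 30000`. Near the
  cluster-splitting phase transitions the linear convergence rate
  approaches 1 and a few grid points exhaust `max_iter`; they are
  returned with `converged=False`, warned about, and counted by the
  cache. Their tables are accurate to far better than the grid
  resolution and remain usable.
- **Degenerate solutions.** Below the first phase transition the exact
  optimum carries zero information; the numerical solution then
  differs from constancy only by solver tolerance. Grid points with
  `I(X;M) < 1e-6` bits are excluded from the fit: a representation
  holding no information about the count cannot predict trial-by-trial
  variation, and regressing on its numerical residue produces spurious
  fits with arbitrarily large slopes.
- Decoder probabilities are floored at 1e-300 for logging only, never
  renormalised; with the uniform-prior joint all `p(y|m)` are strictly
  inside (0,1) at finite β, so infinite surprise cannot occur there
  (it is still detected and warned about if a hand-built solution
  produces it).

## The P300 feature

Epochs are trials × samples matrices (µV) on a uniform grid covering
at least 0–0.5 s around tone onset. After optional baseline
correction (mean subtraction over −200–0 ms, the default when the
epoch includes pre-stimulus samples), the oddball-minus-standard
difference trace is computed; `t_peak` is its argmax within 300–500 ms
(a non-positive maximum raises the no-peak error, which the pipeline
maps to subject exclusion); `t1` and `t2` are the zero crossings
nearest the peak on either side, located by linear interpolation
between samples of opposite sign, with flat zero runs resolved to the
sample nearest the peak and missing crossings clipped to the epoch
edge with a warning. The per-trial AUC is the *signed* trapezoidal
integral of each trial between `t1` and `t2` (negative excursions
subtract; single trials may dip below zero even though the difference
trace is positive there by construction). Per-trial values are
normalised by the AUC of the difference trace itself, making the
feature dimensionless, subject-comparable, and exactly 1 for the
difference trace. When the input is a feature table rather than
epochs, the normalisation constant is the mean oddball AUC minus the
mean standard AUC, which equals the difference-trace AUC when all
trials are valid.

Channel choice is reduced to a helper that picks the channel with the
largest difference-trace peak; surprise-related analysis (SRA)
averages epochs grouped by their (optionally rounded) predictor value.

## Fitting and significance

The response model is `AUC = intercept + slope · predictor + ε`. An
intercept is always included so baseline AUC is not conflated with
surprise sensitivity. Because extreme predictor values are rare by
construction, the regression uses inverse-probability weights computed
from the model's asymptotic tables, never from empirical frequencies:
for NOC, `p(n) = p(y=0,x=n) + p(y=1,x=N−n)`; for IB, surprise values
are first binned to a fixed 1e-4-bit grid (left edges, anchored at 0)
and `p(s)` sums the joint cells sharing a binned value. Weights
therefore depend only on `(model, N, β)`, and two sequences with the
same parameters receive identical weight maps.

The weighted R² is `1 − Σw(y−ŷ)²/Σw(y−ȳ_w)²` with `ȳ_w` the
weight-weighted mean (the closed-form two-parameter weighted
least-squares solution; cross-checked against statsmodels WLS in the
tests — the in-loop implementation is closed-form because the
permutation test refits on the order of 10⁵ times). `(N, β)` are
selected by exhaustive grid search; ties break toward smaller `N`,
then smaller `β` (parsimony). Defaults: `N ∈ {2..50}` and a 30-point
geometric β grid on [0.5, 100], both overridable. Weighted R² values
at different `(N, β)` use different weights and validity masks, so the
criterion surface is flat near the optimum and the argmax carries a
few trials of uncertainty in `N`; the recovery tests quantify this.

Significance uses a within-block permutation test: tones are shuffled
independently inside each block (AUC stays attached to trial
positions, and each block's oddball count is preserved exactly), the
full grid search is re-run, and the *maximum* weighted R² over the
grid is the null statistic, absorbing the multiple comparisons of the
search. The add-one estimator `p = (1 + #{null ≥ observed})/(1 + n_perm)`
never returns zero. IB solutions are cached by `(N, β)`; because they
are data-independent, caching is semantically invisible to
permutation results.

Pooled multi-subject regressions (per-subject mean normalised AUC per
predictor value, running probability or bits on the x-axis) are
single unweighted point-level OLS fits via statsmodels, reporting R²,
F and p.

## Synthetic subjects

The generator's defaults are the study conditions: 5 blocks × 240
trials with oddball probabilities (0.1, 0.2, 0.3, 0.4, 0.5); an IB
observer with `N = 11`, `β = 48.33` and slope 0.93 µV·s/bit; epochs at
256 Hz spanning −0.2–0.9 s with a positive Gaussian deflection centred
at 400 ms. Trial AUC is `intercept + slope·predictor + ε` with i.i.d.
Gaussian ε on valid trials (invalid window trials carry
intercept-plus-noise and stay masked). Waveform rendering
parameterises the bump by its integral so each trial's target AUC is
exact by construction; waveform noise is white. Sequence draw, AUC
noise and waveform noise come from independent seeded substreams of
one subject seed.

No single-trial noise magnitude is prescribed by the response model
itself; it is set by inverting the expected weighted R²,

    σ = |slope| · sqrt(Var_w(predictor) · (1/R² − 1)),

with `Var_w` the inverse-probability-weighted variance of the true
predictor on the subject's own sequence. A target of 0.23 reproduces
the single-trial fit quality regime the models are meant to operate
in.

**What the generator does not emulate:** multichannel EEG, 1/f
background spectra (a pink-noise option is left stubbed), artifacts,
non-stationary or drifting response gain, latency jitter of the P300,
and inter-subject heterogeneity beyond the `SubjectSpec` parameters. Passing
recovery tests therefore show that the pipeline inverts its own
generative assumptions at realistic signal-to-noise — not that real
EEG satisfies those assumptions.

## Problem sizes and reproducibility

The test suite and the acceptance script run at deliberately chosen
desk scales: recovery uses 20 subjects of 1200 trials on an
`N ∈ {2..20}` × 20-point β grid; permutation calibration uses 200
noise-only subjects of 240 trials with 200 permutations each; the
acceptance script fits one representative subject plus a 10-subject
cohort with 200 permutations. These sizes make the statistical checks
sharp while keeping a full run in minutes on one core. All randomness
derives from explicit seeds (per-subject seeds spawn named
substreams), and reruns with the same configuration are byte-identical
up to cache statistics.

## Known limitations

- Fitted β is convention-dependent (natural-log exponent) and
  grid-dependent; only the implied information quantities are
  convention-free.
- Weighted R² is not strictly comparable across `(N, β)` because the
  weights change with the parameters; the grid argmax therefore has a
  broad plateau, and `N` estimates carry ±2-trial uncertainty at the
  study signal-to-noise.
- Near-critical β grid points may not converge to `tol` within the
  iteration cap; they are flagged, not hidden.
- The distance-from-last-oddball baseline is fitted unweighted on
  oddball trials only, as a deliberately weak comparison model.
- Windows are confined to blocks by default (`window_scope="block"`):
  blocks are separated by breaks and have distinct rates, so a window
  spanning the boundary would mix regimes. A `session` scope is
  available for continuous designs.
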