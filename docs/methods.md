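# Methods

## Model and assumptions

The simulator couples two scales. At the molecular scale each cell carries
a toxin/antitoxin/complex network advanced by the exact direct-method
stochastic simulation algorithm (SSA). At the population scale cells grow
deterministically given their current growth rate, divide on volume
doubling, and partition molecules binomially. The assumptions, in order of
consequence:

- **Instantaneous growth feedback.** The growth rate is a deterministic
  function of the current free-toxin concentration,
  `g = λ·exp(−α·T/Ω)`. Toxin effects on growth are assumed faster than the
  0.5-minute reporting step; there is no delay compartment.
- **Growth-mediated dilution as first-order loss.** Every species carries
  a removal channel at rate `g` per molecule. Division *additionally*
  halves counts (binomial partitioning). Both channels are part of the
  model definition; together they set the unstressed stationary free
  antitoxin of a newborn near 60–90 molecules rather than the naive
  `k_a/λ ≈ 182`. The founder starts with 182 (the no-division stationary
  mean, an "excess antitoxin" state); the 100-minute unstressed pre-growth
  relaxes the colony to its true stationary cycle before toxin onset, so
  the exact initial value is immaterial by onset.
- **Raw-number bimolecular propensities.** Binding uses `k_b·T·A` without
  volume scaling, a deliberate simplification of the model family this
  implements.
- **No spatial structure, no death, no gene dosage.** Arrest is the only
  fate distinct from growth, and it is effectively absorbing (constant
  toxin influx with collapsed dilution).

### Numerical scheme

All extant cells advance synchronously on a fixed grid of step
`dt = 0.5` min (≪ the 30-min doubling time). Within a step, counts evolve
by SSA with `g` frozen at its start-of-step value; `g` is then recomputed
from the new toxin count and pre-step volume, and the volume multiplied by
`exp(g·dt)`. Division triggers at the first report time with
`Ω ≥ 2×` birth volume (no sub-step interpolation; the timing bias is
O(λ·dt) and a regression test checks that halving `dt` leaves scan means
unchanged within 20%). Whether `g` should update inside a step is
underdetermined in this model family; boundary update was chosen and the
`dt` sensitivity is tested. Daughter order is randomized at each division
so depth-first leaf order carries no left/right artifact.

The SSA kernels are numba-compiled. Reproducibility contract: replicate
`i` of a run with seed `s` derives two independent streams (SSA kernel,
divisions/daughter order) as a pure function of `(s, i)` via
`SeedSequence(s, spawn_key=(i,))`, so any subset of replicates can be
rerun bit-identically in any order (but single replicates must be advanced
sequentially — the kernel stream is global state).

### Parameters

| parameter | default | units | origin |
|---|---|---|---|
| k_a | 4.2 | molecules/min | fixed antitoxin production |
| k_b, k_u | 0.1, 0.1 | 1/min | binding/unbinding |
| λ | ln2/30 ≈ 0.0231 | 1/min | 30-min doubling time |
| α | 0.1 | volume/molecule | moderate toxicity (0 = none, 0.3 = high) |
| dt | 0.5 | min | reporting/volume-update step |
| t_onset, t_end | 100, 250 | min | pre-growth and horizon |
| arrest cutoff | 0.01 | 1/h | growing/arrested boundary (≈1.67e-4 /min) |
| d_a (unstable-antitoxin variant) | 0.2 | 1/min | not printed in the model family; config-exposed |
| k_on = k_off (telegraph variant) | 0.1 | 1/min | preserves mean synthesis (rate k/p_on while ON); config-exposed |
| population cap | 5000 | cells | hard abort guard |

## Measured regime structure

With these parameters the scan over k_t (toxin production) yields three
regimes: near-maximal mean growth for k_t ≤ 2.5, a graded intermediate
band over 3–4.5 where mean growth falls from ~80% to ~18% of λ with toxin
concentration rising monotonically, and near-zero growth above ~4.7. The
*arrest* transition — where individual cells actually cross the 0.01/h
cutoff — is sharper and sits at k_t ≈ 4.4–5.5: free toxin can only run
away once production outpaces antitoxin production (4.2/min) plus
dilution, so below ≈4.4 cells slow smoothly but essentially never arrest
within the 250-minute horizon. Consequences used by the test suite and
acceptance script:

- The "nearly instantaneous arrest" boundary (final population ≤ 2× onset
  population and >90% arrested) measured on the integer scan grid is
  k_t = 5 /min.
- Mutual information between growth-rate differences and lineage distance
  is elevated across the regulatable band (≈2.5–4.5) and low at both
  extremes; it is estimated with one random extant pair per independent
  colony, 8×8 equal-width bins over the pooled sample range, and 100
  bootstrap resamples (bin edges frozen from the full sample — the
  uncertainty quantifies sampling, not binning). 100 colonies per
  condition are used: with substantially fewer pairs the plug-in
  estimator's small-sample bias swamps the condition ordering. With α = 0
  the growth rate is constant and the MI signal vanishes identically.
- Binary growth/arrest entropy peaks (≈0.9–1.0 bit) at the arrest
  transition k_t ≈ 4.9–5.1, just above the elevated-MI band, and falls to
  0 at both extremes. Fine-grained entropy uses bin width λ/20 for growth
  rates (range/32 generically) and is bounded by the extensive maximum
  log2(population size).
- Arrested-cluster size distributions (runs of arrested cells in
  depth-first leaf order, pooled over 1000 colonies) decay exponentially
  just below the transition (k_t = 4.5; log-linear fit `a·e^(−b·c)`,
  R² ≈ 0.99) and develop systematic positive excess at large sizes near it
  (k_t = 5.25), quantified as the mean log-residual over the upper half of
  occupied sizes with ≥5 observations (rarer sizes abut the whole-colony
  bound and carry finite-size noise).

### Critical slowing down: a known shortfall

Growing-cell-count series (counts of extant cells with g above the
cutoff, from toxin onset onward) are analyzed per replicate: mean
subtraction by the replicate's own window mean, normalized
autocorrelation to a maximum lag of 140 min, then averaging across
replicates; oscillatory convergence is scored by sign changes of the
replicate-mean autocorrelation. In this implementation the near-critical
regime (k_t = 5.0–5.25) robustly shows *two* sign changes (down ≈35 min,
back up ≈115 min) versus one in both sub-critical and extinction regimes —
a real, reproducible oscillatory signature, but one crossing short of the
">2 crossings" convention for flagging the oscillatory regime, because the
third crossing falls beyond the 150-minute post-onset window. Longer
horizons do not recover it (the rise–fall trend then dominates), and
ensemble-mean detrending inverts the comparison by injecting noise
crossings everywhere. The 2-vs-1 distinction is what this model yields at
this horizon.

## Synthetic trajectory generator

`synthesize_tracks` emulates slow minimal-medium time-lapse microscopy:
branching colonies with ~115-minute cell cycles, exponential elongation
near 0.006 /min (per-cell rates N(0.006, 0.001)), 5-minute sampling,
multiplicative log-normal length noise, optional abrupt mid-cycle growth
shifts, and lineage-correlated arrest via a heritable arrest-prone state
(a newborn inherits the mark or acquires it with probability 0.05;
marked cells arrest with an elevated probability, optionally only after an
onset time). Arrested cells stop elongating and never divide.

What it does *not* emulate: segmentation/tracking errors, cell filamentation,
length-dependent division, photobleaching drift, or death/lysis distinct
from arrest. Passing recovery tests therefore demonstrates the fitting
pipeline's statistical behavior under clean exponential-plus-noise data,
not robustness to imaging artifacts. Under the defaults, a complete cycle
yields ~23 length samples, putting the 10% relative accuracy band at
about twice the log-slope standard error — recovery within 10% for ≥90%
of complete cycles is attainable but not trivial, which is the intended
operating point. Fitting is linear regression on log-length (slope
p-value from the regression t-test); cycles failing a Bonferroni-adjusted
screen (α/m over the m fitted cycles) fall back to a continuous
two-segment piecewise-linear fit with the breakpoint grid-searched over
interior sample times (≥2 points per segment). Reported classification
always uses the full-cycle log-slope, which is robust to noisy short
segments.

## Design choices on genuinely open points

- "Lineage neighbors" for clustering = adjacency in depth-first leaf
  order (with randomized daughter order); well-defined on binary trees and
  reproduces visually contiguous arrested blocks.
- Mann–Whitney U: exact enumeration null for small samples (both n ≤ 10),
  including tied data (permutation enumeration); tie-corrected normal
  approximation otherwise.
- The Hill ODE is read as `dT/dt = k_t − [γθ/(θ+T)]·T` — growth-mediated
  dilution at the Hill-decaying per-capita rate — the only reading
  consistent with the closed-form steady state and the arrest condition;
  the boundary case k_t = γθ is classified as arrest (the steady state
  diverges).
- In the binomial-inheritance model, arrest is checked after production
  and before division, and is permanent.
- Degenerate MI binning (an axis with a single occupied bin) returns MI=0
  with a warning rather than an error, because it is the correct limit
  (e.g. α=0 growth rates).

## Limitations

- The arrest transition sits ~0.5–1 /min above the regulatable-growth
  band's upper edge; statements tied to "the critical regime" depend on
  which observable defines it (mean growth vs single-cell arrest).
- Plug-in MI and entropy are biased upward at small sample sizes; all
  comparisons here are relative across conditions, never absolute.
- The population cap (5000) and 250-minute horizon bound what cluster
  sizes and autocorrelation lags are observable.
- Newick export annotates final-state values only; full per-time histories
  live in the long-format CSV.
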