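# Methods

## Model and assumptions

The package implements a two-threshold abstraction of nest choice: when two
candidate sites differ in quality, any distribution of individual acceptance
thresholds collapses to two classes — ants whose threshold lies above the
poor site's quality (fraction *H*, satisfied only by the good site) and ants
below it (fraction *L* = 1 − *H*, satisfied by either).  The models are
non-spatial and neglect travel time; recruitment is mass-action (each ant at
home is recruited at a rate equal to the recruiting fraction of the colony
for that site).  Ants committed to a site never switch directly to another
site; they can only return home by leakage (rate `alpha_leak`) and be
re-recruited.  The single exception is the high-threshold visitor at the
poor site, who defects directly to the good site at rate `alpha_s`.  The
quorum rule stops a run at the first site whose vote reaches the threshold;
the rapid-transport phase that follows a quorum in real emigrations is
outside the model's scope, as is any per-ant identity or memory beyond
compartment membership.

Time unit: the recruiting rate per recruiter–recruitee pair is 1.  All rate
parameters are expressed in that unit.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `H` | fraction of high-threshold (choosy) ants | 0.2 | `L = 1 - H` |
| `z` | scout fraction at t = 0, split equally between sites | 0.3 | empirical scouting fractions are ~0.3 |
| `alpha_p`, `alpha_g` | committed → recruiter conversion rate at poor/good site | 0.1 | `alpha=` shorthand sets both (the default analyses use equal rates to isolate the threshold mechanism) |
| `alpha_s` | poor → good switching rate of high-threshold visitors | 0.1 | 0 disables switching |
| `alpha_leak` | abandon-and-return-home rate | 0.05 | 0 disables unsuccessful emigrations |
| `N` | colony size (stochastic model) | 100 | initial compartments must be integers |
| `quorum_fraction` | quorum threshold / N | 0.5 | validated against the initial votes |
| `n_nest` | number of equal sites (cohesion variant) | 2 | |
| `finish_fraction` | emigrant fraction ending a cohesion run | 0.9 | |

The preset `paper-default` is the baseline above; `pratt-derived`
(`alpha = 0.5`, `alpha_s = 0.25`) rescales field estimates of tandem-running
and conversion rates in *Temnothorax* into the unit-pair-recruiting-rate
time unit.

## Numerical choices

* **ODE integration** is forward Euler at `dt = 0.001` (the reference
  resolution for all reported mean-field results).  Step-halving against
  `dt = 1e-4` changes no compartment by more than 2e-5 over t ∈ [0, 100] at
  the baseline, and a `dt = 1e-5` integration fixes the regression anchor
  for the baseline quorum time (t = 14.022).  The exact dynamics preserve
  positivity and the two class sums; the integrator therefore treats any
  negative excursion beyond 1e-9 as a step-size failure (raised as an
  error), clips smaller round-off excursions to zero on output, and the
  class sums drift by < 1e-12 over t ≤ 1000.
* **Quorum detection** runs at full step resolution inside the integrator
  even when the stored trajectory is decimated (default stride 100).
  Configurations whose initial votes already meet the threshold
  (`quorum_fraction <= z/2`) are rejected as invalid rather than silently
  reported as t = 0; an explicit flag downgrades this to a t = 0 result.
* **Stochastic engine**: exact event-driven sampling over the fifteen
  channels (exponential waiting time from the total rate, channel chosen
  proportionally).  Because every event moves one ant, the two votes can
  never cross the threshold simultaneously and no tie-break is needed.
  The description of the finite-population dynamics as per-step
  probabilities `rate × Δt` is realized as a separate fixed-step engine
  (multinomial per source compartment, per-ant step probabilities required
  < 0.1) used purely to cross-validate the exact one; exactness removes Δt
  as a confounder from all reported results.
* **Seeding**: per-run seeds derive from a master seed via numpy's
  `SeedSequence` (scheme id `seedseq-v1`, 31-bit), recorded in every output
  manifest; identical (parameters, master seed) reproduce batches
  bit-identically, and the compiled and pure-Python engines draw identical
  random streams (asserted bit-for-bit in the tests).
* **Censoring**: runs are cut at `t_max = 1e5` by default and counted
  separately from unsuccessful emigrations; censored runs never enter T or
  P and their count is a first-class output.  A zero-total-rate state that
  is not the all-home state (reachable only in degenerate parameter
  corners such as `alpha_leak = 0` with all rates off) is reported as
  censored at the stop time.
* **Confidence intervals** default to 1.96·sd/√n.  The variant 1.96·sd/n,
  which matches one published figure caption verbatim and is almost
  certainly a typo for the standard error, is available as
  `mode="paper_literal"` for like-for-like comparison only.
* **Correlation**: `pearson_r` is the standard product–moment correlation
  of the per-value (T̄, P) batch means, one point per parameter value,
  unweighted.
* **Cohesion index**: natural logarithms; `p_i` normalizes the site
  occupancies (committed + recruiting ants, who both belong to their site)
  over the *emigrants* at the finish time, not over N, so that the
  distribution sums to one while up to `(1 - finish_fraction)·N` ants remain
  home.  The raw occupancy vector is also returned for inspection under the
  alternative normalization.

## Study conditions and problem sizes

The experiment harness defaults mirror the baseline study conditions:
N = 100, quorum 0.5 N, `alpha = alpha_s = 0.1`, `alpha_leak = 0.05`,
z = 0.3, with 10⁴ runs per parameter value in the acceptance script.
Sweep grids are constrained by the requirement that every initial
compartment count be an integer; where the reference grids are not printed,
the package uses the natural choices that satisfy it: H ∈ {0, 0.2, 0.4,
0.6, 0.8, 1.0} (the only evenly spaced six-point grid at N = 100,
z = 0.3), z in multiples of 0.1 at H = 0.2, quorum fractions
{0.3 … 0.7}, and cohesion scout fractions in multiples of 0.12 (divisible
by 2, 4 and 6 sites, with z = 0.12 as the urgency-sweep anchor).  These
grids are deliberate defaults, overridable everywhere.  The test suite
runs the same experiments at 600–3000 runs per point, enough to resolve
every directional claim it asserts.

## What the simulations do and do not show

All experiments are self-contained simulations of the models; there is no
external data.  Agreement between the two stochastic engines, and between
the stochastic mean and the mean-field trajectory at N = 10⁴, validates the
implementation, not the biology.  The models omit space, travel time,
per-ant assessment noise, the rapid-transport phase after quorum, and
continuous threshold distributions (exact for two site qualities, an
approximation otherwise); quantitative outputs (T, P, T_f, C) are in model
time units and should be read comparatively, not as calendar predictions.

## Known limitations

* The speed–accuracy trade-off region for slow switching
  (`alpha_s = 0.01`) is sensitive to the quorum threshold: the H-sweep
  (T, P) correlation is strongly positive for quorum fractions ≤ 0.3 but
  changes sign by 0.5, where T becomes non-monotone in H.  The qualitative
  sign-flip test therefore pins its reduced grid to quorum fractions
  0.2–0.3.
* With all-equal-quality sites the cohesion variant fixes `H = 0` and
  `alpha_s = 0`; heterogeneous-quality multi-site choice (three or more
  thresholds) is out of scope.
* `finish_fraction = 1.0` with leakage makes finishes vanishingly rare;
  the harness reports censoring rather than waiting for them.
* Recruitment-latency asymmetry (`alpha_g > alpha_p`) is fully
  parameterized but no shipped experiment varies it.
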