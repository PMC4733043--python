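# Methods

## Model and assumptions

`orgcount` models the number of organelles *n* in a single cell as a
continuous-time birth–death chain on the non-negative integers driven by
four memoryless processes: de novo synthesis (state-independent gain at
rate *k*₍de novo₎), fission (per-organelle gain at *k*₍fission₎·*n*), decay
(per-organelle loss at γ·*n*) and fusion (per-ordered-pair loss at
*k*₍fusion₎·*n*(*n*−1)). Organelles are treated as identical and unsized;
there is no spatial structure, no cell division or partitioning, no
feedback of *n* on the rates, and no detection model for how counts are
measured. Time units are arbitrary: uniformly rescaling all four rates
rescales time only, so equilibrium quantities depend on the three ratios
*k*₍de novo₎/γ, *k*₍fission₎/γ, *k*₍fusion₎/γ.

The fusion propensity is taken verbatim as *k*₍fusion₎·*n*(*n*−1) — ordered
pairs, no factor ½. Any symmetric convention is absorbed into the value of
*k*₍fusion₎ and leaves every distribution unchanged.

## Exact solver

Because the chain moves by ±1 steps, stationarity forces the probability
flux between each adjacent state pair to balance (a cut argument: the net
flow across the edge between {0..n} and {n+1,…} must vanish). This gives
the term-ratio recurrence

f₍n+1₎ = (*k*₍de novo₎ + *k*₍fission₎ n) / ((γ + *k*₍fusion₎ n)(n+1)) · fₙ.

The solver seeds the recurrence with an arbitrary first term, iterates
forward and normalises; the seed cancels exactly. Numerical choices:

* **Log-space accumulation throughout.** Terms are carried as logs and
  normalised with log-sum-exp, so large-mean cases (e.g. a Poisson law with
  λ in the thousands) neither overflow nor underflow.
* **Truncation rule.** The support is extended until the running term falls
  below `tail_tolerance × 1e-3` of the retained mass *and* the term ratio
  is below 1 (past the distributional mode). Past the mode the ratio is
  decreasing for every convergent sub-model (the numerator is linear in
  *n*, the denominator at least quadratic or linear with a larger slope),
  so the discarded tail is bounded by a geometric series; that bound is
  reported as `tail_bound`. Defaults: `tail_tolerance = 1e-12`, hard cap
  100,000 states. Hitting the cap raises a truncation error that reports
  the mass retained rather than returning a silently clipped distribution.
* **Support start.** The starting state comes from `classify_regime`, the
  single source of truth for reachability: *n* = 1 for the pure
  fission/fusion model (state 0 unreachable), otherwise 0.
* **Refusal over divergence.** When *k*₍fission₎ ≥ γ with no fusion the
  recurrence terms do not decay and the mean grows without bound; the
  solver raises a regime error instead of truncating a divergent sum. The
  boundary *k*₍fission₎ = γ is included in the divergent class because both
  exact moments diverge there.
* **Degenerate corners.** With no de novo synthesis but active decay, the
  chain is absorbed at 0 and the point mass at 0 is returned as the true
  limiting law. Pure immigration (no decay, no fusion) is classified as
  divergent (`NO_LOSS_PROCESS`). If no process is active at the support
  minimum (e.g. all rates zero, or fusion alone), the recurrence terminates
  immediately and returns the point mass there; these inputs have no unique
  limiting law and the result should be read as "the chain cannot leave
  this state".
* **Fano factor of an empty population** is reported as NaN with an
  explicit `fano_defined=False` flag, never silently as 0: σ²/⟨n⟩ has no
  value at ⟨n⟩ = 0, and a 0 would corrupt Fano-vs-mean curves.

`stationarity_residual` measures the largest adjacent-pair flux imbalance
of any distribution under given rates; solver output satisfies it to
round-off by construction, and for empirical histograms it quantifies
distance from stationarity in probability per unit time.

## Closed forms

The three solvable sub-models are identified directly from the term ratio:
`{de novo; decay}` gives Poisson(λ = *k*₍de novo₎/γ); `{fission; fusion}`
gives the zero-truncated Poisson with λ = *k*₍fission₎/*k*₍fusion₎ on
*n* ≥ 1 (the Poisson pmf conditioned on *n* ≥ 1, i.e. divided by 1−e^(−λ));
`{de novo, fission; decay}` gives the negative binomial with shape
r = *k*₍de novo₎/*k*₍fission₎ and success parameter p = *k*₍fission₎/γ,
pmf ∝ Γ(r+n)/(Γ(r) n!) pⁿ — the unique negative binomial whose term ratio
matches the recurrence, reproducing mean rp/(1−p) and Fano 1/(1−p).

The *shifted* Poisson (1 + Poisson(λ), support *n* ≥ 1) is included as a
deliberate foil: it is not the limiting law of any sub-model, but it has
historically been used for fusion/fission-maintained organelles, and its
Fano-vs-mean curve (mean 1+λ, Fano λ/(1+λ)) differs markedly from the
truncated Poisson's (mean μ = λ/(1−e^(−λ)), Fano 1+λ−μ): the truncated
curve approaches Fano 1 like λe^(−λ) while the shifted curve does so as a
slow power law, so the two laws are best distinguished at small means.
Curve sweeps use a log-spaced grid over the shape parameter to cover both
limits; the negative-binomial sweep is over p at fixed r.

Pmf and moment evaluation delegate to `scipy.stats`; the recurrence solver
is written independently and never calls them, so the term-by-term
agreement asserted in the tests (total variation < 1e−10 across parameter
grids) is a genuine two-route check, not a tautology.

## Simulation

Two samplers share one configuration object:

* **Event-driven** (default): exact stochastic simulation — exponential
  waiting times at the summed propensity, event type drawn proportionally
  to the four propensities.
* **Fixed-step**: at each step of length dt (default 0.0001 time units)
  one uniform variate is compared against the cumulative first-order
  probabilities *k*₍de novo₎dt, *k*₍fission₎*n*dt, γ*n*dt,
  *k*₍fusion₎*n*(*n*−1)dt; at most one event fires per step, so the
  multi-event error is O(dt²). The implementation draws uniforms in blocks
  and scans for the first triggering step, which preserves the exact
  per-step uniform stream while staying fast. `event_probabilities` warns
  when the summed per-step probability exceeds 0.1 and refuses beyond 1;
  the step size is the caller's responsibility and is never clamped.

Identical configuration and seed reproduce a trajectory byte-for-byte.
Ensembles derive one child seed per cell from the master seed via
`numpy.random.SeedSequence.spawn`, a counter-based split that makes the
snapshot independent of execution order. Trajectories in divergent regimes
terminate informatively: when the count exceeds a configurable cap (default
10⁶) a divergence error is raised carrying the regime classification.

Time-average statistics discard the first 20% of a run by default
(overridable); with the reference parameters the relaxation time is a few
1/γ, so any run long relative to that forgets its starting count well
within the burn-in.

## Inference

Observed histograms are summarised by the sample mean and the unbiased
(n−1 denominator) sample variance — the estimator is stated here precisely
so that downstream numbers are reproducible; the Fano factor is their
ratio. Optional percentile-bootstrap confidence intervals and standard
errors resample cells (multinomially over the histogram). Inversion to
rate ratios assumes the fusion-free model and an equilibrated population;
a Fano factor below 1 is refused by default (it falsifies those
assumptions) and may instead be clamped to 1 under an explicit tolerance,
with a warning, to absorb sampling noise straddling the Poisson boundary.
In bootstrap replicates the clamp is always applied, since noise around
Fano 1 would otherwise abort the resampling loop. Percent figures in
reports are rounded to the nearest whole percent; machine-precision values
remain available on the returned objects.

One decomposition subtlety worth recording: at Fano factor 1.1 the split is
1/1.1 ≈ 91% de novo and ≈9% fission. A figure label stating the reverse
(9% de novo, 91% fission) at that Fano factor circulates in the literature;
it contradicts the defining identity F = 1 + *k*₍fission₎⟨n⟩/*k*₍de novo₎
and is treated here as a transcription slip, not an alternative convention.

## What the simulators and tests do and do not show

The synthetic data used throughout the tests are generated by the package's
own samplers under the model's assumptions: well-mixed identical organelles,
constant rates, perfectly counted. Passing tests therefore demonstrate
internal consistency (simulation ↔ exact solver ↔ closed forms ↔
inversion) and correct numerics; they cannot validate the model against
real populations, where cell division, organelle-size-dependent detection
limits, growth-condition shifts and rate feedback all perturb the counts.
In particular, the inversion's output is only as meaningful as the
equilibrium assumption behind it.

Problem sizes used in the test suite and examples — ensembles of 2,000 to
10,000 cells, trajectories of 2,000–3,000 time units, 300–400 bootstrap
replicates — were chosen so that Monte-Carlo standard errors are small
relative to the tolerances being asserted (e.g. a 10,000-cell histogram
has a total-variation sampling floor of ≈0.02, and a 5,000-cell moment
inversion recovers the reference rate ratios within ±3 bootstrap SEs).

## Known limitations

* The four-process model has no mechanism producing sub-Poisson (Fano < 1)
  count distributions without fusion; such data are flagged, not fitted.
* Inference is purely moment-based; no likelihood fitting of the closed
  forms is provided.
* The fixed-step sampler is first-order in dt; it exists to mirror the
  discrete-probability definition of the model and for cross-validation
  against the exact sampler, not as the recommended engine.
* Time-dependent (pre-equilibrium) distributions are available only through
  ensemble simulation; the master equation is not integrated directly.
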