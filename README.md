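# orgcount

Exact equilibrium analysis and stochastic simulation of **organelle
copy-number dynamics** in single cells.

Cell-biological organelles — peroxisomes, Golgi cisternae, vacuoles — are
maintained by a handful of elementary processes: *de novo* synthesis from
precursor material, *fission* of existing organelles, first-order *decay*,
and pairwise *fusion*. The number of organelles per cell, *n*, then follows
a birth–death process, and the shape of the steady-state count distribution
across a cell population (in particular its Fano factor, σ²/⟨n⟩) carries
information about which production pathway dominates. `orgcount` is for
quantitative cell biologists and modellers who want to go from measured
organelle-count histograms to mechanistic rate constants, or from assumed
rate constants to predicted count distributions — without stochastic
approximations.

## The model

In a cell with *n* organelles the four processes fire with propensities

| process  | propensity            | Δn |
|----------|-----------------------|----|
| de novo  | *k*₍de novo₎          | +1 |
| fission  | *k*₍fission₎·*n*      | +1 |
| decay    | γ·*n*                 | −1 |
| fusion   | *k*₍fusion₎·*n*(*n*−1)| −1 |

At equilibrium the probability flux between adjacent states balances,

&nbsp;&nbsp;(*k*₍de novo₎ + *k*₍fission₎ *n*) *f*ₙ = (γ + *k*₍fusion₎ *n*)(*n*+1) *f*ₙ₊₁,

giving a term-ratio recurrence that yields the **exact** limiting
distribution *f*ₙ for any combination of the four processes. Three
sub-models reduce to named laws:

* `{de novo; decay}` → **Poisson**(λ = *k*₍de novo₎/γ);
* `{fission; fusion}` → **zero-truncated Poisson**(λ = *k*₍fission₎/*k*₍fusion₎)
  on *n* ≥ 1 — *not* the shifted Poisson sometimes assumed;
* `{de novo, fission; decay}` → **negative binomial**, with exact moments

&nbsp;&nbsp;⟨n⟩ = *k*₍de novo₎/(γ − *k*₍fission₎),&nbsp;&nbsp;
σ²/⟨n⟩ = γ/(γ − *k*₍fission₎) = 1 + *k*₍fission₎⟨n⟩/*k*₍de novo₎,

valid whenever *k*₍fission₎ < γ (both diverge at the boundary; beyond it no
limiting distribution exists). Inverting these identities turns an observed
(⟨n⟩, Fano) pair into the rate ratios *k*₍de novo₎/γ = ⟨n⟩/F and
*k*₍fission₎/γ = 1 − 1/F, splits total production into de novo (1/F) and
fission ((F−1)/F) fractions, and predicts the relative drop in ⟨n⟩ if the
fission pathway is deleted (exactly *k*₍fission₎/γ).

The package also provides exact (event-driven) and fixed-time-step
stochastic simulators for single-cell trajectories and cell ensembles, with
full seed reproducibility, plus bootstrap moment estimation for observed
histograms.

## Worked example

```python
from orgcount import (ModelRates, stationary_distribution, distribution_stats,
                      invert_rates, decompose_production, knockout_prediction)

rates = ModelRates(k_de_novo=2.0, k_fission=0.9, gamma=1.0, k_fusion=0.02)
stats = distribution_stats(stationary_distribution(rates))
print(f"mean {stats.mean:.4f}  Fano {stats.fano:.4f}")

inferred = invert_rates(mean=3.0, fano=1.1)
d = decompose_production(1.1)
print(f"k_de_novo = {inferred.k_de_novo_over_gamma:.2f} gamma, "
      f"k_fission = {inferred.k_fission_over_gamma:.2f} gamma")
print(f"{d.de_novo_percent}% de novo, {d.fission_percent}% fission; "
      f"knockout drop {knockout_prediction(inferred):.1f}%")
```

prints

```
mean 7.1933  Fano 2.7084
k_de_novo = 2.73 gamma, k_fission = 0.09 gamma
91% de novo, 9% fission; knockout drop 9.1%
```

The first line is the exact equilibrium of the full four-process model: a
mean of ~7.2 organelles with variance 2.7× the mean (strongly
over-dispersed relative to Poisson). The remaining lines invert a typical
observation — 3 organelles per cell on average with Fano factor 1.1 — to
rate ratios: production is ~91% de novo, and deleting fission is predicted
to lower the mean count by only ~9%.

The `examples/` directory contains one narrative script per capability
(exact solver, closed-form laws, simulation vs solver, inference), and the
`orgcount` command line exposes the same operations as subcommands
(`solve`, `simulate`, `curve`, `decompose`, `invert`, `moments`); run
`orgcount --help`.

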