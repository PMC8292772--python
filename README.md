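# glvident

**What can relative abundances tell you about microbial interactions?**

High-throughput sequencing gives *compositions* — the fraction of reads per
taxon — while population-dynamic models such as the generalized
Lotka–Volterra (gLV) model,

    dN_i/dt = N_i ( r_i + Σ_j β_{i,j} N_j ),

are written in *absolute* abundances N_i.  `glvident` quantifies exactly how
much of the gLV parameter set survives the loss of absolute scale, for
microbiome researchers planning time-series studies and for modellers
fitting interaction networks to 16S/amplicon data:

* **Structural identifiability (symbolic).**  For two species the package
  eliminates the unobserved total N and derives the input–output relation —
  a single polynomial DAE in the observed composition x and its derivatives
  x′, x″ — normalizes it monic, and solves the coefficient system against an
  alternative parameter copy.  Verdict: the growth rates r₁, r₂ are uniquely
  identifiable from composition data alone; the interaction rates β_{i,j}
  are identifiable only up to one common scale (gauge β₂,₂), i.e. the ratios
  β_{i,j}/β₂,₂ are what the data determine.
* **Numeric scale-gauge checks (any n).**  Simulating (r, B, X₀) and
  (r, cB, X₀/c) yields compositions agreeing to solver precision, while any
  non-scale perturbation is clearly visible — verified for communities of
  3–5 species.
* **Practical identifiability (particle MCMC).**  A synthetic three-species
  community with multiplicative environmental noise
  (dN_i = N_i(r_i + Σ_j β_{i,j}N_j)dt + σ_i N_i dW_i) and multinomial
  sequencing noise at read depth V is fitted by particle marginal
  Metropolis–Hastings (bootstrap particle filter + adaptive random-walk
  proposals, uniform priors at ±40% of truth).  With the initial total
  abundance supplied, most parameters are recovered within ~20%; fitting
  with an *assumed* N(0) = 1 instead recovers the fold change N(t)/N(0) —
  relative population size is inferable from purely relative data.

## Worked example

```python
import numpy as np
import glvident as g

# the two gauge-equivalent benchmark parameterizations (B differs 100x)
p1, p2 = g.benchmark_parameters(1), g.benchmark_parameters(2)
print(np.unique(p2.B / p1.B))            # -> [100.]
dev = g.numeric_scale_invariance_check(
    p1, 100.0, g.benchmark_initial_state(1), np.linspace(0, 5, 51))
print(f"max composition deviation: {dev:.2e}")   # -> 1.28e-08

# symbolic verdict for two species
report = g.solve_alternative_parameters(g.make_monic(g.derive_io_relation()))
print(report.describe())
```

prints

```
max composition deviation: 1.28e-08
Structural identifiability of the 2-species gLV model from
relative-abundance data:
  identifiable exactly : r1, r2
  identifiable up to a common scale : b11, b12, b21, b22
  gauge (reference) parameter : b22
  dimension of the unidentifiable family : 1
```

Two communities whose interaction matrices differ by a factor of 100 are
*indistinguishable* from composition data (deviation at solver noise), and
the symbolic analysis says that is the only ambiguity: growth rates and
interaction ratios are recoverable.

The full noisy-recovery experiment, from data generation to fit:

```python
latent, counts, truth = g.make_benchmark_dataset(value_set=2, seed=1)
prior = g.PriorSpec.from_reference(g.pack_parameters(truth))
start = g.perturbed_start(truth, np.random.default_rng(2))
post = g.run_pmmh(counts, prior, g.PMCMCConfig.reduced_budget(seed=3),
                  start, N0=0.28)
summary = g.summarize_recovery(post, truth)
print(f"{int(12 * summary.fraction_within)}/12 parameters within 20%")
# -> 12/12 parameters within 20%   (~2 min on one CPU; stochastic, seeded)
```

Command-line equivalents: `glv-ident simulate`, `glv-ident observe`,
`glv-ident identifiability`, `glv-ident fit`, `glv-ident report
--experiment {scale_invariance,structural,practical,fold_change}`.

See `docs/methods.md` for the model, noise layers, sampler protocol and
numerical choices.

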