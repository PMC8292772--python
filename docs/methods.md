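# Methods

## The model

`glvident` studies the generalized Lotka–Volterra (gLV) model of an
n-species microbial community,

    dN_i/dt = N_i ( r_i + Σ_j β_{i,j} N_j ),        i = 1 … n,

with per-capita growth rates r_i (1/time) and interaction rates β_{i,j}
(1/(abundance·time)); β_{i,j} is the effect of species j on the per-capita
growth of species i.  The single-species equilibrium K_i = −r_i/β_{i,i} is
the carrying capacity when β_{i,i} < 0, but no sign constraint is imposed —
none is needed for the identifiability analysis.  Time and abundance are
treated as unitless throughout.

The observation type is the one sequencing provides: the composition
x_i = N_i/N with N = Σ_i N_i.  The central question is what a time series of
x alone determines about (r, β).

## Structural identifiability (two species, symbolic)

Writing the two-species system in (x, N) coordinates and eliminating the
unobserved total N produces a single differential-algebraic relation in
x, x′, x″ whose coefficients are polynomial in the six parameters.  The
elimination implemented in `structural.derive_io_relation` is:

1. express X′ and Y′ via X = Nx, Y = N(1−x); the quotient rule gives
   x′ = x(1−x)[(r₁−r₂) + N((β₁₁−β₂₁)x + (β₁₂−β₂₂)(1−x))];
2. solve that equation (linear in N) for N;
3. substitute N(x, x′) and its total time derivative into the N′ equation
   and clear denominators.

The polynomial is normalized monic by dividing through by the leading-order
coefficient (β₂₁−β₂₂)−(β₁₁−β₁₂) (where that expression vanishes the DAE
drops order and the parametrization is degenerate; `make_monic` raises in
that case).  The monic coefficients are the identifiable quantities.
Equating them to the same expressions in an alternative parameter copy
(a₁,…,a₆) and solving (sympy, `solve_alternative_parameters`) yields

    a₁ = r₁,  a₂ = r₂,
    a₃ = (a₆/β₂₂)β₁₁,  a₄ = (a₆/β₂₂)β₁₂,  a₅ = (a₆/β₂₂)β₂₁,   a₆ free.

Growth rates are exactly identifiable; the four interaction rates form a
one-dimensional scale class — only the ratios β_{i,j}/β₂₂ are determined,
with β₂₂ as the gauge.  Fixing the absolute scale requires one anchor
measurement of absolute abundance (equivalently, N(0)).

For n ≥ 3 the symbolic elimination suffers severe expression swell and is
not attempted.  Instead the same structure is verified numerically for any
n: the composition trajectory is invariant under (r, B, X₀) → (r, cB, X₀/c)
for any c > 0 (`numeric_scale_invariance_check`, asserted at ≤ 1e−6 for
n = 3, 4, 5), while perturbing r or an individual β ratio changes the
composition by orders of magnitude more (`numeric_distinguishability_check`,
the negative control).  For larger communities the up-to-scale statement
should be regarded as a conjecture supported by these checks, not a proved
result.

## Synthetic data

The generator emulates a sequencing time-course over a small community with
two noise layers:

* **Process noise** — the Itô SDE dN_i = N_i(r_i + Σ_j β_{i,j}N_j)dt +
  σ_i N_i dW_i with independent Wiener processes, integrated by
  Euler–Maruyama at step dt = 0.001.  Default σ_i = 0.1 (1/√time).  Both
  terms scale with N_i, so the SDE is gauge-equivariant: driven by the same
  increments, (r, cB, X₀/c) gives exactly 1/c times the (r, B, X₀) path and
  hence identical compositions — the structural result survives process
  noise.  Because multiplicative noise cannot reach zero in continuous
  time, discretization undershoots are clamped at 1e−10 of the community
  total; a species pinned to the floor for 5 consecutive steps is treated
  as extinct (absorbed at 0) and the event logged.
* **Measurement noise** — per sample, either a Dirichlet draw with
  concentrations α_i = V·Ñ_i/Σ_j Ñ_j (which sum to the read depth V, so the
  per-component variance is p(1−p)/(V+1)), or a multinomial draw of V reads
  at the latent proportions.  Default depth V = 500.  The two emissions
  share first moments.  The default fitting data are multinomial counts,
  matching the fitting likelihood; the Dirichlet path is retained because
  it is the natural continuous-proportion emission, and which of the two a
  given pipeline "really" uses is usually immaterial at this depth.

The benchmark community is a three-species system with r = (6, 4, 2) and a
fixed interaction matrix in two gauge-equivalent versions: value set 2 has
B multiplied by 100 and initial abundances divided by 100 (totals 28 vs
0.28).  Two entries are repeating decimals and are stored as exact
rationals (β₂₂ = −2/75, β₃₃ = −2/135 in set 1).  The default observation
grid is 51 evenly spaced samples on t ∈ [0, 5]: the transient — which
carries most of the interaction information — plus the approach to
equilibrium.  The grid length and span are this package's choice of a
realistic dense time-course; the identifiability conclusions are not
sensitive to it, though sparser sampling degrades practical recovery.

The third scenario (`unit_N0`) keeps the benchmark composition 10:14:4 but
starts the community at total abundance 1.  By the scale gauge this
scenario's composition data are indistinguishable from those of *any*
rescaled community, which is exactly why a fit that assumes N(0) = 1 can
only ever recover the population trajectory *relative to its start* — the
fold change N(t)/N(0) — never the absolute scale.

What the generator does **not** emulate: PCR/primer bias, chimeras,
taxonomic misassignment, overdispersion beyond the depth-limited sampling,
irregular sampling designs, or more than one community per dataset.
Passing tests therefore demonstrate the identifiability properties under
idealized sequencing sampling, not robustness to real library-prep
artifacts.

## Practical identifiability (particle MCMC)

The fit treats the SDE as the latent process of a state-space model with
multinomial measurement at depth V, the initial composition fixed at the
observed t = 0 proportions and N(0) supplied.  The marginal likelihood is
estimated by a bootstrap particle filter: Euler–Maruyama propagation
between observations, multinomial log-weights, systematic resampling every
step (the lowest-variance standard scheme).  σ_i are fixed at their
generating value during fitting; only the 12 gLV parameters are sampled.
With σ = 0 and one particle the filter reduces exactly to a
product-multinomial likelihood along the deterministic Euler path, which is
asserted against an independent closed-form implementation.

The sampler is particle marginal Metropolis–Hastings with uniform priors
U(ρ − 0.4|ρ|, ρ + 0.4|ρ|) around the reference (true) values ρ and a
multivariate-normal random walk.  Stage 1 starts with a diagonal proposal
covariance of standard deviations 0.1|ρ| and, after 100 iterations,
switches to the empirical covariance of the chain history scaled by 2.38²/d
(the standard adaptive-Metropolis choice) plus a small diagonal floor
(1e−4 of the initial variances) so that a sticky early chain cannot freeze
the proposal; stage 2 restarts with stage 1's final covariance held fixed,
and only stage 2's chain is retained, thinned to
every 50th sample (40 retained at the full budget of 2000 iterations and
200 particles).  Proposals outside the prior box are rejected outright, so
every retained sample — hence every per-sample relative error — is bounded
by the ±40% prior.  A pilot stage that accepts nothing triggers a halving
of the proposal scale and a retry (at most 3, logged).  The point estimate
is the posterior mean of the retained samples; the median is reported
alongside.

The reduced budget (500 iterations, 100 particles, thin 25 → 20 retained
samples) is the package's desk-scale default and is flagged as such in all
outputs.  At this budget, on value-set-2 data, the majority of the 12
parameters are typically recovered within ±20% relative error; the result
is stochastic, so the acceptance test replicates it over three seeds and
requires two successes.  Acceptance rates at this budget are low (the
particle-likelihood noise with 100 particles makes the chain sticky); the
full budget mixes better.

Fold-change reconstruction: for each retained parameter vector the
deterministic gLV is solved from the observed initial composition scaled to
the assumed N(0), and the total N̂(t) recorded; the mean track and the
pointwise min–max envelope over retained samples are reported, each
normalizable by its t = 0 value.  Samples whose ODE solve fails are dropped
and counted.

## Numerical choices

* Deterministic integration: LSODA, rtol 1e−8, atol 1e−10 (the value-1 vs
  value-2 comparison needs error well below the 1e−6 assertion level);
  tiny negative excursions near extinction are snapped to 0.
* Simplex checks: composition rows must sum to 1 within 1e−9; the
  compositional vector field's components sum to 0 within 1e−10 by
  construction.
* x′ for total-abundance reconstruction: analytic when the trajectory
  carries its totals, centered finite differences otherwise (approximate;
  error scales with the sampling interval).
* Monomial ordering for symbolic coefficient comparison: fixed (x″, x′, x)
  ordering so equality tests are deterministic.
* Particle filter log-weights use a max-shift (log-sum-exp) and declare
  collapse — returning −inf, not raising — when every weight underflows.
* All stochastic components accept explicit seeds; seeds derived inside the
  package stay below 2³¹.

## Known limitations

* The symbolic analysis covers n = 2 only; larger n rely on numeric checks.
* Euler–Maruyama is weak order 1: ensemble means carry an O(dt) bias, and
  the SDE mean itself differs from the noise-free ODE by O(σ²) — tests
  compare against the ODE with a matching systematic allowance.
* The reduced-budget sampler is sticky (acceptance ~0.1–10%); its posterior
  spread understates the full-budget posterior's.
* Priors centered on the truth make the practical-identifiability check a
  *local* statement, as intended; nothing here addresses global
  identifiability or model misspecification.
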