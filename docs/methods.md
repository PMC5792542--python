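# Methods

## Model and assumptions

`psinet` simulates groups of individuals whose phenotypes respond
plastically to the phenotypes of their social partners, with partner
structure given by a weighted network.  The key assumptions:

* **No phenotypic feedback.**  The social environment experienced by
  an individual is built from its partners' *nonplastic* components
  `a + e`, never from their realized phenotypes.  The phenotype
  equation is therefore a one-pass linear map, not a fixed point.
* **Shared plasticity.**  All individuals carry the same interaction
  coefficient `psi_g`.  Positive values pull individuals toward their
  partners' phenotypes, negative values push them away.
* **Self-exclusion.**  An individual is never part of its own social
  environment (the weight matrix has a zero diagonal).  This single
  fact drives the "pull to the mean": in a dense network every
  individual experiences nearly the same social environment *except*
  for the removal of itself, so the social environment is a
  decreasing function of the individual's own value, reaching a
  direct–indirect correlation of exactly −1 on an equal-weight
  complete network.
* **One generation.**  Selection response is the expected
  one-generation change in the group mean under a linear fitness
  gradient, computed through the covariance identity
  `response = beta * Cov(t, z)` between total breeding values and
  phenotypes.  No explicit reproduction step is iterated; a
  multi-generation scheme is out of scope.
* **Social selection absent.**  Fitness depends on own phenotype
  only, through the gradient `beta`.

## Network generation

Positions are uniform in the unit square (no torus; edge effects are
part of the realized density, which is measured, not assumed).  A
single synchronous attraction step moves every individual 15 % of the
way toward its nearest neighbour, with nearest neighbours identified
on the input configuration and ties broken by lowest index — a
sequential update would make the result order-dependent.  Weights are
`exp(-d^2 / r)`; `r = 0` maps to the empty network (the kernel's
limit from above, since the expression is undefined at zero).
Weights strictly below the cutoff 0.05 are removed; boundary values
are kept.

The similarity preference multiplier is

    m = 0.5 + sigma * H * L(|x - y|),   L(d) = 1 / (1 + exp(20 (d - 0.5)))

with `sigma = +1` (homophily) or `-1` (heterophily) and magnitude
`H in [0, 0.5]`, applied to the nonplastic phenotype `a + e`.  The
multiplier is centred on 0.5 so that similar pairs are multiplied by
about `0.5 + H` and dissimilar pairs by about `0.5 - H` under
homophily (reversed under heterophily), and `mode="none"` bypasses
the multiplier entirely (multiplier exactly 1).  Because `m <= 0.5 + H < 1`,
switching preference on also lowers realized density — an emergent
side effect that is visible in the homophily sweeps and is the reason
sweep results are indexed by *measured* density and assortativity
rather than by `r` and `H`.

Density is the sum of realized edge weights over the maximum possible
sum (equivalently the mean weight over all dyads).  Assortativity is
the Newman-style weighted continuous-trait coefficient with every
undirected edge counted once in each direction; it is reported as
`nan` (never 0) when the network is empty or the trait variance over
edge ends vanishes.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `n` | 50 (20 also standard) | group size |
| `r` | grid 0–9, 16 log-spaced steps | interaction range of the distance kernel |
| `move_fraction` | 0.15 | nearest-neighbour attraction step |
| `edge_cutoff` | 0.05 | minimum retained edge weight |
| `psi_g` | 4 | interaction coefficient (dimensionless) |
| `beta` | 0.2 | selection gradient (fitness per trait unit) |
| `bv_dist` | uniform on [−1, 1] | breeding values, variance 1/3 (`normal_01` optional) |
| `env_var` | 0.0625 | environmental variance (trait units²) |
| `H` | grid 0–0.2, 9 steps | homophily magnitude |
| `n_replicates` | 50 | groups per grid point |

The `r` grid is spaced at an increasing rate because density
saturates in `r`; only coverage of the density axis matters, since
results are analyzed against measured density.  The homophily sweep
holds `r = 0.9`, which yields an intermediate baseline density
(≈ 0.72 at n = 50), so assortment has room to act in both directions.

## Seeding

Every replicate draws from
`numpy.random.SeedSequence(master_seed, spawn_key=(grid_index, replicate))`.
Streams are independent across cells, reproducible under the master
seed, and parallel-safe.  Within one group the draw order is fixed:
positions, then breeding values, then environmental deviations.
Sweep tables are byte-identical across reruns on one platform.

## Statistics and numerical conventions

* All sample variances, covariances and correlations use the `n − 1`
  denominator.  Undefined quantities propagate as `nan`, never 0.
* "Variance in indirect effects" is the variance of the realized
  indirect contribution `psi_g * eta`, the term that actually enters
  the phenotype; the direct–indirect correlation is computed between
  `a + e` and `eta` (multiplying `eta` by a positive `psi_g` leaves
  it unchanged; a negative `psi_g` flips its sign).
* The closed-form variance prediction is an exact algebraic
  decomposition of the phenotype equation: feeding it a group's own
  sample moments — `Var(a+e)` as the combined genetic-plus-
  environmental term (which absorbs the finite-sample `Cov(a, e)`),
  `Var(eta)` and `Cov(a+e, eta)` — reproduces the sample `Var(z)` to
  machine precision.  Feeding it population values instead gives the
  expectation.
* The empirical genetic-assortment coefficient is
  `R_hat = Cov(a_i, ahat'_i) / Var(a)`, where `ahat'_i = sum_j w_ij a_j / (n - 1)`
  is the weighted partner mean normalized by the `n − 1` possible
  partners — the same normalization as the social environment — so
  `R_hat` scales with realized connection strength.  This is the
  normalization under which the closed-form response
  `(1 + psi_g s_bar) G (1 + R psi_g) beta` is exact on equal-weight
  networks (where it reduces to `R = -s_bar / (n - 1)`) and tracks
  the simulated response across the density sweep within Monte-Carlo
  error.  Normalizing by the sum of weights instead would leave the
  coefficient density-free and systematically overstate the
  assortment term in sparse networks.  Individuals with no partners
  are excluded from the covariance; with no connected individuals
  `R_hat` is `nan` and the response prediction falls back to `R = 0`.
* The response prediction is an approximation for heterogeneous
  connection strengths; agreement tests therefore use three-standard-
  error Monte-Carlo bands per density bin rather than exactness.
* Total breeding values use the symmetric weight matrix's column
  means; with symmetric weights, incoming and outgoing strengths
  coincide, matching the equal-interaction limit of the closed-form
  model.

## What the generator emulates — and what it does not

The synthetic groups emulate spatially driven interaction structure:
individuals distributed in a plane, interacting more intensely with
closer neighbours, with optional phenotype-based preference.  They do
not emulate temporal dynamics (re-wiring, repeated observation
sampling of edges), directed or multilayer relations, heritable
variation in connection strength or in plasticity, phenotypic
feedback, or measurement error in edge weights.  Passing tests
therefore demonstrate the internal consistency of the model and its
closed-form predictions under idealized network observation, not the
behaviour of inferred networks from field data.

## Design choices where the design was open

* The similarity multiplier is centred on 0.5 with `H` as half-range;
  the verbal description (midpoint at average trait difference,
  magnitude `H`) is internally consistent under this form, whereas a
  multiplier reaching ~0 or ~1 for identical individuals would not be
  compatible with `H <= 0.2`.
* `env_var = 0.0625` is taken as authoritative for the environmental
  variance even though it is not exactly one fifth of the uniform
  breeding-value variance (1/15 ≈ 0.0667).
* Replicate-level standardization of `psi_g` is not performed: group
  means and variances fluctuate by sampling, so there is no canonical
  in-simulation standardization; `psi_g` is used on the raw trait
  scale.
* The response to selection uses the covariance identity rather than
  simulating truncation or reproduction, because the fitness model is
  a linear gradient and the identity is exact for it.

## Known limitations

* The closed-form response is only approximate off the equal-weight
  limit; deviations grow mildly with the heterogeneity of individual
  connection strengths at intermediate densities.
* Assortativity of a continuous trait on a finite network cannot
  reach 1 in practice; homophily sweeps reach measured assortment of
  roughly 0.07 at `H = 0.2`, n = 50, so directional tests pool groups
  rather than requiring large per-group coefficients.
* Degenerate inputs (empty networks, zero-variance traits) yield
  `nan` flags by design; downstream aggregation uses `nan`-aware
  reductions.
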