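# Methods

## Model

`rangex` simulates a range expansion of immortal, immobile individuals in an
unbounded two-dimensional continuum. Each generation, every established
individual draws an independent Poisson(1) offspring count (time is measured
in mean generation times). Each offspring disperses from its parent in a
uniformly random direction, with a distance drawn from the two-part jump
kernel

    J(r) = p / rb                               r <= rb
    J(r) = (1 - p) mu rb^mu r^-(mu + 1)         r >  rb

so that `p` is exactly the probability of landing within the interaction
radius `rb`, and the tail is a pure power law with exponent `mu`. Sampling
is by inverse transform: `r = u rb / p` for a uniform deviate `u < p`, and
`r = rb ((1-u)/(1-p))^(-1/mu)` otherwise; both branches meet at `r = rb`.

Density regulation is local and individual-based: an offspring establishes
only if strictly fewer than `K` established individuals lie within the
*closed* disc of radius `rb` around its landing point; otherwise it dies
immediately. The disc is the continuum analog of a deme, and
`rho = K / (pi rb^2)` is the saturation density. Established individuals
never move, die, or change allele; neutral allele labels are inherited
exactly (no mutation).

Reference time scales: a pioneer's disc fills at logistic rate ~ `p`
(`tau_s = 1/p`), while a saturated disc emits long-range migrants at rate
`K (1 - p)` (`tau_j = 1/(K(1-p))`). The instant-saturation, founder-takes-all
regime assumed by lattice models requires `tau_s << tau_j`, i.e.
`p/(1-p) >> K`; the crossover `p* = K/(K+1)` is exposed by
`criterion_fast_local`.

## Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| `mu` | kernel tail exponent (> 0; smaller = heavier tail) | required |
| `p` | local dispersal probability in [0, 1] | required |
| `K` | local carrying capacity (integer >= 1) | required |
| `rb` | interaction radius; the length unit | 1 |
| `n0` | founder count, Gaussian-spread around the origin | `10 K` |
| `init_sigma` | founder spread (s.d. per coordinate) | `2 rb` |
| `m_stop` | stop once the population reaches this size | `1e4 n0` |
| `seed` | RNG seed; one generator drives the whole run | 0 |

The founder population is exempt from the density check (its transient local
density may exceed `rho`), matching the initialization of the expansions the
model targets.

## Scheduling and determinism

One sweep is one generation. All offspring of a generation are pooled,
shuffled uniformly, and processed sequentially; an offspring established
earlier in the sweep counts toward the density check of later offspring in
the same sweep. This removes parent-order bias while keeping the density
feedback within a generation. A single seeded `numpy` generator drives
initialization, offspring counts, dispersal, and processing order, so runs
are bit-reproducible given the seed.

Internally the neighbor index is split into a cell-sorted (CSR) layout for
individuals established before the current generation and a linked-cell
hash grid for the current generation's newcomers. Because the former part is
immutable during a sweep, each candidate's "static" neighbor count is
precomputed with candidates visited in spatial order (cache locality); the
sequential pass then adds same-generation contributions in the shuffled
order. The split is purely an optimization: counts, and hence trajectories,
are identical to a naive sequential implementation.

Numerical conventions: the disc boundary is closed (distance exactly `rb`
counts — a measure-zero choice fixed for reproducibility); recorded neighbor
counts in the birth log are clamped at `K` (survival only needs the
comparison), while `count_neighbors` always returns the exact count; `p = 0`
and `p = 1` reduce cleanly to the pure-tail and pure-local kernels.

## Analyses

**Local saturation.** Pioneers are survived offspring with zero neighbors at
establishment and no established individual within `10 rb` (the isolation
radius is a parameter; the threshold separating "empty region" from the
frontier is genuinely open). Since individuals are immortal and immobile,
disc occupancy at any time is reconstructed exactly from establishment
times. The ensemble-mean occupancy is fit by the logistic
`n(dt) = K'/(1 + (K'-1) e^(-lam dt))` with `n(0) = 1` pinned (the pioneer),
a two-parameter least-squares fit (scipy, tolerance 1e-10, rate initialized
at `p + 0.05` when `p` is known, else 0.3; plateau initialized at the
maximum observed count). The saturation time is the closed form
`t_sat = (2/lam) ln(K' - 1)` (time to reach `K' - 1`), zero when `K' <= 2`.
Headline fits use only traces whose tracking window (default 15-200
generations, depending on the analysis) fits inside the run: truncated
traces drop out of late-dt bins and would bias the pointwise mean. The
fitted plateau `K'` need not equal `K` — partial disc overlaps let packing
exceed `K` per disc — so `K'/K` is reported rather than assumed to be 1.

**Heterozygosity.** `H = 1 - sum_i f_i^2` over allele frequencies, locally
(within a pioneer's disc, measured by default when occupancy first reaches
the fitted plateau, else at the end of the run — the measurement instant is
another open choice) or globally. Local values are normalized by
`H_N = 2 (1/K)(1 - 1/K)`, the heterozygosity of a full disc with exactly one
non-founder allele: normalized values above 1 diagnose the breakdown of
founder-takes-all. Global trajectories are pooled over replicate runs into
log-spaced bins of `M/M0` (20 bins per decade) with the within-bin standard
error of the mean as the uncertainty band.

**Growth and kernel inference.** The core radius is the mass-equivalent
radius `ell = sqrt(M/(pi rho))`. Jump-driven growth obeys the time-doubling
self-consistency `ell(t)^(d+mu) ~ t ell(t/2)^(2d)`; fitting
`t ell(t/2)^(2d) = B ell(t)^nu` by unweighted OLS in log space yields an
inferred exponent `mu_i = nu - d`. Only even times in the late half of a
trajectory are used, so `t/2` lies on the recorded integer grid (no
interpolation) and the pre-hierarchy transient is excluded. Per-run fits are
aggregated with a percentile bootstrap of the mean (2000 resamples,
seeded). The machinery has an exact oracle: for `ell = A t^beta` the fit
returns `nu = 1/beta + 2d` to machine precision, so `beta = 1/(mu - d)`
recovers `mu_i = mu` for `d < mu < d+1`, linear growth (`beta = 1`) maps to
the marginal kernel `mu_i = d + 1`, and the marginal kernel `mu = d` is the
steep-growth limit `beta -> inf`, where no finite power law exists (the true
asymptote is stretched-exponential); it is checked at `beta = 50`, where the
identity gives `mu_i = d + 0.02` exactly.

**Lattice reference.** A deliberately minimal deme model for regime
comparisons: demes are occupied or empty, occupied demes emit Poisson(1)
migrants per generation with pure power-law distances (r >= 1 lattice unit)
rounded to the nearest deme; the first successful migrant takes the deme
permanently. The seed cluster is a filled disc of radius 3 demes. Rounding
of displacements and the deme/rb length correspondence are modeling choices;
only qualitative regime classifications (heterozygosity plateau for
`mu < d`, steady decay for `d < mu < d+1`) are asserted against it.

## What the tests do and do not show

Simulation-backed tests run reduced ensembles (10-20 replicates to
`M/M0 = 1e2-1e4`, versus hundreds of replicates to `M/M0 = 1e4` and beyond
in full studies). They establish directions and orderings — growth
acceleration as `p` falls, higher global diversity under slow local
dynamics, plateau-vs-decay regime classification — not converged ensemble
values. The acceptance script reports the heterozygosity-decay percentages
at `M/M0 = 1e4` from 2 replicates (K = 100, runs to M = 1e7) and 12
replicates (K = 10, runs to M = 1e6), the largest ensembles that fit the
single-CPU runtime envelope.

A balanced two-allele expansion is a poor self-averager: whether one allele's
satellites happen to dominate early is close to a coin flip per run, so the
final `H` of individual runs at `K = 10, p = 0.5, mu = 2.5` spreads over
roughly 0.36-0.50 (s.d. ~ 0.05, and the lattice model shows the same
heavy-tailed spread). The ensemble-*mean* decay is therefore resolved to a
few percentage points at these replicate counts, and desk-scale means sit
below fully converged ones whenever the ensemble misses the rare
deep-coarsening runs that drag the mean down. Decay estimates from the
script should be read with that uncertainty in mind; the robust desk-scale
statements are the orderings (slow local dynamics retain more diversity
than fast at every scale measured) and the regime classifications, which
the test suite asserts directly.

The generator emulates the idealized model exactly; it does not emulate
features of real populations that the model itself excludes (mortality,
movement, mutation, heterogeneous habitat), so passing tests validate the
algorithmic contract, not ecological realism.

## Known limitations

- Two dimensions only in the engine (`d` is symbolic in analysis formulas).
- No post-establishment death, movement, competition, or mutation; no
  lineage tracking, so same-allele multiple incursions are invisible to the
  local-diversity diagnostic.
- The pioneer isolation radius and the local-H measurement instant are
  heuristic parameters (defaults `10 rb` and first-plateau-hit).
- Extremely heavy tails (`mu` near 0) produce astronomically distant
  satellites; positions are exact floats and the index handles them, but
  growth-curve statistics at such `mu` need far larger populations than the
  desk-scale defaults.
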