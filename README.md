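# rangex

Continuum-space, individual-based simulation of range expansions driven by
long-range dispersal, with explicit local density regulation — plus the
analysis toolkit that goes with it: local saturation dynamics around
pioneers, local and global neutral heterozygosity, core-radius growth
curves, and kernel-exponent inference.

## The problem

When an expanding population (an invasive plant, a spreading epidemic)
disperses offspring with a fat-tailed jump kernel, rare long jumps seed
satellite colonies far ahead of the densely occupied core. Classic lattice
models of this process assume each local habitat ("deme") saturates
instantly when the first migrant arrives, so the founder's descendants take
the whole deme. Real populations live in continuous space and saturate
local neighborhoods at a finite rate, which lets later migrants establish
alongside the pioneer. `rangex` is for population geneticists and
ecological modelers who want to quantify what that difference does to
population growth and to the fate of neutral genetic diversity.

## The model

Individuals occupy an unbounded 2D plane, reproduce as a rate-1 Poisson
process (one sweep = one generation), and never move or die once
established. Offspring disperse a distance drawn from

    J(r) = p / rb                     for r <= rb,
    J(r) ~ (1 - p) r^-(mu + 1)        for r > rb,

in a uniform direction: `p` is the probability of a local jump, `mu` the
power-law tail exponent. An offspring establishes only if fewer than `K`
individuals already occupy the disc of radius `rb` around its landing
point (`rho = K / (pi rb^2)` is the saturation density). Neutral alleles
are inherited without mutation.

Key derived quantities:

- `p* = K/(K+1)` — the local dispersal probability above which local
  saturation outpaces long-range seeding (`p/(1-p) >> K` is the
  instant-saturation regime; `criterion_fast_local`).
- `H = 1 - sum_i f_i^2` — neutral heterozygosity; locally normalized by
  `H_N = 2(1/K)(1 - 1/K)` to diagnose founder-takes-all breakdown.
- `ell(t) = sqrt(M/(pi rho))` — mass-equivalent core radius, with the
  time-doubling relation `ell(t)^(d+mu) ~ t ell(t/2)^(2d)` whose fitted
  exponent `nu` yields an inferred kernel exponent `mu_i = nu - d`.

A minimal lattice (instant-saturation, founder-takes-all) model is included
as a comparison oracle, and `docs/methods.md` details every numerical
choice.

## Worked example

Eight replicate expansions at `K = 10`, `mu = 2.5`, mostly-local dispersal
(`p = 0.9`), run to 300x the initial population:

```python
import rangex as rx

params = rx.SimParams(mu=2.5, p=0.9, K=10, m_stop=300 * 100, seed=5)
runs = [rx.run(params, seed=5 + i) for i in range(8)]

per_run = [rx.fit_run(r).mu_i for r in runs]
mu_hat, (lo, hi) = rx.bootstrap_mu_i(per_run, seed=0)
print(f"inferred kernel exponent: mu_i = {mu_hat:.2f} (95% CI [{lo:.2f}, {hi:.2f}])")

H = rx.global_het_vs_size(runs)
print(f"global heterozygosity: {H['H_mean'].iloc[0]:.3f} -> "
      f"{H['H_mean'].iloc[-1]:.3f} at M/M0 = {H['M_over_M0'].iloc[-1]:.0f}")
```

prints

```
inferred kernel exponent: mu_i = 1.84 (95% CI [1.48, 2.22])
global heterozygosity: 0.500 -> 0.375 at M/M0 = 292
```

The inferred exponent undershoots the true `mu = 2.5`: with `p = 0.9 < p*`
local discs are still filling while they emit migrants, so the population
grows faster than the instant-saturation hierarchy predicts — the
systematic `mu_i < mu` bias that motivates the continuum model (short
trajectories amplify it; the bias shrinks only as `p -> 1`). The balanced
two-allele heterozygosity starts at 1/2 and is eroded by founder events as
this `d < mu < d+1` kernel predicts.

The same experiments are scriptable from a shell:

```sh
rangex simulate --mu 2.5 --p 0.9 --K 10 --m-stop 30000 --seed 5 \
       --replicates 8 --out-dir out/
rangex infer-mu out/*.growth.tsv
rangex lattice-simulate --mu 2.5 --m-stop 20000 --out-dir out/
```

Outputs are tab-separated tables (growth curves `t, M, ell[, H]`; snapshots
`id, x, y, allele, t_birth`; birth logs) with a JSON manifest recording all
parameters and the seed; identical manifests reproduce bit-identical runs.

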