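# Methods

## Model and conventions

`phylofe` simulates multi-type birth–death–mutation–sampling (BDMS)
processes.  Time `τ` is measured *before the present*: the process starts at
`τ = t_max` with a single lineage of type `a ~ Cat(π)` and runs to `τ = 0`.
All branch lengths are `parent.time − child.time`.  Lineages evolve
independently given their type (no density dependence): type-`a` lineages
split into `(a, b)` daughters at rate `λ_ab(τ)`, die at rate `μ_a(τ)`, mutate
anagenetically at rate `γ_ab(τ)` (`b ≠ a`), and are sampled serially at rate
`ψ_a(τ)`, dying on sampling with probability `r_a(τ)`.  Concerted sampling
events (CSEs) at `t_0 = 0 < t_1 < … ≤ t_max` sample extant type-`a` lineages
independently with probability `ρ_al` (death-given-sampled `q_al`).  The
present-day CSE always exists; `ρ_{·,0} = 0` encodes "no present-day
sampling".

Rates are one of three realizations: constant; **piecewise-constant**,
right-continuous in `τ` with jumps at the declared breakpoints (the value on
the smaller-`τ` side applies strictly below a breakpoint — this convention
makes inter-breakpoint waiting-time inversion exact); or a **grid
interpolant** (linear).  Every rate exposes `upper_bound_on(lo, hi)`, a
finite bound on its supremum over the window, which is the contract the
thinning sampler relies on.  `r_a` and the CSE probabilities use the same
machinery restricted to [0, 1].

The reconstructed phylogeny keeps exactly the lineages ancestral to at least
one sampling event.  The empty outcome is an explicit sentinel object, never
`None`; all consumers handle it.

## Full simulation

The full simulator is breadth-first in biological time.  It maintains, per
type, the set of extant lineages in an indexable array with swap-remove plus
a token→position map, so insertion, removal and uniform draws are O(1) in the
population size.  Each iteration draws the time and category of the next
event of the *superposed* population process (O(d²) work), then lands it on a
uniform random extant lineage of the drawn type:

* all rates constant — the waiting time is exponential at the total rate;
* all rates piecewise-constant — exact inversion of the integrated intensity,
  carrying one exponential deviate across constant segments;
* otherwise — windowed thinning: candidates from a homogeneous process at the
  per-window upper bound, accepted with probability intensity/bound.  Windows
  are `max(0.5, interval/64)` time units wide, a balance between bound
  tightness and bound-computation overhead.

The event category is drawn *after* the event time is fixed, from the
intensity decomposition at that time (valid for superposed Poisson
processes).  A proposed event time that falls at or beyond the next CSE time
is discarded and the CSE applied instead (ties break toward the CSE).  If the
extant population ever exceeds the capacity `n_max`, the partial tree is
returned with a flag rather than raising, so callers can account for the
discarded work.  Replicate sets draw each replicate from an independent child
stream spawned from the master seed, making them reproducible and
order-independent.

Pruning runs in linear time: a postorder pass marks nodes with sampled
descendants, and a rebuild pass applies the two single-survivor birth rules
(dissolve when the surviving daughter has the parent's type; convert to an
anagenetic-mutation node when it does not).  Serial-sampling survivors are
kept as unary nodes; a survivor whose continuation has no sampled descendant
is truncated at the sampling node.  The stem origin at `t_max` is kept as the
root of the reconstructed tree so that both pipelines use the same origin
convention.

## Non-observation ODE and the forward-equivalent map

`E_a(τ)` — the probability that a type-`a` lineage at `τ` leaves no sampled
descendant — is integrated in increasing `τ` from `E_a(0⁻) = 1`, with the
jump `E_a(t_l⁺) = (1 − ρ_al) E_a(t_l⁻)` at each CSE (the minus side is the
limit from below, i.e. the biologically *post*-CSE value).  The integrator is
classical fixed-step RK4 on a uniform grid within each inter-CSE interval,
**512 steps per time unit** by default (minimum 10 per interval).  At `h =
1/512` the RK4 global error on these O(1)-magnitude, smooth systems is
~1e-11–1e-12, comfortably below the default 1e-8 refinement tolerance, and
the solve stays sub-second for horizons up to ~50 time units in pure Python;
finer grids cost linearly and buy nothing at the checked tolerance.  An
optional tolerance check re-solves at twice the resolution and reports the
achieved sup-discrepancy.  Between grid points the solution is interpolated
with monotone piecewise cubics (PCHIP), whose values never leave the range of
the local grid values — that shape-preservation is what makes cheap, exact
window extrema (hence valid thinning bounds) possible for the transformed
rates.  Queries at a CSE time return the `τ⁻` limit by default, with an
explicit one-sided API for the map, which needs both.

With `p_a = 1 − E_a`, the forward-equivalent model is

```
π^FE_a ∝ π_a p_a(t_max)      λ^FE_ab = p_b λ_ab       μ^FE ≡ 0
ψ^FE_a = ψ_a / p_a           r^FE_a = r_a + (1 − r_a) E_a
γ^FE_ab = (p_b / p_a)(γ_ab + E_a λ_ab)    (b ≠ a)
ρ^FE_al = ρ_al / p_a(t_l⁺)   q^FE_al = q_al + (1 − q_al) E_a(t_l⁻)
```

The `ψ^FE` and `ρ^FE` entries **divide** by the observation probability:
conditioning a lineage on being observed raises the apparent sampling rates.
Two requirements pin the division form down.  First, consistency:
`E_a(0⁺) = 1 − ρ_{a,0}`, so only division yields complete present-day
sampling `ρ^FE_{a,0} = 1` (multiplication would give `ρ²`).  Second, Monte
Carlo: the distributional-equivalence test with serial sampling plus an
intermediate CSE (`tests/test_fe.py`) rejects the multiplicative reading and
accepts the division form.  The transformed rates are implemented as exact
closures over the PCHIP interpolant (not re-gridded), with thinning bounds
assembled from grid extrema; divisions are guarded by an observation-
probability floor of 1e-12 — a type whose observation probability falls
below the floor *and* has a nonzero transformed numerator raises an
infeasibility error rather than producing unbounded rates.  The ODE solve and
the map are computed once per parameter bundle and memoized across
replicates.

`simulate_reconstructed` runs the full simulator on the transformed model
(its full tree *is* the reconstructed tree).  Unconditional simulation first
draws a Bernoulli with the non-emptiness probability `1 − Σ_a π_a
E_a(t_max)`.  A finite `n_max` under the transformed model conditions on the
reconstructed tree's maximal width: capacity-exceeded replicates are rejected
and redrawn.

## Efficiency accounting

The cost of either pipeline is proportional to the expected number of
simulated events per non-empty reconstructed tree; the speedup is
`E[#nodes(T)] / E[#nodes(R(T))]` (Wald's identity folds the empty-tree
retries into the unconditional expectations).  **Counting convention:** every
node except the stem-origin marker counts — births, deaths, mutations,
serial samples, sampled CSE tips, *and* present-day tip markers whether or
not they were sampled, because the simulator spends one event's worth of work
advancing and Bernoulli-sampling each survivor.  Counting unsampled present
tips is what makes the trivial stick process cost Θ(1) per attempt and hence
speed up by exactly `1/ρ`; excluding them would make the stick's full-side
expected count `ρ` and the ratio 1, contradicting the method's basic
accounting.  Both expectations are computed by time discretization of the
linear mean-field ODE for per-type expected extant counts (RK4, 256
steps/unit, trapezoidal accumulation of the total event intensity), the
reconstructed side by running the same computation under the transformed
model and rescaling by the non-emptiness probability.  Monte-Carlo estimates
report delta-method standard errors for the ratio of means.

For a single-type constant-rate process over one time unit with extant
sampling probability `ρ`, the closed form is `(1+μ)/ρ` at `λ = μ` and
`(1/ρ)[1 + μ(e^{λ−μ} − 1)/((λ−μ) e^{λ−μ})]` otherwise (branch switch at
`|λ−μ| < 1e-8`; the branches agree in the limit).  Algebraically this equals
`(L + D)/(ρ L)` with `L = e^{λ−μ}` (expected survivors) and
`D = μ(e^{λ−μ}−1)/(λ−μ)` (expected deaths): it is **exactly the ratio of
expected leaf counts** of the full and reconstructed trees, and the
brute-force verification checks it against the Monte-Carlo leaf-count ratio,
where agreement is exact up to sampling error.  The all-events node ratio
converges to the same value as trees grow but sits a few percent below it at
horizon 1 (e.g. 19.25 vs 20 at `λ = μ = 1`, `ρ = 0.1`); the node ratio is
therefore verified against the mean-field ODE instead.

## Statistics and validation

Per-tree summaries: event count (nodes excluding the stem marker), leaf
count, branch length per type and total, subtree-size counts, and per-type
lineage counts at time cross-sections (an edge `(τ_c, τ_p]` counts at `τ`
iff `τ_c < τ ≤ τ_p`, so counts are right-continuous).  Blocks are maximal
connected same-type subtrees; each non-root node is assigned to the block of
its incoming edge, so a mutation node belongs to its parent-side
(pre-mutation) block and a birth node to its parent-type block — this makes
blocks partition the edges, block branch lengths sum to the total, and block
event counts sum to the event count.

The equivalence suite draws matched samples of non-empty reconstructed trees
from both pipelines and compares every statistic with two-sided Mann–Whitney
U and two-sample Kolmogorov–Smirnov tests at α = 0.001, reporting raw
per-statistic p-values (a Bonferroni note is attached; the battery is ~12
statistics).  The KS null is asymptotic and only approximate for discrete
counts, so small-count KS p-values deserve caution.  Jointly constant
samples (e.g. stick leaf counts) are reported as non-rejections.

## Problem sizes, seeds and flakiness budget

The shipped validation battery uses: 500 trees per arm for the two-type
distributional-equivalence study (two-type Fit/Unfit model, `λ = (1, 0.25)`,
`μ = 0.25`, `γ_{F→U} = 0.8`, `γ_{U→F} = 0.1`, `ρ = 0.5`, `t_max = 20`,
cross-section at `τ = 4`); 1e5 full simulations per sampling probability for
the closed-form speedup check; 1.2e3–2e4 replicates per model for the
non-emptiness checks; 200 random trees for the pruning-oracle comparison.
All stochastic tests are seeded and deterministic as shipped.  Under reseeding
they are designed for ≥3-SE (binomial/delta-method) margins or α = 0.001
non-rejection surfaces: with roughly two dozen such assertions, the expected
flake rate under a fresh seed is of order a few percent for the suite as a
whole — any single failure under a new seed should be re-run and investigated
only if it repeats.  The null-calibration test has the widest legitimate
spread (binomial on 200 repetitions).

Two-type preset parameters leave the root-type distribution unstated in
their sources; the presets use uniform `π = (1/2, 1/2)` (the transformed-rate
quantities are π-independent).  The illustration model's horizon is set to
`t_max = 10`; the relative-birth-rate bound is insensitive to it.  In the
massive-subsampling preset the death rates are assigned as `μ_Fit = 0.25`,
`μ_Unfit = 0.5`: with the fit type strongly supercritical the mean-field
growth rate is 0.528, giving ~4e10 extant lineages at `t_max = 47` and
conditional sample sizes in the tens to hundreds at `ρ = 1e-9` — the regime
the preset exists to demonstrate.  Assigning the larger death rate to the
fit type instead collapses growth to 0.311 (~2e6 lineages) and makes almost
every non-empty sample a singleton, which defeats the preset's purpose.

## What passing tests do and do not show

The simulators *are* the data generators here, so the validation is
self-referential in one direction (both arms share the event-sampling
machinery) and independent in the others: waiting-time laws are checked
against closed-form inversion oracles, the ODE against Riccati closed forms
and brute-force Monte Carlo, pruning against an exhaustive-search reference,
and the two pipelines against each other — the last being the substantive
claim, since they share almost no code path (constant-rate exact sampling
plus pruning vs thinned time-inhomogeneous sampling of transformed rates).
Distributional agreement on a dozen scalar statistics is evidence, not proof,
of equality of the full tree laws.  Real data features outside the model —
density-dependent rates, continuous trait spaces, sequence evolution along
branches, epoch-varying sampling effort beyond the CSE grid — are out of
scope.

## Known limitations

* `get_next_event` is O(d²) per event; very large type spaces would want a
  different event-selection structure.
* Thinning efficiency degrades when a transformed rate is sharply peaked
  inside a window (e.g. `ψ^FE = ψ/p_a` near the present under very sparse
  sampling); windows are fixed-width rather than adaptive.
* The mean-field node-count ODE gives expectations only; it says nothing
  about the variance of the speedup, for which the Monte-Carlo estimator
  (with SEs) is provided.
* Piecewise-constant rates must declare their breakpoints; arbitrary
  black-box rate callables without an upper-bound contract are deliberately
  unsupported.
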