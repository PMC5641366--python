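# Methods

## The stochastic model

Each individual *i* of a finite simple undirected graph draws, once and for
all, an initial status (infective with probability `1 − z_i − y_i`,
susceptible with `z_i`, recovered/vaccinated with `y_i`), an infectious
period `μ_i ∈ [0, ∞]`, and for each neighbour *j* a contact delay
`ω_{ji} ∈ [0, ∞]` measured from the moment *i* becomes infected. *i* makes
an infectious contact to *j* iff `ω_{ji} < μ_i` (the tie `ω = μ`, a
null event for continuous laws, counts as no contact). Susceptibles are
infected at the first infectious contact they receive; infecteds recover
when their period ends. Draws are independent across individuals and of the
initial statuses, but within an individual the set `{−μ, ω_j (all j)}` may
be positively dependent (associated). Because all behaviour is fixed at
draw time, infection times are exactly first-passage (shortest-path) times
from the seed set through the effective edge delays — the simulator is a
static percolation computation with no event queue, and its replicates are
drawn vectorized from a single seeded `numpy` generator (one generator
rather than per-replicate spawned substreams: the output is a deterministic
function of the seed either way, and vectorized inverse-CDF sampling is two
orders of magnitude faster in this workload).

**Association via a common shock.** The only dependent family shipped is a
Bernoulli mixture: with probability `π` an infected individual adopts
disease-combating behaviour, slowing contacts (`β₁ ≤ β₀`) *and* shortening
the infectious period (`γ₁ ≥ γ₀`); conditional on the shock, delays and
period are independent exponentials drawn by inverse CDF from independent
uniforms. Every member of `{−μ, ω_j}` is then a monotone function of
independent variables sharing one shock, so the set is associated by the
closure property of association under non-decreasing transforms. The
induced transmission kernel is the closed-form mixture
`f(τ) = π β₁ e^{−(β₁+γ₁)τ} + (1−π) β₀ e^{−(β₀+γ₀)τ}`, which is what
`common_shock_kernel` returns and what the sampler is tested against.

## Transmission kernels

`f(τ)` is a sub-probability density; its mass `p` is the probability that
an edge ever transmits. Families: Markovian (`β e^{−(β+γ)τ}`,
`p = β/(β+γ)`), fixed infectious period (`β e^{−βτ} 1{τ<R}`,
`p = 1 − e^{−βR}`), generic independent contact×survival products (mass by
adaptive quadrature to the horizon where both factors drop below 1e−12,
capped at 1e4 with a warning), the common-shock mixture, and tabulated
grids (values between tabulated points are interpolated linearly and the
sup bound is taken over the table only — a spiky user kernel can evade it,
which we document rather than solve). `μ = ∞` / `ω = ∞` are `+inf`
sentinels throughout.

## Discretization

One uniform grid `0, dt, …, t_max` is shared by every solver; all
convolutions use the composite trapezoid rule, so every cross-model
comparison is grid-aligned and carries the same `O(dt²)` quadrature error.
The fixed-recovery kernel jumps to zero at `τ = R`; evaluating the jump
node at the half-value `β e^{−βR}/2` makes the two cells adjacent to the
jump cancel their leading `O(dt)` errors, preserving second-order accuracy
of the convolutions (verified by the dt-halving test). Defaults: `dt =
0.005`, `t_max = 4` for time-course comparisons; long-time ("t = ∞")
computations integrate to `t = 80` (or 160 where round-off-level residuals
are asserted) and are always compared against the algebraic root rather
than trusting the horizon.

## Message passing

The messages solve
`F[i←j](t) = 1 − ∫₀ᵗ f_ij(τ)(1 − y_j − z_j ∏_{k∈N(j)\i} F[j←k](t−τ)) dτ`,
discretized as above and iterated to a fixed point (Picard, full-sweep
Jacobi updates) from the constant-1 start, tolerance 1e−10 in sup norm,
at most 500 sweeps. The iteration map is monotone in the messages, so the
upper start descends to the maximal feasible solution; the solver asserts
this monotonicity every sweep. `uniqueness_check` additionally iterates
from the lower envelope `F = 1 − ∫₀ᵗ f` (the all-infected solution, below
every feasible one) and reports the sup distance between the two limits —
a numerical certificate of uniqueness on the given instance. Messages are
stored densely per directed edge and time index (`O(|E|·T)` memory);
per-direction heterogeneous kernels (`f_ij ≠ f_ji`) are accepted.

Marginals: `S_i = z_i ∏_j F[i←j]`, `R_i = y_i + r_i ∗ (1 − y_i − S_i)`
(the convolution is an exact index shift when the infectious period is a
point mass), `I_i` by complement. On trees these equal the exact marginals
up to quadrature error; on cyclic graphs they are one-sided bounds, which
the experiments verify against the exact oracle with tolerance 5e−3.

## Homogeneous system, final size, thresholds

For arc-transitive *n*-regular graphs all messages coincide and the system
is the scalar Volterra equation of the README. Arc-transitivity is **not**
verified algorithmically (graph-automorphism search is out of scope): the
bundled generators document which families are genuinely symmetric
(complete, cycle, ring lattice) versus test-only trees (star, balanced
tree, path), and the solvers trust the caller. The Markovian ODE route and
the fixed-recovery DDE route (method of steps; the delay must be a
grid multiple so the delayed argument stays grid-aligned; half-step stage
values interpolate the computed history linearly) are integrated with a
fixed-step classical 4th-order scheme on the same grid, and agree with the
Volterra route to ≤ 5e−4 at `dt = 0.005`.

Final size: `u = F(∞)` solves `u = 1 − p + py + pzu^{n−1}`. The map is
convex in `u` with non-negative value at 0 and non-positive value at 1, so
bisection (tolerance 1e−14 on `u`) finds the unique sign change; when the
value at 1 vanishes (`p = 0` or `z = 1 − y`) the largest root `u = 1` is
returned — the no-outbreak branch, which is the epidemiologically relevant
one at criticality. A major outbreak is impossible when `R₀ = (n−1)p ≤ 1`
or `y ≥ 1 − 1/R₀`; the boundary `y = 1 − 1/R₀` is a double root of the
final-size equation, so the "no outbreak ⇒ S(∞) = z" assertion is tested
at parameters strictly inside the no-outbreak region (the root there is
within 1e−10 of `z` already at `z = 1 − y − 1e−12`; at the double root the
defect decays only like `√ε`). The mean-field relation
`S/(1−y) = e^{−R₀(1−S−y)}` is solved the same way (`1 − y` returned when
`R₀(1−y) ≤ 1`, otherwise the unique interior root by Brent) and is
verified as the `n → ∞` limit of the network final size with
`p = R₀/(n−1)`, `z = 1 − 1e−6`.

The dynamic-vs-algebraic final-size check runs over a small `(n, p)`
lattice chosen off-critical (`|R₀ − 1| ≥ 0.25`): at `R₀ = 1` the approach
to the final size is algebraically slow and no fixed horizon stands in for
`t = ∞`, so near-critical points would test the horizon, not the root.

## Pairwise model

For Poisson contacts independent of recovery, the closed singles/pairs
system (with its two memory integrals and initial-infective source terms)
is equivalent to the homogeneous message system through
`[S] = N·S_mes`, `[SS] = nNz²F^{2(n−1)}`,
`[SI] = nNzF^{n−1}(−Ḟ/β)`. The cheap route reads these off a solved
message system (`Ḟ` by centred differences, one-sided second-order at the
ends); the direct route integrates the integro-differential system with
Heun stepping, accumulating the `exp(−∫ β(n−1)/n [SI]/[S])` weight through
its running log-integral so each step costs `O(t)` (the solve is `O(T²)`
overall). Division by `[S]` is guarded: if `[S] = 0` the corresponding
right-hand sides are set to zero, matching the limit. The direct route
requires a continuous recovery density; for a point-mass infectious period
(where delta source terms would appear) it refuses and the message route
with the DDE solver must be used instead.

## Kermack–McKendrick

The renewal equation is integrated in `Ṡ` form — the `Ṡ` history is stored
and convolved, rather than differentiating a computed `S` — with the
implicit diagonal term of the trapezoid memory solved exactly within each
step and the state update iterated to consistency (an `O(dt²)` scheme).
The convergence experiment fixes `f_n = f*/n` exactly, so the scaling
error of the limit theorem vanishes by construction and only the genuine
`O(1/n)` model distance is measured; it is restricted to continuously
differentiable kernels (the fixed-recovery kernel violates that hypothesis
and is excluded). The ordering check compares, on one grid: the mass-action
ODEs, the homogeneous message system with `n` = the graph degree, and the
exact master-equation marginals, with tolerance 1e−6 on the KM side (the
inequality is strict in theory, and discretization error is the only slack
needed) and 5e−3 against the oracle.

## Exact oracle and simulator validation

For Markovian dynamics on at most 10 nodes the Kolmogorov forward
equations over all `3^N` network states are assembled as a sparse
generator (per-node recovery at rate γ; infection at β × the number of
currently infected neighbours) and propagated with Krylov
matrix-exponential action on the whole time grid; marginals are obtained by
summing over states. Initial laws are products of per-node
`(z, 1−z−y, y)`.

Simulator validation compares 10⁵-replicate empirical marginals on the
3-node path against the oracle pointwise, normalizing by the binomial
standard error computed from the *exact* probability (so the band never
collapses where the empirical count is zero). The "within 3σ everywhere"
band is applied at ~2400 correlated grid comparisons; the observed sup of
|deviation|/σ is typically 0.7–0.9 but, being an extreme statistic, can
exceed 1 for occasional seeds — a property of the band, not of the
simulator. Unit tests run reduced replicate counts against a widened 4σ
band; the full-scale seeded check lives in the acceptance tests. The
association sampler is validated against the closed-form mixture mass
(`p = 0.35` for the reference instance `π = 0.5`, `β = (1, 0.5)`,
`γ = (1, 2)`) and by the sign of all pairwise sample correlations of
`{−μ, ω₁, ω₂}`.

## What the synthetic instances do and do not show

All fixtures are generated programmatically: small named graphs (paths,
stars, cycles, complete graphs, ring lattices, balanced trees) and
parametric kernels at desk scale (≤ 10 nodes for oracle comparisons, grids
of ≤ 16 001 points, 10⁵ Monte-Carlo replicates). These scales exercise
every structural property the models possess — exactness, bounds,
uniqueness, equivalences, limits are statements that hold at any scale —
but they do not probe large-graph performance, heavy-tailed degree
structure, or kernels outside the shipped families; the per-edge message
solver is dense and `O(|E|·T)` in memory by design. Infinite lattices
(square, Bethe) satisfy the homogeneous symmetry assumptions but cannot be
represented as explicit graphs here; the homogeneous analytic system
stands in for them, which is a restriction of scope, not of the
mathematics.

## Known limitations

* General associated joint laws beyond the common-shock family would need
  a user-supplied conditional kernel `f(τ) = h(τ) P(μ > τ | ω = τ)`; the
  package does not infer it from a joint sampler.
* The direct pairwise route omits the delta-recovery case (see above).
* Arc-transitivity of user graphs is trusted, not checked.
* The sup bound of tabulated kernels is certified only at tabulated points.
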