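# Methods

## Models and assumptions

All models are mass-action binding schemes analyzed at steady state.
Binding and unbinding are assumed fast relative to downstream processes, so
the equilibrium describes the immediate response of the pathway before
receptor- or ligand-level feedback acts. Ligands are soluble and present in
large excess, so receptor binding does not deplete them: the free ligand
concentration `C` is a fixed parameter (the finite-pool extension relaxes
this). The medium is well mixed — every cell sees the same `C`.

Units are arbitrary throughout: ACU for ligand concentrations, ARU for
receptor amounts. Affinities are association constants, so the equilibrium
relations read `P = K_P·C·A` (partial complex) and, depending on the
architecture, `F = K_F·A·P`, `F = K_F·P²`, or `F = K_F·P·B` (full complex).
No internal rescaling is performed; the dimensionless groups that govern
behaviour are `K_P·C` and `K_F·A⁰` (plus `A⁰/B⁰` for heterodimers).

Stoichiometric conservation per architecture:

* `AL`: `A + F = A⁰`
* `ALA`, `LAAL`: `A + P + 2F = A⁰` (a full complex holds two subunits)
* `ALB`: `A + P + F = A⁰` and `B + F = B⁰`

The downstream response is `E = e·Fⁿ` with activity rate `e` (response per
full complex) and exponent `n = 1` by default; `n ≠ 1` models cooperative
downstream steps.

## Closed-form solvers

`AL` is Michaelis–Menten: `F = A⁰·K_P C/(1 + K_P C)`. `ALA` and `LAAL`
reduce to a quadratic in free `A`; `ALB_SEQ` to a quadratic in `F` whose
smaller root is the physical one (the larger violates `F ≤ min(A⁰, B⁰)`).
Quadratics are solved with the cancellation-stable form
`x = 2|c|/(b + √(b² − 4ac))` because low-affinity regimes make the linear
term dominate by many decades and the textbook formula loses all precision.
Degenerate inputs (`C = 0`, `A⁰ = 0`) return exact all-zero complex states
rather than erroring, because population sampling can produce near-zero
draws.

A noteworthy equilibrium consequence in `LAAL`: as the pairing affinity
`K_F → ∞` at `K_P·C = 1`, the first binding step re-equilibrates while
partial complexes pair off, so *all* subunits end up in full complexes
(`2F/A⁰ → 1`), not just the half initially in partial complexes. The naive
frozen-first-step intuition gives `2F/A⁰ → 1/2`, which is wrong at
equilibrium; both the closed form and the network solver confirm the former.

## The general network solver

`rlscale.network` solves arbitrary association networks. Every species is a
monomial in the *base* species (free species that are never a reaction
product), with constants folded into the coefficient. The conservation laws
are then solved by damped Newton iteration on the log base amounts —
positivity is automatic, no clipping — with an analytic Jacobian.
Convergence: maximum relative residual below 1e-10 or 200 iterations; the
step is halved (up to 60 times) until the residual decreases;
one-dimensional problems that stall fall back to bracketed bisection.
Initial guess: each base species at half the tightest total that constrains
it. A product reachable by several reaction routes (a thermodynamic cycle,
as in the non-sequential heterodimer) must satisfy detailed balance: the
route coefficients must agree to relative 1e-6, a tolerance chosen to
absorb the limited precision of user-entered constants.

This solver is deliberately independent of the closed forms — it shares no
algebra with them — and serves as the oracle in the test suite (agreement
to relative 1e-8 over 1000 random draws per architecture). It is also the
only solver used for competition and non-sequential networks, except that
the two-ligand competition system happens to stay quadratic in the shared
free subunit; that vectorized shortcut (used for population-scale
simulation) is itself validated against the network solver.

## The local scaling metric

`S = d ln E / d ln A⁰` is computed by a central finite difference in log
space with relative step `h = 1e-4` (truncation error `O(h²) ≈ 1e-8`, far
below any tolerance used). Because `ln E = ln e + n·ln F`, the activity
rate cancels exactly in the difference; the implementation differentiates
`ln F` and multiplies by `n`, so scaling is independent of `e` *by
construction* (bit-identical, not merely approximately equal) and the
`n`-fold chain rule is exact. The numeric derivative is the ground-truth
method; the closed forms

* `S_ALA = 2/(1 + 2F/A⁰)`
* `S_A = A⁰ / [(A⁰−F)·B⁰/(B⁰−F) + F]` (and the A↔B mirror for `S_B`)

are derived accelerators, validated against the numeric derivative to 1e-4
across random draws before use. For heterodimers the bound fraction is
reported relative to the less abundant subunit, `F/min(A⁰, B⁰)`.

Scans default to 41 log-spaced points per axis over `[1e-4, 1e4]`, which
spans all regimes (quadratic/linear for homodimers; sub-saturated/saturated
for heterodimers); the scaling-extremes computation uses a wider
`[1e-6, 1e6]` 61-point grid so the asymptotic corners are approached within
0.01.

## Population simulations

Receptor totals are drawn per cell from a gamma distribution parameterised
by mean and SD (shape `(mean/sd)²`, scale `sd²/mean`); the reference
population has mean 1 ARU and SD 0.5, with 100,000 cells. Subunit totals
for heterodimers are drawn independently by default; a Gaussian-copula
correlation knob exists because real subunit covariance is unknown. All
randomness flows through a single integer seed (`numpy.random.default_rng`)
and reruns are bit-identical.

To compare ligands, each ligand's activity rate is set to
`e = target/mean(Fⁿ)` so the population mean response is exactly the target
(the response is linear in `e`, so matching is exact to round-off). All
ligands within one comparison are evaluated on the *same* receptor sample,
mirroring a paired design: CV differences then reflect ligand identity
only. The CV of an all-zero response (`C = 0`) is reported as NaN, not 0.

Default ligand panels (chosen to span the occupancy regimes, since real
ligand panels are system-specific):

* monomer panel: five ligands, `C = 1`, affinities log-spaced `[1e-2, 1e2]`;
* homodimer panel: `K_P·C = 1`, `K_F·A⁰` log-spaced `[1e-2, 1e2]`
  (occupancy from ≈0.005 to ≈0.87, scaling from ≈1.99 to ≈1.07);
* heterodimer panel: weak (`0.01, 0.01`), intermediate (`1, 1`) and
  saturating (`1e4, 1e4`) affinity pairs.

A caveat the tests make explicit: the twofold CV bound for homodimers is a
small-noise (delta-method) statement, `CV(E) ≈ S·CV(A⁰)`. At receptor CV
0.5, a panel pushed to the exact asymptotic corners yields a CV ratio of
about 2.08, because the CV of the *square* of a gamma variate slightly
exceeds twice the gamma's CV. The default panel spans the regimes without
sitting on the corners and gives a ratio of about 1.94, approaching 2.

The four default heterodimer populations are archetypes: balanced subunits;
imbalanced with a tight abundant subunit; imbalanced with a variable
abundant subunit; and an extreme case (100-fold imbalance, abundant-subunit
CV 1, limiting-subunit CV 0.05). Only the last exceeds a tenfold
ligand-to-ligand CV spread. At 10-fold imbalance with abundant-subunit CV 1
the spread saturates near 5: the gamma's low tail leaves a few percent of
cells limited by the "abundant" subunit under a saturating ligand, which
re-injects its variability into the response. Order-of-magnitude
discrimination therefore needs either stronger imbalance or a tighter
limiting subunit.

## Competition

A zero-activity inhibitor (same binding scheme, `e = 0`) competing for the
receptor pool breaks the one-to-one map between scaling and occupancy: two
parameter settings with identical activator complex amounts can differ in
`S` by far more than numerical error. Along a path in the `(C_L, C_I)`
plane holding the activator complex fixed at a reference cell, the
population CV decreases as inhibitor increases. Two practical constraints
shape the default conditions (activator `C = 0.1`, `K_P = 1`, `K_F = 0.1`;
inhibitor `K_P = 1`, `K_F = 10`): the path is only feasible while the
target complex amount stays below the hook-effect peak of the
inhibitor-laden dose-response (the solver raises a clear error otherwise),
and a monotone CV decrease requires the inhibitor to pair substantially
more strongly than the activator, so that it sequesters subunits into inert
dimers and linearises the activator's response.

## Extensions

**Turnover.** Receptors are produced at constant rate and degraded with
first-order kinetics; complexes may degrade faster than free receptors
(ligand-induced internalisation). Binding still equilibrates fast, so the
slow production/degradation balance sets an emergent receptor total, and
scaling is computed against the production rate — the cell-intrinsic
quantity replacing `A⁰`. With uniform degradation the model reduces exactly
to the fixed-total model with `A⁰ = production/degradation` (asserted to
1e-9). Whether partial complexes degrade at the free or the complex rate is
a config flag defaulting to the complex rate. The extension covers the
single-subunit architectures; a heterodimer version would need per-subunit
production rates and is out of scope.

**Finite ligand pool.** The ligand becomes a conserved per-cell species
(one extra conservation law handed to the network solver). The
constant-ligand solution is recovered in the large-pool limit; when the
pool is comparable to the receptor total, even the monomeric scaling
deviates from 1, since receptors now compete for a shared resource. Pools
are per-cell; a population-shared pool is out of scope.

**Nonlinear response.** `E = e·Fⁿ` gives `S(n) = n·S(1)` exactly; the
attainable range rescales but remains independent of ligand parameters and
of `e`.

## What the synthetic populations do and do not capture

The generator emulates a single noise source — receptor expression
variability with gamma statistics — under a well-mixed, steady-state
stimulus. It does not model intrinsic/transcriptional noise downstream of
the receptor, receptor trafficking dynamics, spatial ligand gradients,
subunit co-regulation (unless the correlation knob is set), or kinetic
(pre-steady-state) effects. Passing tests therefore demonstrate properties
of the equilibrium architecture-noise interaction, not a full account of
variability in any real pathway.

## Problem sizes and numerical tolerances

Reference computations use 100,000 cells, 41–61 point grid axes, and
1000–10,000 random draws for oracle sweeps; all closed-form paths are
vectorized, so the full test suite runs in seconds. Key tolerances:
conservation residuals ≤ 1e-9 relative (closed forms, round-off), 1e-10
(network solver), oracle agreement 1e-8, closed-form scaling vs numeric
derivative 1e-4, Monte-Carlo CV checks ±0.01 at n = 100,000.

## Known limitations

* `ALB_NONSEQ` has no closed form here and always goes through the network
  solver (scalar, not vectorized), so large non-sequential population
  simulations are comparatively slow.
* The inhibitor constant-complex path requires the target to be reachable
  (below the hook-effect peak); infeasible configurations raise rather than
  extrapolate.
* Gamma moment-matching requires `sd > 0` for a nondegenerate draw; `sd = 0`
  produces a deterministic population by design.
* Scaling is defined with respect to receptor totals (or production rate,
  under turnover) only — not with respect to ligand concentration or
  affinities.
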