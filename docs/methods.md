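# Methods

`brainlife` implements a metabolically explicit life-history model of brain
evolution and a numerical solver for the energy-allocation schedule that
maximizes lifetime reproduction. This note documents the model, the
numerical choices, the benchmark parameter provenance, and the known
limitations. Nothing here reports an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Model

### States and energy bookkeeping

A female is partitioned into brain, reproductive, and somatic tissue with
masses `x_b, x_r, x_s` (kg); `x_k` is her skill level at energy extraction
(arbitrary "skill units"). All heats are in MJ, time in years.

Resting metabolic rate is a power law of body mass scaled by how successful
the individual currently is at extracting energy:

    B_rest(t) = K · e(t) · x_B(t)^beta,      x_B = x_b + x_r + x_s,

and splits exactly into maintenance and growth (synthesis):

    B_maint = x_b·B_b + x_r·B_r + x_s·B_s,     B_syn = B_rest − B_maint.

The evolving trait is the allocation schedule `u(t) = (u_b, u_r, u_s)` on
the unit simplex, dividing the growth metabolic rate among the tissues:

    dx_i/dt = u_i · B_syn / E_i,   i ∈ {b, r, s},

where `E_i` is the heat released per kg of tissue synthesized. A fixed
fraction `s_k` of the brain's metabolic rate drives skill dynamics against a
per-skill memory cost `B_k` and learning cost `E_k`:

    dx_k/dt = ( s_k·[x_b·B_b + u_b·B_syn] − x_k·B_k ) / E_k.

When brain growth has stopped, skill saturates at the asymptote
`x̂_k = s_k·B_b·x_b/B_k`, making adult skill proportional to adult brain
mass — the model's explanation for brain-size/cognition correlations.

### Environment (me vs nature)

Extraction efficiency is a contest against the non-social environment:

    e = c(x_k) / (d(t) + c(x_k)),        d(t) = alpha · (1 − phi0·e^(−phi_r·t)),

with competence either a power (`c = x_k^gamma`) or an exponential
(`c = exp(gamma·x_k)`) function of skill. Maternal facilitation `phi(t)`
shields the young; it decays exogenously (an endogenous, maternal-skill-
dependent variant is a deliberate extension point: any callable
`e(x_k, t)` can be substituted in principle, but only the me-vs-nature form
ships). The degenerate 0/0 contest (zero competence against a fully
facilitated challenge) is resolved as `e = 1` with a warning: zero
difficulty means nothing stands between the individual and the energy.

### Demography and objective

Mortality is age-independent (`l(t) = e^(−mu·t)`). Effective fecundity is by
default proportional to reproductive-tissue mass, `m = C·f0·x_r`; an exact
offspring-accounting mode integrates `dx_o/dt = (s_o·B_rest,r − x_o·B_o)/E_o`
and is opt-in (`IntegrationOptions.exact_fecundity`), because the linear
approximation is accurate whenever offspring maintenance by reproductive
tissue is negligible and `B_r ≫ E_r`/year — conditions the benchmark values
satisfy. The objective is the basic reproductive number

    R0 = ∫_0^T l(t)·m(t) dt.

Because the me-vs-nature efficiency does not depend on the resident
population's strategy, an uninvadable strategy is exactly an R0 maximizer,
so no game-theoretic fixed point is needed. `C` and `f0` rescale R0 but
never move the argmax; both are kept so reported R0 values are
interpretable.

### Boundary closure at exhausted tissues

When `B_syn < 0`, allocated tissues shrink — propagated literally, since
clamping would silently change the optimization landscape. The literal
dynamics are however ill-defined once an allocated tissue has reached zero
mass: its shrinkage can no longer pay the maintenance deficit, and a naive
floor-at-zero would let maintenance go unpaid (a free-energy leak that the
optimizer exploits ruthlessly). `physiology.effective_allocation` closes
the boundary: exactly at that corner — and nowhere else — the exhausted
tissue's shrinkage share is redistributed to the remaining tissues in
proportion to their stored synthesis energy `x_i·E_i`, preserving the
energy-conservation identity `Σ_i dx_i/dt · E_i = B_syn` everywhere.

## Numerics

* **Reference integrator** (`trajectory.integrate`): SciPy `solve_ivp`
  (RK45 by default; LSODA's stiffness switching can stall on the
  discontinuous shrink-to-zero corner), restarted at every control node so
  discontinuities are never smoothed; default tolerances 1e-8/1e-10;
  R0 carried as an augmented state; reporting grid of 1000 points; states
  floored at zero with a warning (shrinkage to zero is a legitimate corner
  of parameter sweeps, not an error).
* **Batched engine** (`_engine.BatchEvaluator`): classical RK4 with steps
  aligned to the control mesh, numba-compiled, used by the optimizer,
  the brute-force oracle, and the certificates. Steps are capped at 0.1 y
  and refined per interval against the fastest relaxation rate the batch's
  controls can excite (`u_i·B_i/E_i`, `B_k/E_k`). All certificate-grade
  comparisons are evaluated inside a single batch so candidates share one
  step schedule and differential discretization error cancels. Agreement
  with the reference integrator is part of the test suite; at the flooring
  corner the scheme degrades to first order, so convergence checks there
  use small fixed steps.
* **Solver** (`optimal_control.optimize`): first-discretize. Each mesh
  interval's simplex triple is parameterized by two unconstrained logits
  via a softmax map (the third logit pinned at 0); L-BFGS-B with gradients
  from one batched central-difference pass per iteration; multistart from a
  staged human-like guess, the uniform strategy, and seeded random simplex
  draws (the landscape is nonconvex and only local uninvadability is
  claimed). Gradient passes alternate with cyclic per-interval coordinate
  refinement (global simplex lattice at step 0.1 plus local tangent offsets
  down to radius 1e-3), which drives each interval to per-interval
  optimality well below certificate precision; a greedy vertex polish
  removes interior allocations a pure vertex beats. Finally the flat
  late-life region — where `B_syn ≈ 0` makes the objective allocation-
  insensitive — is canonicalized to the reproductive vertex from the
  terminal interval backwards, stopping at the first interval where that
  would genuinely lower R0 (a reporting convention, not an optimization
  step).
* **Certificates**: `needle_test` applies mesh-aligned perturbations
  (whole-interval vertex swaps and random simplex replacements) by default;
  sub-interval needles are available behind `sub_interval=True` but measure
  mesh coarseness rather than solver failure. `brute_force_search`
  exhaustively enumerates simplex-lattice schedules on meshes of up to 4
  intervals as an independent oracle.
* **Switching times**: thresholds on the control (`epsilon = 1e-3` by
  default): brain growth onset/arrest are the first/last ages with
  `u_b > ε`; maturity is the first age with `u_r > ε`; adulthood is the
  first age after which `u_r > 1 − ε` persistently, falling back — when a
  trajectory is available and no such age exists — to the age after which
  the growth metabolic rate stays below 1e-3 of its lifetime peak (growth
  depleted). The threshold convention is a reporting choice.

## Benchmark parameters (synthetic reconstruction)

The packaged benchmark files
(`src/brainlife/data/benchmark_{power,exponential}_synthetic.toml`) are
**synthetic reconstructions**: they were not transcribed from any
published estimation of this model family. The physiological block was assembled from standard
human-female physiology: newborn total mass 3.4 kg with 0.35 kg brain;
adult resting metabolic rate near 5.5 MJ/day at ~51 kg giving `K = 125.5`
MJ·y⁻¹·kg⁻ᵝ at `beta = 0.75`; brain maintenance `B_b = 336` MJ·y⁻¹·kg⁻¹
(≈1.2 MJ/day for a 1.3 kg brain); soma as the cheapest tissue to maintain
(`B_s = 31.5`); reproductive tissue (narrowly construed, ovarian-follicle
like) far costlier to maintain than to build (`B_r = 2000 ≫ E_r = 50`);
synthesis heats of order 10–50 MJ/kg; background mortality `mu = 0.02` y⁻¹
and reproductive lifespan `T = 50` y. The skill/environment block
(`alpha, gamma, x_k0, s_k, B_k, E_k, phi_r`; `phi0 = 0.6` fixed) was
calibrated by trial and error — first on the adult steady-state yield
surface, then on full optimizations — so that the optimized strategy lands
near observed human-female adult masses. The resulting optima give roughly
50–54 kg body and 1.2–1.4 kg brain (EQ ≈ 5.5) under power competence, and
a larger brain under exponential competence, with childhood growth, an
adolescent mixed phase, and late-life reproduction.

**Known limitation.** The optimal *stage sequence* under these
reconstructed costs is not the canonical one: small brain allocations
persist through much of life and some reproductive-tissue building occurs
in early childhood, so the strict ordering (brain growth onset ≤ arrest ≤
maturity ≤ adulthood) fails at many sweep points, and literature values
for human switching ages are not quantitatively reproduced. The stage sequence is
known to be sensitive to the relative magnitudes of the tissue maintenance
and synthesis costs; pinning it down requires the original empirical
estimates, which this package does not redistribute. The tests that assert
human-calibrated target values are therefore expected to fail against the
synthetic benchmarks, and are kept failing rather than weakened.

What the passing tests do show: exact energy conservation along
trajectories, closed-form demographic limits, skill saturation at the
analytic asymptote, solver agreement with exhaustive enumeration, local
optimality of returned strategies under mesh-aligned perturbations, and the
rise-then-fall response of adult brain mass to environmental difficulty and
to skill effectiveness. What they do not show: quantitative agreement with
any particular published parameterization, or behavior under social
(us-vs-them) settings, which are out of scope.

## Reproducibility

Every stochastic component (multistart draws, needle perturbations) is
driven by an explicit integer seed; rerunning with the same seed reproduces
summary outputs byte-for-byte. Problem sizes used by the shipped tests and
the acceptance script — meshes of 25–40 intervals, 2–4 multistarts,
three-point parameter sweeps — were chosen as the smallest sizes at which
the qualitative results are stable.
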