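# Methods

## Scope and model assumptions

nessflow integrates deterministic mass-action kinetics for well-mixed,
isothermal, ideal solutions (activities = 1). Concentrations are in
mol L⁻¹, time in s, temperature in K, R = 8.314 J mol⁻¹ K⁻¹. Stoichiometric
coefficients are non-negative integers ≤ 4 (small molecularity; the Schlögl
model needs order 3). Open systems are ideal CSTRs: one dilution rate `flow`
applies to every exchanged species k, contributing
f·(c_in,k − c_k) to its balance. A species may instead be *clamped* (held
fixed); clamping is supported because it is the textbook driving of the
Schlögl model, but every thermodynamic report on a clamped network carries a
`clamped` label — a clamped entropy balance is a necessary, not a
sufficient, stationarity condition, and the implied fluxes that hold the
clamp are made explicit in the exchange accounting.

Every reversible transformation is represented as two unidirectional
mass-action steps sharing a `pair_id` (the stoichiometric-network-analysis
decomposition). Strictly irreversible steps are allowed in the dynamics but
rejected by all thermodynamic operations: with v_r = 0 the affinity
R·T·ln(v_f/v_r) diverges, so a network must be "thermodynamically
complete" (all steps paired) before affinities, entropy production, GEC or
probes are computed. Model steps that are conceptually irreversible (Frank
autocatalysis) therefore carry small but finite reverse constants.

## Entropy accounting

For pair ρ: Af_ρ = R·T·ln(v_f/v_r) (positive when the forward direction is
spontaneous) and

    σ_int = R Σ_ρ (v_f − v_r)·ln(v_f/v_r) = (1/T) Σ_ρ Af_ρ (v_f − v_r) ≥ 0,

in J K⁻¹ s⁻¹ L⁻¹ (specific, per unit volume). An equivalent
relative-potential form sums over the unidirectional steps,
σ = −R Σ_steps v·Σ_k ν_k ln(c_k/c_k,eq); `entropy_production_relative`
implements it and the test suite verifies its identity with the pairwise
form to 1e-10 relative on randomly generated detailed-balance-consistent
networks.

**Reference potentials.** Relative chemical potentials are
μ_k = R·T·ln(c_k/c_k,ref), with c_ref the detailed-balance equilibrium of
the *closed chemical subnetwork* on the stoichiometric class of the
composition at hand. It exists iff the rate constants satisfy the
Wegscheider cycle conditions (checked by least squares on
ln(k_f/k_r) ∈ range(Nᵀ)); inconsistent ("driven by construction") constants
require explicit standard potentials via `mu_standard`. c_ref is computed
exactly: the log-composition solves Nᵀx = ln(k_f/k_r) plus moiety-total
matching, a small convex Newton solve.

**Exchange term.** σ_exch = −(1/T) Σ_k μ_k J_k, where J_k is the net inflow
(CSTR terms on exchanged species, implied clamp fluxes on clamped ones).
With μ defined as above, σ_int + σ_exch = 0 holds *identically* at any
stationary composition — the NESS balance — and off-stationary compositions
satisfy it along whole curves. `balance_residual` therefore always reports
max|dc/dt| beside the balance and flags zero-balance non-stationary points
as `balance_only`; `balance_zero_contour` traces such a curve over a 2-D
concentration grid (grid-line sign changes refined by bisection) and marks
which of its points are actual NESSs. The precise exchange bookkeeping is a
*convention of this package*, chosen so that the balance is exact and
σ_int + σ_exch = −(1/T)·dG/dt along trajectories for the ideal free energy
built from the same potentials (verified by finite differences in the
tests).

## General evolution criterion

The time derivative of the entropy production splits into a force part and
a current part, dP/dt = d_F P/dt + d_J P/dt, computed *analytically* by the
chain rule through the mass-action monomials (no differencing):
dAf_ρ/dt = −R·T·Σ_k ν_kρ·ċ_k/c_k and dv/dt from the rate Jacobian.
Exchange flows are decomposed like reactions into inflow (f·c_in) and
outflow (f·c) steps with pair affinity R·T·ln(c_in/c). For pure-outflow
species (c_in = 0) that affinity is singular, so the outflow force is
measured against the 1 mol L⁻¹ standard state (−R·T·ln c). The force
*derivative* is −R·T·ċ/c in either convention, hence the closed form

    d_F P/dt = −R Σ_k ċ_k² / c_k  ≤ 0   (over non-clamped species)

is convention-free; only the reported P and d_J P offsets of outflow-only
species depend on the standard-state choice, and dP = d_F P + d_J P matches
finite differences of the same P series. In the linear regime
(max|Af|/RT < 1e-3, i.e. |Af| ≪ 2.5 kJ mol⁻¹ at 300 K) the symmetry of the
near-equilibrium response makes d_F P ≈ d_J P, so dP/dt ≤ 0 and σ_int
decreases monotonically to its stationary minimum; the suite checks both to
1 %.

## Stationary states and stability

`find_steady_states` runs a multistart root search (default 64 starts,
log-uniform over [1e-6, 1e2] mol L⁻¹, seeded; default seed 20210805) on the
kinetic equations restricted to the stoichiometric compatibility class of
the initial composition (conserved-moiety totals are constraints, solved in
reduced coordinates). Roots are accepted by residual (max|dc/dt| ≤ 1e-9
mol L⁻¹ s⁻¹) rather than by the MINPACK status flag, deduplicated at 1e-6
relative distance, validated by a short integration, and classified.

Stability is decided twice: Routh–Hurwitz conditions on the characteristic
polynomial (coefficients by Faddeev–LeVerrier, so the route is independent
of any eigenvalue computation) and direct eigenvalues; disagreement demotes
the verdict to `marginal` with a warning. Conserved directions are deflated
first — the structural zero eigenvalues of closed systems are not
marginality. The probe operation (`local_potential_probe`) perturbs a NESS
along seeded random unit directions plus named symmetry directions,
projected onto the reactive subspace (clamped components and conserved
moiety displacements removed, since those cannot relax back), integrates
each probe, verifies d_F P/dt ≤ 0 along the way, and classifies well (all
return) vs saddle; the classification must and does agree with the
Jacobian verdict on every preset.

`scan_branch` continues a branch along a monotone parameter grid by
integrating to steady state from the previous point's state, optionally in
both directions; hysteresis is flagged when the sweeps disagree beyond
1e-4 relative on an overlapping window, limit points from state-jump
outliers, and slope discontinuities of σ_int(parameter) from
second-difference outliers (> 5× median). An optional relative `perturb`
nudges the seed so a sweep can abandon an unstable symmetric branch — used
to follow the stable scalemic branch of the Frank model across its
bifurcation, where σ_int shows the slope discontinuity that signals the
instability of the thermodynamic branch.

## Numerical choices

Stiff integration uses `scipy.integrate.solve_ivp` (Radau) with the
analytic Jacobian, rtol 1e-10 / atol 1e-12 — tighter than usual because the
entropy balances are certified at 1e-10 scale; tolerances are configurable,
extended precision beyond double is out of scope. Steady-state stops use a
terminal event on max|dc/dt|. Equations are solved in the original
variables (preserving linear-network exactness); negative excursions
smaller than 100·atol are clipped to zero post hoc. Probe fates: returned =
within 1e-6 relative of the probed NESS, integrating up to 50× the slowest
relaxation time; escaped = within 1e-4 of another known attractor, beyond
the concentration window, or neither (unknown).

## Built-in models and the random fixture generator

* **A⇌B** (k1 = 2, km1 = 1, 1 M total): equilibrium [B]/[A] = 2; the
  textbook anchor for affinities (Af = RT·ln 2 ≈ 1.729 kJ mol⁻¹ at unit
  composition; σ_int = R·ln 2 ≈ 5.763 J K⁻¹ s⁻¹ L⁻¹).
* **Competitive CSTR** (A⇌C @ 10/1, A⇌D @ 1/0.1, A fed at 1 M): equal
  Keq = 10; NESS selectivity k1C(km1D+f)/(k1D(km1C+f)) — 1 as f→0, 5.5 at
  f = 1, →10 as f→∞ — with the identity
  [C]/[D] = (KeqC/KeqD)·exp((Af_D−Af_C)/RT) holding to 1e-10 at every NESS.
  The reaction list behind the open-flow selectivity figure is not printed
  anywhere authoritative; this A⇌C/A⇌D topology is reconstructed from the
  equal-equilibrium-constant description and reproduces its qualitative
  behaviour exactly in closed form.
* **Schlögl** (A⇌X, 3X⇌2X+B; A, B clamped): defaults place the stationary
  cubic at (x−1)(x−2)(x−3); sweeps of the pump constant across the window
  k1 ∈ (5.62, 6.39) show hysteresis with two limit points.
* **Frank** (A⇌L, A⇌D, A+L⇌2L, A+D⇌2D, L+D⇌P in a CSTR, all species
  exchanged): defaults k_prod = 0.5, k_auto = 2, k_inhib = 10, reverse
  constants 1 % of forward, A fed at 1 M. The 1 % reversibility is a
  deliberate choice: with much smaller reverse constants the racemic branch
  stays unstable down to physically uninteresting flows (~1e-7 s⁻¹),
  whereas at 1 % the full phenomenology is accessible — racemic NESS stable
  below f ≈ 0.012 s⁻¹, unstable between ≈ 0.012 and ≈ 0.48 s⁻¹ (the SMSB
  window, where two mirror scalemic NESSs at ee ≈ ±0.90 coexist), stable
  again above. Both thresholds are located at run time by bisection on the
  antisymmetric eigenvalue λ = J_LL − J_LD of the racemic NESS (an exact
  eigenvalue by mirror symmetry), never hard-coded. The default preset flow
  (0.15 s⁻¹) sits inside the window.
* **random_network(n_species, n_pairs, driven, seed)**: uni/bimolecular
  reversible pairs; constants are made Wegscheider-consistent by assigning
  each species a random standard potential g_k ∈ ±4 kJ mol⁻¹ and setting
  k_f/k_r = exp(−Δg/RT) with symmetric log-uniform prefactors; `driven`
  adds two chemostats (a single one would let a consistent chemistry relax
  to genuine equilibrium). Generation is seed-reproducible to the byte.

The generator emulates small, connected, thermodynamically consistent
networks with O(1) concentrations and rate constants. It does not emulate
wide timescale separations, large networks, conservation-broken
stoichiometries, non-ideal activities, or stochastic (small-copy-number)
effects — passing tests certify the accounting identities and solver
behaviour on this class, not performance on real large-scale kinetic
models.

## Problem sizes used by the test suite

The property suites run 50 seeded random networks × 200 trajectory points
for the GEC checks (> 10⁴ points), 50 networks × 50 compositions for the
two-forms identity, 21-point bidirectional sweeps for the Schlögl
hysteresis, and single-figure grids elsewhere; the full suite and the
acceptance script each complete in a few minutes on one CPU.

## Known limitations

Affinities are undefined at zero concentrations, so thermodynamic series
must start from strictly positive compositions. Heat flows, temperature
gradients, non-ideal activities, reaction–diffusion structure and
stochastic kinetics are out of scope. The second-variation (δ²S) stability
criterion is deliberately not implemented: it can be inconclusive, and the
eigenvalue/Routh–Hurwitz route decides local stability unambiguously. The
exchange-entropy convention (reference potentials, standard-state offset
for outflow-only species) is one consistent choice among several; all
balance and GEC statements certified by the tests are invariant under that
choice except the absolute offset of reported P for outflow-only species.
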