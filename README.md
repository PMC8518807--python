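# nessflow

Deterministic simulation of mass-action chemical reaction networks — closed
or driven through an ideal open-flow reactor (CSTR) — with complete
non-equilibrium thermodynamic accounting: per-reaction affinities, internal
and exchange entropy production and their balance at nonequilibrium
stationary states (NESSs), the general evolution criterion, linear
stability by Routh–Hurwitz *and* eigenvalues, and local-potential probing
of stationary states.

It is aimed at chemists and systems/origins-of-life researchers who study
dissipative reaction networks — competitive selectivity under flow,
bistability (Schlögl), spontaneous mirror symmetry breaking (Frank
autocatalysis) — and want the entropy bookkeeping done exactly rather than
assumed.

## The model

Every reversible transformation is stored as two unidirectional
mass-action steps (the stoichiometric-network-analysis representation):
forward and backward reactions are different reactions, each with its own
current. For a pair ρ with currents v_f and v_r at ideal activities and
constant temperature,

```
Af_ρ     = R T ln(v_f / v_r)                         affinity, J/mol
σ_int    = R Σ_ρ (v_f − v_r) ln(v_f / v_r)  ≥ 0      J K⁻¹ s⁻¹ L⁻¹
σ_exch   = −(1/T) Σ_k μ_k J_k                        exchange term
```

with J_k the net matter inflow of species k (CSTR flow terms, or the
implied fluxes holding clamped species fixed) and μ_k = R T ln(c_k/c_k,ref)
the chemical potential relative to a detailed-balance equilibrium of the
closed chemistry. Two exact statements organise everything the package
computes:

* **NESS balance** — at any stationary composition,
  σ_int + σ_exch = 0. Off-stationary compositions also satisfy the balance
  along whole *curves*, which is why `balance_residual` always reports
  max|dc/dt| next to the balance: zero balance alone certifies nothing.
* **General evolution criterion (GEC)** — along any trajectory the force
  part of dP/dt is non-positive:
  d_F P/dt = −R Σ_k (dc_k/dt)² / c_k ≤ 0, with
  dP/dt = d_F P/dt + d_J P/dt. Stable NESSs are wells of the probed
  dynamics; unstable ones are saddles whose returning subspace preserves
  the product ratio (e.g. the racemic composition in the Frank model).

## Worked example

Competitive production of C and D from a fed reactant A (A⇌C, A⇌D, equal
equilibrium constants, C kinetically favoured) in a CSTR at flow
f = 1 s⁻¹:

```python
>>> import nessflow as nf
>>> net = nf.make_competitive()          # k1C=10, km1C=1, k1D=1, km1D=0.1
>>> ness = nf.find_steady_states(net, n_starts=16, seed=11)[0]
>>> ness.conc.round(6)                   # [A], [C], [D] in mol/L
array([0.144737, 0.723684, 0.131579])
>>> ness.conc[1] / ness.conc[2]          # selectivity [C]/[D]
5.500000000000001
>>> bal = nf.balance_residual(net, ness.conc)
>>> bal.sigma_int, bal.sigma_total
(6.793637160988195, -8.881784197001252e-16)
```

At equilibrium (f→0) the selectivity would be KeqC/KeqD = 1; at f = 1 the
flow keeps the system far from equilibrium and the kinetically faster
channel wins ([C]/[D] = 5.5, approaching k1C/k1D = 10 as f grows), while
the entropy produced internally (6.79 J K⁻¹ s⁻¹ L⁻¹) is exported exactly
(σ_total ≈ −9e-16 ≈ 0) — the NESS balance. If C and D are enantiomers
(identical constants), the same computation returns selectivity 1: the
racemate, regardless of how biased the starting composition is.

The command line exposes the same operations
(`nessflow simulate|ness|stability|thermo|gec|probe|scan|contour|demo`), e.g.

```
nessflow demo figure1 --preset competitive --out out/f1   # selectivity & yield vs flow
nessflow ness --preset schlogl-cubic --out out/ness       # 3 states: stable/unstable/stable
nessflow demo frank --preset frank --out out/frank        # SMSB thresholds and ee
```

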