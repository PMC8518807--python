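"""Built-in model networks and a seeded generator of thermodynamically
consistent random fixtures.

Four systems are provided, each emitted in the plain-text network dialect
(so every preset is parseable and serialisable like any user network):

* ``make_ab`` — the minimal closed isomerisation A<->B; relaxes to the
  detailed-balance equilibrium [B]/[A] = k1/km1.
* ``make_competitive`` — an open CSTR with two channels A<->C and A<->D
  sharing the same equilibrium constant by default; flow tunes the
  selectivity [C]/[D] between 1 (equilibrium) and the kinetic ratio
  k1C/k1D.  With mirror-identical constants the channels model a pair of
  enantiomers and the NESS selectivity is exactly 1.
* ``make_schlogl`` — the cubic autocatalytic bistable model
  A <-> X, 3X <-> 2X + B with A and B clamped (the textbook driven form;
  thermodynamic reports on it carry the clamped-scenario caveat).
* ``make_frank`` — enantioselective autocatalysis with mutual inhibition
  (direct production A<->L, A<->D; autocatalysis A+L<->2L, A+D<->2D;
  heterochiral inhibition L+D<->P) in a CSTR.  Above a critical flow the
  racemic NESS destabilises and two mirror-image scalemic NESSs appear
  (spontaneous mirror symmetry breaking); the threshold is located at run
  time from the leading antisymmetric eigenvalue rather than hard-coded.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .dynamics import DEFAULT_SEED, find_steady_states
from .errors import DomainError, NetworkValidationError
from .network import ReactionNetwork, parse_network, serialize_network

#: reverse/forward rate-constant ratio used where a step is conceptually
#: irreversible: finite so every affinity stays defined, and large enough
#: (1 %) that the near-equilibrium regime — where the racemic branch of the
#: Frank model must be stable — sits at numerically accessible flow rates.
REVERSIBILITY_EPS = 1e-2


def _r(x) -> str:
    """Round-trippable decimal form of a scalar for the network dialect."""
    return repr(float(x))


def make_ab(k1: float = 2.0, km1: float = 1.0, total: float = 1.0,
            temperature: float = 300.0) -> ReactionNetwork:
    """Closed A<->B isomerisation starting from pure A."""
    text = (
        f"species A init={_r(total)}\n"
        f"species B init=0.0\n"
        f"reaction R1: A <-> B ; kf={_r(k1)}, kr={_r(km1)}\n"
        f"system T={_r(temperature)} flow=0.0\n"
    )
    return parse_network(text)


def make_competitive(k1C: float = 10.0, km1C: float = 1.0,
                     k1D: float = 1.0, km1D: float = 0.1,
                     inflow_A: float = 1.0, flow: float = 1.0,
                     temperature: float = 300.0) -> ReactionNetwork:
    """Open-flow competitive network A<->C, A<->D (all species exchanged).

    The defaults give both channels the same equilibrium constant (10) with
    C kinetically favoured; the NESS selectivity is
    [C]/[D] = k1C (km1D + f) / (k1D (km1C + f)).
    """
    text = (
        f"species A init={_r(inflow_A)} exchanged inflow={_r(inflow_A)}\n"
        f"species C init=0.0 exchanged inflow=0.0\n"
        f"species D init=0.0 exchanged inflow=0.0\n"
        f"reaction RC: A <-> C ; kf={_r(k1C)}, kr={_r(km1C)}\n"
        f"reaction RD: A <-> D ; kf={_r(k1D)}, kr={_r(km1D)}\n"
        f"system T={_r(temperature)} flow={_r(flow)}\n"
    )
    return parse_network(text)


def make_enantiomeric(k1: float = 1.0, km1: float = 0.1,
                      inflow_A: float = 1.0, flow: float = 0.5,
                      temperature: float = 300.0) -> ReactionNetwork:
    """Competitive network whose products are enantiomers: both channels
    carry mirror-identical constants, so the NESS selectivity must be 1."""
    return make_competitive(k1, km1, k1, km1, inflow_A, flow, temperature)


def competitive_selectivity_closed_form(k1C, km1C, k1D, km1D, flow) -> float:
    """Steady-state [C]/[D] of the linear competitive CSTR."""
    return k1C * (km1D + flow) / (k1D * (km1C + flow))


def competitive_ness_closed_form(network: ReactionNetwork) -> np.ndarray:
    """Exact NESS of the linear competitive network (A, C, D order)."""
    (jfC, jrC) = network.pairs["RC"]
    (jfD, jrD) = network.pairs["RD"]
    k1C = network.reactions[jfC].rate_constant
    km1C = network.reactions[jrC].rate_constant
    k1D = network.reactions[jfD].rate_constant
    km1D = network.reactions[jrD].rate_constant
    f = network.flow_rate
    a_in = network.inflow[network.species_index("A")]
    gC = k1C * km1C / (km1C + f)
    gD = k1D * km1D / (km1D + f)
    a = f * a_in / (k1C + k1D + f - gC - gD)
    c = k1C * a / (km1C + f)
    d = k1D * a / (km1D + f)
    return np.array([a, c, d])


def make_schlogl(k1: float = 6.0, km1: float = 11.0,
                 k2: float = 1.0, km2: float = 6.0,
                 a_clamped: float = 1.0, b_clamped: float = 1.0,
                 x0: float = 0.5,
                 temperature: float = 300.0) -> ReactionNetwork:
    """Schlögl bistable model with clamped feed species A and B:

        A <-> X   (k1, km1),    3X <-> 2X + B   (k2, km2)

    so dX/dt = k1*a - km1*x - k2*x^3 + km2*b*x^2.  The defaults put the
    stationary cubic at (x-1)(x-2)(x-3) = 0: three states, x = 1 and 3
    stable, x = 2 unstable.
    """
    text = (
        f"species A init={_r(a_clamped)} clamped\n"
        f"species X init={_r(x0)}\n"
        f"species B init={_r(b_clamped)} clamped\n"
        f"reaction R1: A <-> X ; kf={_r(k1)}, kr={_r(km1)}\n"
        f"reaction R2: 3 X <-> 2 X + B ; kf={_r(k2)}, kr={_r(km2)}\n"
        f"system T={_r(temperature)} flow=0.0\n"
    )
    return parse_network(text)


def schlogl_cubic_roots(k1, km1, k2, km2, a, b) -> np.ndarray:
    """Real positive roots of k1*a - km1*x + km2*b*x^2 - k2*x^3 = 0
    (independent oracle for the stationary states)."""
    roots = np.roots([-k2, km2 * b, -km1, k1 * a])
    real = roots[np.abs(roots.imag) < 1e-9].real
    return np.sort(real[real > 0])


def make_frank(k_prod: float = 0.5, km_prod: float | None = None,
               k_auto: float = 2.0, km_auto: float | None = None,
               k_inhib: float = 10.0, km_inhib: float | None = None,
               inflow_A: float = 1.0, flow: float = 0.15,
               exchange_ld: bool = True,
               temperature: float = 300.0) -> ReactionNetwork:
    """Frank enantioselective-autocatalysis network in a CSTR.

    Every step is reversible (reverse constants default to
    ``REVERSIBILITY_EPS`` times the forward ones) so affinities and entropy
    production stay finite.  The two enantiomer channels share one constant
    set by construction, which keeps the kinetics exactly equivariant under
    the L <-> D relabelling; a chiral-bias input would be a separate,
    explicit modification, not a parameter of this factory.
    """
    km_prod = k_prod * REVERSIBILITY_EPS if km_prod is None else km_prod
    km_auto = k_auto * REVERSIBILITY_EPS if km_auto is None else km_auto
    km_inhib = k_inhib * REVERSIBILITY_EPS if km_inhib is None else km_inhib
    ld = "exchanged inflow=0.0" if exchange_ld else ""
    text = (
        f"species A init={_r(inflow_A)} exchanged inflow={_r(inflow_A)}\n"
        f"species L init=0.01 {ld}\n"
        f"species D init=0.01 {ld}\n"
        f"species P init=0.0 exchanged inflow=0.0\n"
        f"reaction PL: A <-> L ; kf={_r(k_prod)}, kr={_r(km_prod)}\n"
        f"reaction PD: A <-> D ; kf={_r(k_prod)}, kr={_r(km_prod)}\n"
        f"reaction AL: A + L <-> 2 L ; kf={_r(k_auto)}, kr={_r(km_auto)}\n"
        f"reaction AD: A + D <-> 2 D ; kf={_r(k_auto)}, kr={_r(km_auto)}\n"
        f"reaction IN: L + D <-> P ; kf={_r(k_inhib)}, kr={_r(km_inhib)}\n"
        f"system T={_r(temperature)} flow={_r(flow)}\n"
    )
    net = parse_network(text)
    validate_mirror_symmetry(net)
    return net


def validate_mirror_symmetry(network: ReactionNetwork, l="L", d="D") -> None:
    """Check that the network is invariant under the L <-> D relabelling."""
    def swap(side):
        return tuple(sorted(
            (d if n == l else (l if n == d else n), c)
            for n, c in side.items()))

    def plain(side):
        return tuple(sorted(side.items()))

    table = {}
    for r in network.reactions:
        key = (plain(r.reactants), plain(r.products))
        mirror = (swap(r.reactants), swap(r.products))
        # a reaction and its mirror image share one bucket
        table.setdefault(min(key, mirror), []).append(r.rate_constant)
    for key, ks in table.items():
        if len(set(ks)) != 1:
            raise NetworkValidationError(
                "enantiomer channels carry different rate constants: "
                f"{key} -> {ks}; mirror symmetry is broken"
            )


def enantiomeric_excess(network: ReactionNetwork, conc, l="L", d="D") -> float:
    """ee = ([L] - [D]) / ([L] + [D])."""
    cl = conc[network.species_index(l)]
    cd = conc[network.species_index(d)]
    if cl + cd == 0:
        return 0.0
    return float((cl - cd) / (cl + cd))


def racemic_ness(network: ReactionNetwork, guess=None):
    """The mirror-symmetric stationary state of a Frank-type network,
    found by root search restricted to the L = D subspace, plus the leading
    antisymmetric eigenvalue lambda = J_LL - J_LD (an exact eigenvalue of
    the full Jacobian by symmetry)."""
    import scipy.optimize

    iL = network.species_index("L")
    iD = network.species_index("D")
    others = [i for i in range(network.n_species) if i not in (iL, iD)]

    def expand(y):
        c = np.empty(network.n_species)
        c[others] = y[:-1]
        c[iL] = c[iD] = y[-1]
        return c

    def resid(y):
        dc = network.time_derivatives(np.clip(expand(y), 0.0, None))
        return np.append(dc[others], dc[iL])

    if guess is None:
        guesses = [np.append(network.init_conc[others],
                             max(network.init_conc[iL], 1e-4))]
        # fallback guess: relax the symmetrised dynamics numerically
        from .dynamics import integrate_to_steady
        c0 = network.init_conc.copy()
        c0[iL] = c0[iD] = 0.5 * (c0[iL] + c0[iD])
        try:
            traj = integrate_to_steady(network, np.clip(c0, 1e-8, None),
                                       steady_tol=1e-8, t_max=1e6)
            cf = traj.final_state
            cf_sym = 0.5 * (cf[iL] + cf[iD])
            guesses.append(np.append(cf[others], cf_sym))
        except Exception:
            pass
    else:
        guesses = [np.asarray(guess, dtype=float)]
    best = None
    for g0 in guesses:
        sol = scipy.optimize.root(resid, g0, method="hybr",
                                  options={"xtol": 1e-13})
        r = float(np.max(np.abs(resid(sol.x))))
        if (expand(sol.x) < -1e-9).any():
            continue
        if best is None or r < best[0]:
            best = (r, sol.x)
    if best is None or best[0] > 1e-9:
        raise DomainError("racemic stationary state not found")
    c = np.clip(expand(best[1]), 0.0, None)
    J = network.jacobian(c)
    lam_anti = float(J[iL, iL] - J[iL, iD])
    return c, lam_anti


def find_smsb_threshold(frank_factory, f_lo: float, f_hi: float,
                        n_bracket: int = 25, xtol: float = 1e-10):
    """Critical flow rates where the racemic NESS of a Frank network changes
    stability, located by bisection on the antisymmetric eigenvalue.

    ``frank_factory(flow)`` must return the network at a given flow rate.
    Returns the sorted list of thresholds found inside [f_lo, f_hi]
    (typically two: the window of spontaneous mirror symmetry breaking).
    """
    grid = np.geomspace(f_lo, f_hi, n_bracket)

    def lam(f):
        _, l = racemic_ness(frank_factory(f))
        return l

    vals = np.array([lam(f) for f in grid])
    thresholds = []
    for i in range(len(grid) - 1):
        if np.sign(vals[i]) * np.sign(vals[i + 1]) < 0:
            thresholds.append(brentq(lam, grid[i], grid[i + 1], xtol=xtol))
    return thresholds


# -- preset registry ---------------------------------------------------------

PRESETS = {
    "ab": make_ab,
    "competitive": make_competitive,
    "enantiomeric": make_enantiomeric,
    "schlogl-cubic": make_schlogl,
    "frank": make_frank,
}


def get_preset(name: str, **params) -> ReactionNetwork:
    if name not in PRESETS:
        raise DomainError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name](**params)


def write_preset_files(directory) -> None:
    """Materialise every preset as a network file in ``directory``."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, factory in PRESETS.items():
        (directory / f"{name}.net").write_text(
            serialize_network(factory()))


# -- random thermodynamically consistent fixtures ----------------------------

_TEMPLATES = ("uni", "bi_assoc", "bi_dissoc", "bi_exchange")


def random_network(n_species: int, n_pairs: int, driven: bool = False,
                   seed: int = DEFAULT_SEED,
                   temperature: float = 300.0) -> ReactionNetwork:
    """Seeded random reversible network with detailed-balance-consistent
    constants.

    Each species gets a random standard potential g_k; every pair obeys
    ln(kf/kr) = -sum(nu_k g_k)/(R*T) with a random symmetric prefactor, so
    the closed network relaxes to equilibrium with all affinities zero.
    With ``driven=True`` one or two species are exchanged through a CSTR
    flow, producing a genuine NESS with positive entropy production.
    """
    if n_species < 2 or n_pairs < 1:
        raise DomainError("need n_species >= 2 and n_pairs >= 1")
    rng = np.random.default_rng(seed)
    names = [f"S{i+1}" for i in range(n_species)]
    RT = 8.314 * temperature
    for _attempt in range(100):
        g = rng.uniform(-4000.0, 4000.0, size=n_species)  # J/mol
        pairs = []
        for _ in range(n_pairs):
            kind = _TEMPLATES[rng.integers(len(_TEMPLATES))]
            if kind == "uni":
                a, b = rng.choice(n_species, size=2, replace=False)
                reac, prod = {names[a]: 1}, {names[b]: 1}
            elif kind == "bi_assoc" and n_species >= 3:
                a, b, c = rng.choice(n_species, size=3, replace=False)
                reac, prod = {names[a]: 1, names[b]: 1}, {names[c]: 1}
            elif kind == "bi_dissoc" and n_species >= 3:
                a, b, c = rng.choice(n_species, size=3, replace=False)
                reac, prod = {names[a]: 1}, {names[b]: 1, names[c]: 1}
            elif kind == "bi_exchange" and n_species >= 4:
                a, b, c, d = rng.choice(n_species, size=4, replace=False)
                reac, prod = {names[a]: 1, names[b]: 1}, \
                             {names[c]: 1, names[d]: 1}
            else:
                a, b = rng.choice(n_species, size=2, replace=False)
                reac, prod = {names[a]: 1}, {names[b]: 1}
            pairs.append((reac, prod))
        used = set()
        for reac, prod in pairs:
            used |= set(reac) | set(prod)
        if used != set(names):
            continue
        lines = []
        exchanged = set()
        if driven:
            # two incompatible chemostats: one alone would let a
            # detailed-balanced chemistry relax to genuine equilibrium
            n_x = min(2, n_species)
            exchanged = set(rng.choice(n_species, size=n_x, replace=False))
        for i, nm in enumerate(names):
            init = float(np.exp(rng.uniform(np.log(0.05), np.log(2.0))))
            if i in exchanged:
                cin = float(np.exp(rng.uniform(np.log(0.1), np.log(2.0))))
                lines.append(
                    f"species {nm} init={_r(init)} exchanged inflow={_r(cin)}")
            else:
                lines.append(f"species {nm} init={_r(init)}")
        for j, (reac, prod) in enumerate(pairs):
            dg = (sum(g[names.index(n)] * c for n, c in prod.items())
                  - sum(g[names.index(n)] * c for n, c in reac.items()))
            kappa = float(np.exp(rng.uniform(np.log(0.2), np.log(5.0))))
            kf = kappa * float(np.exp(-dg / (2 * RT)))
            kr = kappa * float(np.exp(dg / (2 * RT)))
            lhs = " + ".join(f"{c} {n}" if c != 1 else n
                             for n, c in reac.items())
            rhs = " + ".join(f"{c} {n}" if c != 1 else n
                             for n, c in prod.items())
            lines.append(f"reaction P{j+1}: {lhs} <-> {rhs} ; "
                         f"kf={_r(kf)}, kr={_r(kr)}")
        flow = 0.3 if driven else 0.0
        lines.append(f"system T={_r(temperature)} flow={_r(flow)}")
        return parse_network("\n".join(lines) + "\n")
    raise DomainError("could not generate a connected random network")
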