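"""Non-equilibrium thermodynamic accounting for mass-action networks.

Every reversible transformation is carried as two unidirectional steps, so
each pair rho has a forward current v_f, a backward current v_r, and an
affinity

    Af_rho = R*T*ln(v_f / v_r)        [J mol^-1]

positive when the forward direction is spontaneous.  The specific internal
entropy production (per unit volume) is

    sigma_int = R * sum_rho (v_f - v_r) * ln(v_f / v_r)   >= 0
              = (1/T) * sum_rho Af_rho * (v_f - v_r)      [J K^-1 s^-1 L^-1]

Matter exchange with the surroundings (CSTR flows, or the implied fluxes
that hold clamped species fixed) carries the entropy current

    sigma_exch = -(1/T) * sum_k mu_k * J_k

with J_k the net inflow of species k and mu_k = R*T*ln(c_k / c_k,ref) the
chemical potential relative to a detailed-balance equilibrium of the closed
chemical subnetwork (ideal activities).  With this bookkeeping
sigma_int + sigma_exch vanishes identically at any stationary state — the
balance every NESS must satisfy — while off-stationary compositions trace
out whole curves of zero balance, which is why a zero balance alone is
never a NESS certificate and is always reported next to max|dc/dt|.

The general evolution criterion (GEC) splits the time derivative of the
entropy production into a force part and a current part,

    dP/dt = d_F P/dt + d_J P/dt ,      d_F P/dt <= 0 ,

where the force part follows analytically from the chain rule,
d_F P/dt = -R * sum_k (dc_k/dt)^2 / c_k over all non-clamped species once
exchange flows are decomposed, like reactions, into unidirectional
inflow/outflow steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
from scipy.optimize import brentq

from .dynamics import (
    DEFAULT_SEED,
    SteadyState,
    Trajectory,
    integrate,
)
from .errors import (
    DomainError,
    ThermodynamicallyIncompleteError,
    UndefinedAffinityError,
    WegscheiderError,
)
from .network import ReactionNetwork, _integer_left_nullspace, pair_rates


# -- data records -------------------------------------------------------------


@dataclass
class ThermoState:
    """Thermodynamic snapshot of one composition."""

    conc: np.ndarray
    pair_ids: list
    v_forward: np.ndarray
    v_reverse: np.ndarray
    affinities: np.ndarray          # J mol^-1, per pair
    sigma_int: float                # J K^-1 s^-1 L^-1
    sigma_exch: float
    sigma_total: float
    chem_potentials: np.ndarray | None   # J mol^-1, per species
    max_dcdt: float
    clamped: bool                   # clamped-scenario caveat label


@dataclass
class BalanceReport:
    sigma_int: float
    sigma_exch: float
    sigma_total: float
    max_dcdt: float
    is_stationary: bool
    balance_only: bool              # zero balance at a non-stationary point
    clamped: bool


@dataclass
class GECRecord:
    """Force/current split of dP/dt at one trajectory point."""

    time: float
    P: float        # entropy production incl. exchange pseudo-pairs
    dP: float
    dFP: float      # force part, always <= 0
    dJP: float      # current part
    sigma_int: float


@dataclass
class ProbeFate:
    name: str
    direction: np.ndarray
    fate: str                      # 'returned' | 'escaped:<target>'
    final_state: np.ndarray
    gec_ok: bool


@dataclass
class ProbeReport:
    ness_conc: np.ndarray
    radius: float
    fates: list
    classification: str            # 'well' | 'saddle'
    returning: list                # names of directions that returned
    gec_ok: bool

    @property
    def all_returned(self) -> bool:
        return all(f.fate == "returned" for f in self.fates)


@dataclass
class ContourResult:
    species_pair: tuple
    points: np.ndarray             # (m, 2) refined zero-balance points
    is_stationary: np.ndarray      # (m,) bool
    dcdt_norms: np.ndarray
    base: np.ndarray


@dataclass
class SelectivityReport:
    ratio: float                   # [C]/[D]
    keq_ratio: float
    affinity_factor: float         # exp((Af_D - Af_C)/RT)
    predicted: float
    residual: float


# -- pair-level quantities ----------------------------------------------------


def _require_complete(network: ReactionNetwork) -> None:
    if not network.thermodynamically_complete:
        labels = [str(j) for j in network.unpaired]
        raise ThermodynamicallyIncompleteError(
            "network has strictly irreversible reactions (indices "
            + ", ".join(labels)
            + "); affinities are undefined without a reverse partner"
        )


def affinities(network: ReactionNetwork, conc) -> np.ndarray:
    """Per-pair affinity Af = R*T*ln(v_f/v_r), J mol^-1."""
    _require_complete(network)
    vf, vr = pair_rates(network, conc)
    for pid, f, r in zip(network.pair_ids, vf, vr):
        if f <= 0 or r <= 0:
            raise UndefinedAffinityError(
                f"pair {pid!r}: zero {'forward' if f <= 0 else 'reverse'} "
                "rate, affinity undefined"
            )
    RT = network.gas_constant * network.temperature
    return RT * np.log(vf / vr)


def entropy_production_internal(network: ReactionNetwork, conc) -> float:
    """sigma_int = R * sum (v_f - v_r) ln(v_f/v_r), J K^-1 s^-1 L^-1."""
    _require_complete(network)
    vf, vr = pair_rates(network, conc)
    for pid, f, r in zip(network.pair_ids, vf, vr):
        if f <= 0 or r <= 0:
            raise UndefinedAffinityError(
                f"pair {pid!r}: zero unidirectional rate"
            )
    return float(network.gas_constant * np.sum((vf - vr) * np.log(vf / vr)))


# -- reference equilibrium (relative chemical potentials) --------------------


def _pair_stoich(network: ReactionNetwork) -> np.ndarray:
    """Net stoichiometry of the forward member of each pair,
    shape (n_species, n_pairs)."""
    cols = [network.stoichiometric_matrix[:, network.pairs[p][0]]
            for p in network.pair_ids]
    return np.array(cols).T if cols else np.zeros((network.n_species, 0))


def check_wegscheider(network: ReactionNetwork, tol=1e-8):
    """Least-squares consistency of ln(k_f/k_r) with a potential assignment.

    Returns the particular solution x0 of N_pair^T x = ln(kf/kr); raises
    WegscheiderError when the cycle conditions are violated.
    """
    _require_complete(network)
    Np = _pair_stoich(network)
    kf = np.array([network.reactions[network.pairs[p][0]].rate_constant
                   for p in network.pair_ids])
    kr = np.array([network.reactions[network.pairs[p][1]].rate_constant
                   for p in network.pair_ids])
    b = np.log(kf / kr)
    if b.size == 0:
        return np.zeros(network.n_species)
    x0, *_ = np.linalg.lstsq(Np.T, b, rcond=None)
    resid = float(np.max(np.abs(Np.T @ x0 - b))) if b.size else 0.0
    if resid > tol * max(1.0, float(np.max(np.abs(b)))):
        raise WegscheiderError(
            "rate constants violate the detailed-balance (Wegscheider) cycle "
            f"conditions (residual {resid:.3e}); supply explicit standard "
            "potentials instead"
        )
    return x0


def reference_equilibrium(network: ReactionNetwork, conc=None,
                          tol=1e-12) -> np.ndarray:
    """Detailed-balance equilibrium of the closed chemical subnetwork on the
    stoichiometric class of ``conc`` (default: the initial concentrations).

    All species are treated as free (flows and clamps removed); the
    equilibrium satisfies v_f = v_r for every pair and conserves every
    moiety total of ``conc``.
    """
    x0 = check_wegscheider(network)
    conc = network.init_conc if conc is None else np.asarray(conc, float)
    Np = _pair_stoich(network)
    M = _integer_left_nullspace(Np)          # moieties of the closed chemistry
    if M.shape[0] == 0:
        c_ref = np.exp(x0)
    else:
        totals = M @ conc
        if (totals <= 0).any():
            raise DomainError(
                "every conserved moiety must have positive total to define "
                "the reference equilibrium"
            )

        def g(alpha):
            return M @ np.exp(x0 + M.T @ alpha) - totals

        def jac(alpha):
            return (M * np.exp(x0 + M.T @ alpha)) @ M.T

        sol = scipy.optimize.root(g, np.zeros(M.shape[0]), jac=jac,
                                  method="hybr", options={"xtol": 1e-13})
        if np.max(np.abs(g(sol.x))) > 1e-9 * max(
                1.0, float(np.max(totals))):
            raise DomainError("reference-equilibrium solve did not converge")
        c_ref = np.exp(x0 + M.T @ sol.x)
    # certify detailed balance
    vf, vr = pair_rates(network, c_ref)
    if vf.size and np.max(np.abs(vf - vr)) > 1e-8 * max(1.0, float(np.max(vf))):
        raise DomainError("reference composition is not detailed-balanced")
    return c_ref


def chemical_potentials(network: ReactionNetwork, conc, ref) -> np.ndarray:
    """mu_k = R*T*ln(c_k / c_k,ref), J mol^-1 (ideal activities)."""
    conc = np.asarray(conc, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if (conc <= 0).any():
        raise DomainError("chemical potentials need strictly positive "
                          "concentrations")
    RT = network.gas_constant * network.temperature
    return RT * np.log(conc / ref)


def _check_ref_equilibrium(network, ref):
    ref = np.asarray(ref, dtype=float)
    if (ref <= 0).any():
        raise DomainError("reference equilibrium must be strictly positive")
    vf, vr = pair_rates(network, ref)
    scale = max(1.0, float(np.max(vf)) if vf.size else 1.0)
    if vf.size and np.max(np.abs(vf - vr)) > 1e-9 * scale:
        raise DomainError(
            "supplied reference is not a detailed-balance equilibrium "
            f"(max |v_f - v_r| = {np.max(np.abs(vf - vr)):.3e})"
        )
    return ref


def entropy_production_relative(network: ReactionNetwork, conc,
                                ref_equilibrium) -> float:
    """Internal entropy production from relative chemical potentials,
    summed over *unidirectional* reactions:

        sigma = -R * sum_rho v_rho * sum_k nu_k,rho * ln(c_k / c_k,eq)

    Must equal :func:`entropy_production_internal` whenever the rate
    constants satisfy detailed balance at ``ref_equilibrium``.
    """
    _require_complete(network)
    ref = _check_ref_equilibrium(network, ref_equilibrium)
    conc = np.asarray(conc, dtype=float)
    if (conc <= 0).any():
        raise DomainError("composition must be strictly positive")
    v = network.rates(conc)
    N = network.stoichiometric_matrix
    lnr = np.log(conc / ref)
    return float(-network.gas_constant * np.sum(v * (N.T @ lnr)))


# -- exchange entropy and NESS balance ---------------------------------------


def exchange_fluxes(network: ReactionNetwork, conc) -> np.ndarray:
    """Net inflow J_k per species: CSTR flow terms on exchanged species plus
    the implied fluxes that hold clamped species at fixed concentration."""
    conc = np.asarray(conc, dtype=float)
    J = np.zeros(network.n_species)
    if network.flow_rate > 0:
        J[network.exchanged_mask] = network.flow_rate * (
            network.inflow[network.exchanged_mask]
            - conc[network.exchanged_mask]
        )
    if network.clamped_mask.any():
        prod = network.stoichiometric_matrix @ network.rates(conc)
        J[network.clamped_mask] = -prod[network.clamped_mask]
    return J


def entropy_exchange(network: ReactionNetwork, conc, ref=None,
                     mu_standard=None) -> float:
    """sigma_exch = -(1/T) sum_k mu_k J_k over exchanged (and clamped)
    species; 0 for closed networks.

    ``mu_standard`` (J mol^-1 per species, with mu = mu0 + R*T*ln c) may be
    supplied for networks whose constants violate Wegscheider consistency;
    otherwise the reference equilibrium fixes the potentials.
    """
    if network.is_closed:
        return 0.0
    conc = np.asarray(conc, dtype=float)
    if mu_standard is not None:
        RT = network.gas_constant * network.temperature
        mu = np.asarray(mu_standard, float) + RT * np.log(conc)
    else:
        if ref is None:
            ref = reference_equilibrium(network, conc)
        mu = chemical_potentials(network, conc, ref)
    J = exchange_fluxes(network, conc)
    return float(-np.sum(mu * J) / network.temperature)


def balance_residual(network: ReactionNetwork, conc, ref=None,
                     mu_standard=None, stationary_tol=1e-9,
                     balance_tol=None) -> BalanceReport:
    """sigma_int + sigma_exch, reported alongside max|dc/dt| so a zero
    balance is never mistaken for a NESS certificate."""
    s_int = entropy_production_internal(network, conc)
    s_exch = entropy_exchange(network, conc, ref=ref, mu_standard=mu_standard)
    total = s_int + s_exch
    max_dcdt = float(np.max(np.abs(network.time_derivatives(conc))))
    if balance_tol is None:
        balance_tol = 1e-10 * max(s_int, network.gas_constant)
    stationary = max_dcdt < stationary_tol
    return BalanceReport(
        sigma_int=s_int, sigma_exch=s_exch, sigma_total=total,
        max_dcdt=max_dcdt, is_stationary=stationary,
        balance_only=(abs(total) < balance_tol and not stationary),
        clamped=bool(network.clamped_mask.any()),
    )


def thermo_state(network: ReactionNetwork, conc, ref=None,
                 mu_standard=None) -> ThermoState:
    """Full thermodynamic snapshot at one composition."""
    conc = np.asarray(conc, dtype=float)
    Af = affinities(network, conc)
    vf, vr = pair_rates(network, conc)
    s_int = entropy_production_internal(network, conc)
    s_exch = entropy_exchange(network, conc, ref=ref, mu_standard=mu_standard)
    mu = None
    if not network.is_closed or (conc > 0).all():
        try:
            if mu_standard is not None:
                RT = network.gas_constant * network.temperature
                mu = np.asarray(mu_standard, float) + RT * np.log(conc)
            else:
                r = ref if ref is not None else reference_equilibrium(
                    network, conc)
                mu = chemical_potentials(network, conc, r)
        except (WegscheiderError, DomainError):
            mu = None
    return ThermoState(
        conc=conc, pair_ids=list(network.pair_ids), v_forward=vf,
        v_reverse=vr, affinities=Af, sigma_int=s_int, sigma_exch=s_exch,
        sigma_total=s_int + s_exch, chem_potentials=mu,
        max_dcdt=float(np.max(np.abs(network.time_derivatives(conc)))),
        clamped=bool(network.clamped_mask.any()),
    )


# -- general evolution criterion ----------------------------------------------


def _exchange_forces(network, conc):
    """Per-exchanged-species force X_k and current J_k of the exchange step.

    Exchange is decomposed like a reaction: inflow at f*c_in against outflow
    at f*c, force X = R*T*ln(c_in/c).  A pure outflow (c_in = 0) has no
    inflow partner; its force is measured against the 1 mol/L standard
    state, X = -R*T*ln(c).  The force *derivative* -R*T*(dc/dt)/c is the
    same either way, so the GEC force part is convention-free.
    """
    RT = network.gas_constant * network.temperature
    f = network.flow_rate
    idx = np.nonzero(network.exchanged_mask)[0]
    X = np.zeros(len(idx))
    J = np.zeros(len(idx))
    for i, k in enumerate(idx):
        cin, c = network.inflow[k], conc[k]
        J[i] = f * (cin - c)
        X[i] = RT * np.log(cin / c) if cin > 0 else -RT * np.log(c)
    return idx, X, J


def gec_point(network: ReactionNetwork, conc, dcdt=None):
    """(P, dP, dFP, dJP, sigma_int) at one strictly positive composition.

    All derivatives are analytic (chain rule through the mass-action
    monomials); no finite differencing enters.
    """
    _require_complete(network)
    conc = np.asarray(conc, dtype=float)
    if (conc <= 0).any():
        raise DomainError("GEC needs strictly positive concentrations")
    T = network.temperature
    RT = network.gas_constant * T
    if dcdt is None:
        dcdt = network.time_derivatives(conc)
    v = network.rates(conc)
    dv = network.rate_jacobian(conc) @ dcdt          # dv_rho/dt per reaction
    idxf = np.array([network.pairs[p][0] for p in network.pair_ids], int)
    idxr = np.array([network.pairs[p][1] for p in network.pair_ids], int)
    vf, vr = v[idxf], v[idxr]
    w = vf - vr
    Af = RT * np.log(vf / vr)
    dAf = RT * (dv[idxf] / vf - dv[idxr] / vr)
    dw = dv[idxf] - dv[idxr]
    P = float(np.sum(Af * w) / T)
    dFP = float(np.sum(w * dAf) / T)
    dJP = float(np.sum(Af * dw) / T)
    sigma_int = P

    if network.flow_rate > 0:
        idx, X, J = _exchange_forces(network, conc)
        dX = -RT * dcdt[idx] / conc[idx]
        dJ = -network.flow_rate * dcdt[idx]
        P += float(np.sum(X * J) / T)
        dFP += float(np.sum(J * dX) / T)
        dJP += float(np.sum(X * dJ) / T)
    if network.clamped_mask.any():
        # implied clamp fluxes: constant force (c clamped), varying current
        k = np.nonzero(network.clamped_mask)[0]
        Jc = -(network.stoichiometric_matrix @ v)[k]
        Xc = -RT * np.log(conc[k])
        dJc = -(network.stoichiometric_matrix @ dv)[k]
        P += float(np.sum(Xc * Jc) / T)
        dJP += float(np.sum(Xc * dJc) / T)
    return P, dFP + dJP, dFP, dJP, sigma_int


def gec_decomposition(network: ReactionNetwork,
                      trajectory: Trajectory) -> list:
    """Force/current split of dP/dt along a trajectory (list of GECRecord).

    Raises on non-positive concentrations, naming the offending time point.
    """
    records = []
    for t, c, dc in zip(trajectory.times, trajectory.states,
                        trajectory.derivatives):
        if (c <= 0).any():
            bad = network.species_names[int(np.argmin(c))]
            raise DomainError(
                f"non-positive concentration of {bad} at t = {t!r}"
            )
        P, dP, dFP, dJP, s_int = gec_point(network, c, dc)
        records.append(GECRecord(float(t), P, dP, dFP, dJP, s_int))
    return records


def gec_force_closed_form(network: ReactionNetwork, conc) -> float:
    """Independent closed form of the GEC force part,
    dFP = -R * sum_k (dc_k/dt)^2 / c_k over non-clamped species."""
    conc = np.asarray(conc, dtype=float)
    dcdt = network.time_derivatives(conc)
    free = ~network.clamped_mask
    return float(-network.gas_constant
                 * np.sum(dcdt[free] ** 2 / conc[free]))


# -- local-potential probe ----------------------------------------------------


def local_potential_probe(network: ReactionNetwork, ness: SteadyState,
                          radius=None, n_directions: int = 16,
                          seed: int = DEFAULT_SEED, named_directions=None,
                          known_attractors=None, return_rtol=1e-6,
                          attractor_rtol=1e-4, t_factor=50.0,
                          conc_ceiling=1e3, check_gec=True,
                          steady_tol=1e-11) -> ProbeReport:
    """Fate of small compositional fluctuations around a NESS.

    Perturbs the stationary composition along seeded random unit directions
    (plus any named symmetry directions), integrates each probe, verifies
    d_F P/dt <= 0 along the probe paths, and classifies the NESS as a well
    (every direction returns) or a saddle (mixed fates), listing the
    returning directions.
    """
    if n_directions < 8:
        raise DomainError("n_directions must be >= 8")
    c_star = np.asarray(ness.conc, dtype=float)
    pos = c_star[c_star > 0]
    if radius is None:
        radius = 1e-3 * float(pos.min())
    rng = np.random.default_rng(seed)
    n = network.n_species
    free = ~network.clamped_mask
    # admissible fluctuations live in the reactive subspace: clamped
    # components stay fixed and conserved-moiety displacements are removed
    # (they would relax to a different stoichiometric class, not back)
    from .network import conservation_laws

    cons = conservation_laws(network)

    def admissible(vec):
        vec = np.where(free, np.asarray(vec, dtype=float), 0.0)
        for m in cons:
            mm = m @ m
            if mm > 0:
                vec = vec - (m @ vec) / mm * m
        nrm = np.linalg.norm(vec)
        return vec / nrm if nrm > 1e-12 else None

    directions = []
    if named_directions:
        for name, vec in named_directions.items():
            v = admissible(vec)
            if v is not None:
                directions.append((name, v))
    i = 0
    while sum(1 for nm, _ in directions
              if nm.startswith("random")) < n_directions:
        v = admissible(rng.standard_normal(n))
        i += 1
        if v is not None:
            directions.append((f"random{i - 1}", v))
        if i > 10 * n_directions:
            break

    lam = np.abs(np.asarray(ness.jacobian_eigenvalues).real)
    lam = lam[lam > 1e-9]
    t_end = min(t_factor / lam.min(), 1e7) if lam.size else 1e5

    fates = []
    scale = max(1.0, float(np.linalg.norm(c_star)))
    for name, vec in directions:
        c0 = np.clip(c_star + radius * vec, 0.0, None)
        traj = integrate(network, c0, t_end, steady_tol=steady_tol)
        final = traj.final_state
        gec_ok = True
        if check_gec:
            gec_ok = _gec_ok_along(network, traj)
        if np.linalg.norm(final - c_star) / scale < return_rtol:
            fate = "returned"
        else:
            fate = "escaped:unknown"
            if (final > conc_ceiling).any():
                fate = "escaped:unbounded"
            elif known_attractors is not None:
                for j, att in enumerate(known_attractors):
                    att = np.asarray(att, dtype=float)
                    s = max(1.0, float(np.linalg.norm(att)))
                    if np.linalg.norm(final - att) / s < attractor_rtol:
                        fate = f"escaped:attractor{j}"
                        break
        fates.append(ProbeFate(name, vec, fate, final, gec_ok))

    returning = [f.name for f in fates if f.fate == "returned"]
    classification = "well" if len(returning) == len(fates) else "saddle"
    return ProbeReport(c_star, float(radius), fates, classification,
                       returning, all(f.gec_ok for f in fates))


def _gec_ok_along(network, traj, tol_scale=1e-10) -> bool:
    for c, dc in zip(traj.states, traj.derivatives):
        if (c <= 0).any():
            continue
        _, _, dFP, _, _ = gec_point(network, c, dc)
        floor = tol_scale * max(network.gas_constant, abs(dFP))
        if dFP > floor:
            return False
    return True


# -- zero-balance contour -----------------------------------------------------


def balance_zero_contour(network: ReactionNetwork, species_pair,
                         grid1, grid2, base=None, ref=None,
                         stationary_tol=1e-6) -> ContourResult:
    """Zero-level set of sigma_int + sigma_exch over a 2-D concentration
    grid of two scanned species, the others fixed at ``base`` (default the
    network's initial concentrations).

    Sign changes of the balance along each grid line are refined by
    bisection; each contour point is marked stationary or not via
    max|dc/dt|, exhibiting the paper-level point that the zero-balance set
    is a curve of which at most a few points are actual NESSs.
    """
    if network.is_closed:
        raise DomainError("contour operation needs an open network")
    i1 = network.species_index(species_pair[0])
    i2 = network.species_index(species_pair[1])
    base = network.init_conc if base is None else np.asarray(base, float)
    if ref is None:
        ref = reference_equilibrium(network, base)
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    if (grid1 <= 0).any() or (grid2 <= 0).any():
        raise DomainError("grids must be strictly positive")

    def sigma_total(x, y):
        c = base.copy()
        c[i1], c[i2] = x, y
        return (entropy_production_internal(network, c)
                + entropy_exchange(network, c, ref=ref))

    points = []
    for x in grid1:
        vals = np.array([sigma_total(x, y) for y in grid2])
        for j in range(len(grid2) - 1):
            if np.sign(vals[j]) * np.sign(vals[j + 1]) < 0:
                y0 = brentq(lambda y: sigma_total(x, y),
                            grid2[j], grid2[j + 1], xtol=1e-14, rtol=1e-14)
                points.append((x, y0))
    for y in grid2:
        vals = np.array([sigma_total(x, y) for x in grid1])
        for j in range(len(grid1) - 1):
            if np.sign(vals[j]) * np.sign(vals[j + 1]) < 0:
                x0 = brentq(lambda x: sigma_total(x, y),
                            grid1[j], grid1[j + 1], xtol=1e-14, rtol=1e-14)
                points.append((x0, y))

    pts = np.array(points) if points else np.zeros((0, 2))
    norms, flags = [], []
    for x, y in pts:
        c = base.copy()
        c[i1], c[i2] = x, y
        nrm = float(np.max(np.abs(network.time_derivatives(c))))
        norms.append(nrm)
        flags.append(nrm < stationary_tol)
    return ContourResult((species_pair[0], species_pair[1]), pts,
                         np.array(flags, dtype=bool), np.array(norms), base)


# -- selectivity identity -----------------------------------------------------


def selectivity_identity_residual(network: ReactionNetwork, conc,
                                  pairC: str, pairD: str) -> SelectivityReport:
    """Residual of the competitive-selectivity identity

        [C]/[D] = (KeqC/KeqD) * exp((Af_D - Af_C) / (R*T))

    at a composition (exact at every NESS of a competitive network; an
    algebraic identity under mass-action affinities, reported as an internal
    consistency certificate).
    """
    conc = np.asarray(conc, dtype=float)
    Af = affinities(network, conc)
    af = dict(zip(network.pair_ids, Af))
    RT = network.gas_constant * network.temperature

    def product_species(pid):
        jf = network.pairs[pid][0]
        net = network.stoichiometric_matrix[:, jf]
        made = np.nonzero(net > 0)[0]
        if len(made) != 1:
            raise DomainError(
                f"pair {pid!r} must produce exactly one species")
        return made[0]

    iC, iD = product_species(pairC), product_species(pairD)
    if conc[iD] <= 0:
        raise DomainError("zero concentration of the D-channel product")

    def keq(pid):
        jf, jr = network.pairs[pid]
        return (network.reactions[jf].rate_constant
                / network.reactions[jr].rate_constant)

    keq_ratio = keq(pairC) / keq(pairD)
    factor = float(np.exp((af[pairD] - af[pairC]) / RT))
    predicted = keq_ratio * factor
    ratio = float(conc[iC] / conc[iD])
    return SelectivityReport(ratio, keq_ratio, factor, predicted,
                             abs(ratio - predicted))
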