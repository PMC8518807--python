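"""Time integration, steady-state location, linear stability and branch scans.

Stationary states of driven networks (NESSs) are found either by stiff
integration until the right-hand side vanishes or by multistart root
finding on the kinetic equations restricted to the stoichiometric
compatibility class of a reference composition.  Stability is decided
twice — by Routh–Hurwitz conditions on the characteristic polynomial and
by direct eigenvalues — and the two verdicts must agree; conserved
directions are deflated first so that structural zero eigenvalues of
closed systems are not mistaken for marginality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.integrate import solve_ivp

from .errors import DomainError, IntegrationError
from .network import ReactionNetwork, conservation_laws

DEFAULT_SEED = 20210805

#: absolute residual bound, mol L^-1 s^-1, for a composition to count as steady
STEADY_RESIDUAL_TOL = 1e-9


@dataclass
class Trajectory:
    """Time-ordered concentration states with their derivatives."""

    times: np.ndarray
    states: np.ndarray        # (n_times, n_species)
    derivatives: np.ndarray   # (n_times, n_species)
    reached_steady: bool = False
    message: str = ""

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def __len__(self):
        return len(self.times)


@dataclass
class StabilityReport:
    verdict: str                    # stable | unstable | marginal
    eigenvalues: np.ndarray
    n_unstable: int
    routh_hurwitz_verdict: str
    eigenvalue_verdict: str
    char_poly: np.ndarray | None
    warning: str | None = None


@dataclass
class SteadyState:
    conc: np.ndarray
    residual_norm: float
    jacobian_eigenvalues: np.ndarray
    verdict: str
    n_unstable: int
    stability: StabilityReport | None = None

    @property
    def is_stable(self) -> bool:
        return self.verdict == "stable"


@dataclass
class BranchScan:
    parameter: str
    grid: np.ndarray
    states_up: list
    states_down: list | None
    sigma_up: np.ndarray
    sigma_down: np.ndarray | None
    hysteresis: bool
    limit_points: list
    slope_discontinuities: list
    bidirectional: bool


# -- integration -------------------------------------------------------------


def integrate(network: ReactionNetwork, c0, t_end, *, t_eval=None,
              rtol=1e-10, atol=1e-12, method="Radau",
              steady_tol=None, max_step=np.inf) -> Trajectory:
    """Stiff-capable integration of the kinetic equations.

    When ``steady_tol`` is given, integration stops early once
    ``max|dc/dt| < steady_tol`` (the event sets ``reached_steady``).
    Concentrations are solved in the original variables; negative
    excursions smaller than ``100*atol`` in magnitude are clipped to zero
    post hoc.
    """
    c0 = np.asarray(c0, dtype=float)
    if (c0 < 0).any():
        raise DomainError("initial concentrations must be >= 0")
    if not t_end > 0:
        raise DomainError("t_end must be > 0")

    def rhs(t, y):
        return network.time_derivatives(np.clip(y, 0.0, None))

    def jac(t, y):
        return network.jacobian(np.clip(y, 0.0, None))

    events = None
    if steady_tol is not None:
        def steady_event(t, y):
            return float(np.max(np.abs(rhs(t, y)))) - steady_tol
        steady_event.terminal = True
        steady_event.direction = -1
        events = [steady_event]

    sol = solve_ivp(rhs, (0.0, t_end), c0, method=method, jac=jac,
                    t_eval=t_eval, rtol=rtol, atol=atol, events=events,
                    max_step=max_step, dense_output=False)
    if not sol.success and sol.status != 1:
        raise IntegrationError(
            f"solver failed: {sol.message}",
            t=sol.t[-1] if sol.t.size else 0.0,
            last_state=sol.y[:, -1] if sol.t.size else c0,
        )
    states = sol.y.T.copy()
    neg = states < 0
    small = neg & (states > -100 * atol)
    states[small] = 0.0
    derivs = np.array([network.time_derivatives(np.clip(s, 0.0, None))
                       for s in states])
    reached = bool(sol.status == 1)
    return Trajectory(sol.t.copy(), states, derivs, reached_steady=reached,
                      message=sol.message)


def integrate_to_steady(network: ReactionNetwork, c0, *, steady_tol=1e-10,
                        t_max=1e8, **kw) -> Trajectory:
    """Integrate until max|dc/dt| < steady_tol (or t_max)."""
    traj = integrate(network, c0, t_max, steady_tol=steady_tol, **kw)
    return traj


# -- Jacobian and stability ---------------------------------------------------


def jacobian_at(network: ReactionNetwork, conc) -> np.ndarray:
    """Analytic Jacobian of dc/dt at ``conc`` (clamped rows zero)."""
    return network.jacobian(conc)


def _char_poly_coeffs(J: np.ndarray) -> np.ndarray:
    """Coefficients of det(sI - J) by Faddeev–LeVerrier,
    [1, a1, ..., an]; independent of any eigenvalue computation."""
    n = J.shape[0]
    coeffs = np.empty(n + 1)
    coeffs[0] = 1.0
    M = np.eye(n)
    for k in range(1, n + 1):
        JM = J @ M
        c = -np.trace(JM) / k
        coeffs[k] = c
        M = JM + c * np.eye(n)
    return coeffs


def _routh_verdict(coeffs: np.ndarray, tol: float) -> str:
    """Routh–Hurwitz verdict for the polynomial with given coefficients
    (leading coefficient positive): 'stable' when every first-column entry
    of the Routh array is positive, 'unstable' on a sign change, 'marginal'
    when a pivot is numerically zero."""
    n = len(coeffs) - 1
    if n == 0:
        return "stable"
    rows = np.zeros((n + 1, (n // 2) + 2))
    rows[0, : len(coeffs[0::2])] = coeffs[0::2]
    rows[1, : len(coeffs[1::2])] = coeffs[1::2]
    for i in range(2, n + 1):
        pivot = rows[i - 1, 0]
        if abs(pivot) <= tol:
            return "marginal"
        for j in range(rows.shape[1] - 1):
            rows[i, j] = (
                rows[i - 1, 0] * rows[i - 2, j + 1]
                - rows[i - 2, 0] * rows[i - 1, j + 1]
            ) / rows[i - 1, 0]
    first = rows[: n + 1, 0]
    if np.any(np.abs(first) <= tol):
        return "marginal"
    return "stable" if np.all(first > 0) else "unstable"


def classify_stability(jacobian: np.ndarray, *, conserved=None,
                       tol=1e-9) -> StabilityReport:
    """Verdict from Routh–Hurwitz on the characteristic polynomial AND from
    direct eigenvalues; the two must agree, otherwise the state is reported
    marginal with a warning.

    ``conserved`` may carry a (q, n) basis of conserved directions that is
    deflated (the Jacobian is projected onto the orthogonal complement)
    before either criterion runs, so structural zeros do not pollute the
    verdict.
    """
    J = np.asarray(jacobian, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise DomainError("jacobian must be square")
    if conserved is not None:
        conserved = np.atleast_2d(np.asarray(conserved, dtype=float))
        if conserved.size and conserved.shape[0] > 0:
            B = scipy.linalg.null_space(conserved)
            J = B.T @ J @ B
    eigs = np.linalg.eigvals(J)
    scale = max(1.0, float(np.max(np.abs(J))) if J.size else 1.0)
    etol = tol * scale
    n_unstable = int(np.sum(eigs.real > etol))
    if np.all(eigs.real < -etol):
        ev = "stable"
    elif n_unstable > 0:
        ev = "unstable"
    else:
        ev = "marginal"

    warning = None
    coeffs = _char_poly_coeffs(J) if J.size else np.array([1.0])
    if not np.all(np.isfinite(coeffs)):
        rh = ev
        coeffs = None
        warning = "characteristic polynomial overflow; eigenvalues only"
    else:
        ptol = tol * max(1.0, float(np.max(np.abs(coeffs))))
        rh = _routh_verdict(coeffs, ptol)

    if rh == ev:
        verdict = rh
    elif "marginal" in (rh, ev):
        verdict = "marginal"
    else:
        verdict = "marginal"
        warning = (warning or "") + " Routh–Hurwitz and eigenvalue verdicts disagree"
    return StabilityReport(verdict, eigs, n_unstable, rh, ev, coeffs, warning)


# -- steady states ------------------------------------------------------------


def _class_basis(network: ReactionNetwork):
    """(free index array, orthonormal basis B of the reactive subspace of the
    free coordinates).  Columns of B span the directions along which the
    dynamics can move; conserved moieties are orthogonal to them."""
    free = np.nonzero(~network.clamped_mask)[0]
    cons = conservation_laws(network)
    if cons.shape[0]:
        M = cons[:, free]
        B = scipy.linalg.null_space(M)
    else:
        B = np.eye(len(free))
    return free, B


def find_steady_states(network: ReactionNetwork, n_starts: int = 64,
                       seed: int = DEFAULT_SEED, guesses=None,
                       anchor=None, window=(1e-6, 1e2),
                       dedup_rtol=1e-6) -> list:
    """Multistart root search for all non-negative stationary compositions.

    Roots are sought on the stoichiometric compatibility class of ``anchor``
    (default: the network's initial concentrations), polished, deduplicated
    at relative distance ``dedup_rtol``, validated by a short integration,
    and returned with stability verdicts (conserved directions deflated).
    """
    if n_starts < 1:
        raise DomainError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    free, B = _class_basis(network)
    anchor = network.init_conc if anchor is None else np.asarray(anchor, float)
    c_full = anchor.copy()

    def assemble(xi):
        c = c_full.copy()
        c[free] = anchor[free] + B @ xi
        return c

    def residual(xi):
        return B.T @ network.time_derivatives(
            np.clip(assemble(xi), 0.0, None))[free]

    lo, hi = np.log(window[0]), np.log(window[1])
    starts = [np.zeros(B.shape[1])]
    if guesses is not None:
        for g in guesses:
            g = np.asarray(g, dtype=float)
            starts.append(B.T @ (g[free] - anchor[free]))
    for _ in range(n_starts):
        c_s = np.exp(rng.uniform(lo, hi, size=len(free)))
        starts.append(B.T @ (c_s - anchor[free]))

    found: list[SteadyState] = []
    for xi0 in starts:
        sol = scipy.optimize.root(residual, xi0, method="hybr",
                                  options={"xtol": 1e-13})
        c = assemble(sol.x)
        if (c < -1e-9).any():
            continue  # negative-component root discarded
        c = np.clip(c, 0.0, None)
        # polish once more from the clipped composition
        xi = B.T @ (c[free] - anchor[free])
        sol2 = scipy.optimize.root(residual, xi, method="hybr",
                                   options={"xtol": 1e-13})
        if not (assemble(sol2.x) < -1e-9).any():
            c2 = np.clip(assemble(sol2.x), 0.0, None)
            if (np.max(np.abs(network.time_derivatives(c2)))
                    <= np.max(np.abs(network.time_derivatives(c)))):
                c = c2
        res = float(np.max(np.abs(network.time_derivatives(c))))
        if res > STEADY_RESIDUAL_TOL:
            continue
        # dedupe (relative on the concentration vector)
        dup = False
        for st in found:
            scale = max(1.0, float(np.linalg.norm(st.conc)))
            if np.linalg.norm(st.conc - c) / scale < dedup_rtol:
                if res < st.residual_norm:
                    st.conc, st.residual_norm = c, res
                dup = True
                break
        if dup:
            continue
        found.append(SteadyState(c, res, np.zeros(0, dtype=complex),
                                 "marginal", 0))

    if not found:
        warnings.warn("find_steady_states: no root found")
        return []

    results = []
    cons = conservation_laws(network)
    for st in found:
        J = network.jacobian(st.conc)
        Jff = J[np.ix_(free, free)]
        rep = classify_stability(
            Jff, conserved=cons[:, free] if cons.shape[0] else None)
        ok = _validate_by_integration(network, st.conc, rep)
        if not ok:
            warnings.warn("steady state failed short-integration validation")
            continue
        results.append(SteadyState(st.conc, st.residual_norm,
                                   rep.eigenvalues, rep.verdict,
                                   rep.n_unstable, rep))
    results.sort(key=lambda s: tuple(np.round(s.conc, 9)))
    return results


def _validate_by_integration(network, conc, rep) -> bool:
    """Short integration from the root: a genuine stationary point must not
    drift on a timescale short relative to its slowest dynamics."""
    lam = np.abs(rep.eigenvalues.real)
    lam = lam[lam > 1e-12]
    t_short = 0.01 / lam.max() if lam.size else 1.0
    try:
        traj = integrate(network, conc, t_short, rtol=1e-10, atol=1e-12)
    except IntegrationError:
        return False
    scale = max(1.0, float(np.linalg.norm(conc)))
    return float(np.linalg.norm(traj.final_state - conc)) / scale < 1e-6


# -- parameter scans ----------------------------------------------------------


def set_parameter(network: ReactionNetwork, name: str,
                  value: float) -> ReactionNetwork:
    """Return a copy of the network with one scan parameter replaced.

    Accepted names: ``flow``; ``inflow:<species>``; ``kf:<pair>`` /
    ``kr:<pair>`` (forward/reverse rate constant of a reversible pair);
    ``clamp:<species>`` (clamped concentration).
    """
    from dataclasses import replace as _rep

    if name == "flow":
        return network.with_updates(flow_rate=value)
    kind, _, target = name.partition(":")
    if kind == "inflow":
        sp = [(_rep(s, inflow_conc=float(value)) if s.name == target else s)
              for s in network.species]
        return network.with_updates(species=sp)
    if kind == "clamp":
        sp = [(_rep(s, init_conc=float(value)) if s.name == target else s)
              for s in network.species]
        return network.with_updates(species=sp)
    if kind in ("kf", "kr"):
        direction = "forward" if kind == "kf" else "reverse"
        rxns = []
        hit = False
        for r in network.reactions:
            if r.pair_id == target and r.direction == direction:
                rxns.append(_rep(r, rate_constant=float(value)))
                hit = True
            else:
                rxns.append(r)
        if not hit:
            raise DomainError(f"no {direction} reaction in pair {target!r}")
        return network.with_updates(reactions=rxns)
    raise DomainError(f"unknown scan parameter {name!r}")


def scan_branch(network: ReactionNetwork, parameter: str, grid,
                bidirectional: bool = True, *, c0=None, steady_tol=1e-10,
                t_max=1e7, perturb=0.0, seed=DEFAULT_SEED,
                hysteresis_rtol=1e-4, jump_factor=20.0) -> BranchScan:
    """Continuation along a monotone parameter grid.

    At each grid point the network is integrated to steady state seeded from
    the previous point's state (optionally nudged by a relative ``perturb``
    so that an unstable symmetric branch can be abandoned); an optional
    reverse sweep starts from the final up-sweep state.  Entropy production
    is recorded per point; hysteresis is flagged when up and down sweeps
    disagree beyond tolerance at the same parameter value, and
    slope-discontinuity points are located from second-difference outliers
    (> 5x the median).
    """
    from .thermo import entropy_production_internal
    from .errors import NessflowError

    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or not (np.all(np.diff(grid) > 0)
                             or np.all(np.diff(grid) < 0)):
        raise DomainError("grid must be monotone with at least 2 points")
    rng = np.random.default_rng(seed)
    c0 = network.init_conc if c0 is None else np.asarray(c0, dtype=float)

    def sweep(values, c_seed):
        states, sigmas = [], []
        c = c_seed.copy()
        for val in values:
            net = set_parameter(network, parameter, val)
            seed_state = np.clip(c, 0.0, None)
            if perturb:
                seed_state = seed_state * (
                    1.0 + perturb * rng.uniform(-1.0, 1.0, size=len(c)))
                seed_state = np.clip(seed_state, 0.0, None)
            try:
                traj = integrate_to_steady(net, seed_state,
                                           steady_tol=steady_tol, t_max=t_max)
                if not traj.reached_steady:
                    raise IntegrationError("steady state not reached")
                c = traj.final_state
                states.append(c.copy())
                try:
                    sigmas.append(entropy_production_internal(net, c))
                except NessflowError:
                    sigmas.append(np.nan)
            except IntegrationError:
                states.append(None)
                sigmas.append(np.nan)
        return states, np.array(sigmas)

    states_up, sigma_up = sweep(grid, c0)
    states_down = sigma_down = None
    hysteresis = False
    if bidirectional:
        seed_state = next((s for s in reversed(states_up) if s is not None), c0)
        states_down_rev, sigma_down_rev = sweep(grid[::-1], seed_state)
        states_down = states_down_rev[::-1]
        sigma_down = sigma_down_rev[::-1]
        for su, sd in zip(states_up, states_down):
            if su is None or sd is None:
                continue
            scale = max(1.0, float(np.linalg.norm(su)))
            if np.linalg.norm(su - sd) / scale > hysteresis_rtol:
                hysteresis = True
                break

    limit_points = _jumps(grid, states_up, jump_factor)
    if states_down is not None:
        limit_points += _jumps(grid, states_down, jump_factor)
    discontinuities = _slope_breaks(grid, sigma_up)
    if sigma_down is not None:
        discontinuities += _slope_breaks(grid, sigma_down)
    return BranchScan(parameter, grid, states_up, states_down, sigma_up,
                      sigma_down, hysteresis, sorted(set(limit_points)),
                      sorted(set(discontinuities)), bidirectional)


def _jumps(grid, states, factor):
    steps = []
    for i in range(len(grid) - 1):
        if states[i] is None or states[i + 1] is None:
            steps.append(np.nan)
        else:
            steps.append(float(np.linalg.norm(states[i + 1] - states[i])))
    steps = np.array(steps)
    ok = np.isfinite(steps)
    if ok.sum() < 3:
        return []
    med = np.median(steps[ok])
    thresh = factor * max(med, 1e-12)
    return [float(0.5 * (grid[i] + grid[i + 1]))
            for i in np.nonzero(ok & (steps > thresh))[0]]


def _slope_breaks(grid, sigma, factor=5.0):
    ok = np.isfinite(sigma)
    if ok.sum() < 5:
        return []
    d2 = np.abs(np.diff(sigma, 2))
    d2 = d2[np.isfinite(d2)]
    if d2.size < 3:
        return []
    med = np.median(d2)
    out = []
    dd = np.diff(sigma, 2)
    for i, val in enumerate(dd):
        if np.isfinite(val) and abs(val) > factor * max(med, 1e-300):
            out.append(float(grid[i + 1]))
    return out
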