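"""Mass-action reaction networks: data model, rates, ODE right-hand side,
stoichiometric decomposition into unidirectional steps, conservation laws,
and the plain-text network dialect.

Conventions
-----------
Concentrations are in mol L^-1, time in s, temperature in K.  Activities are
ideal (gamma = 1) and the system is isothermal.  Every reversible
transformation is stored as *two* unidirectional mass-action reactions that
share a ``pair_id`` — forward and backward steps are different reactions,
each with its own current; this is the stoichiometric-network-analysis (SNA)
representation on which all the thermodynamic bookkeeping in
:mod:`nessflow.thermo` rests.

Open systems are ideal CSTRs: one dilution rate ``flow_rate`` applies to all
exchanged species, each with its own inflow concentration.  A species may
instead be *clamped* (held at a fixed concentration); clamped boundary
conditions are supported for comparison but flagged by the thermodynamic
reports, since a clamped entropy balance is a necessary, not a sufficient,
condition for a stationary state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import sympy

from .errors import (
    DomainError,
    NetworkParseError,
    NetworkValidationError,
)

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Largest stoichiometric coefficient accepted (small-molecularity mass action).
MAX_STOICH = 4

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


@dataclass(frozen=True)
class Species:
    """A chemical species and its boundary condition."""

    name: str
    init_conc: float = 0.0
    exchanged: bool = False
    inflow_conc: float = 0.0
    clamped: bool = False

    def validate(self) -> None:
        if not _NAME_RE.match(self.name):
            raise NetworkValidationError(f"invalid species name {self.name!r}")
        if self.init_conc < 0:
            raise NetworkValidationError(
                f"species {self.name}: init_conc must be >= 0"
            )
        if self.inflow_conc < 0:
            raise NetworkValidationError(
                f"species {self.name}: inflow_conc must be >= 0"
            )
        if self.clamped and self.exchanged:
            raise NetworkValidationError(
                f"species {self.name}: cannot be both clamped and exchanged"
            )


@dataclass(frozen=True)
class Reaction:
    """One unidirectional mass-action step.

    ``pair_id`` links the step to its reverse partner; ``None`` marks a
    strictly irreversible step (allowed in dynamics, rejected by every
    thermodynamic operation).
    """

    reactants: dict
    products: dict
    rate_constant: float
    pair_id: str | None = None
    direction: str = "forward"

    def validate(self) -> None:
        if not self.reactants and not self.products:
            raise NetworkValidationError("reaction with empty both sides")
        for side in (self.reactants, self.products):
            for name, coef in side.items():
                if not isinstance(coef, (int, np.integer)) or coef < 0:
                    raise NetworkValidationError(
                        f"stoichiometric coefficient of {name} must be a "
                        f"non-negative integer, got {coef!r}"
                    )
                if coef > MAX_STOICH:
                    raise NetworkValidationError(
                        f"stoichiometric coefficient of {name} exceeds "
                        f"{MAX_STOICH}"
                    )
        if not (self.rate_constant > 0):
            raise NetworkValidationError(
                f"rate constant must be > 0, got {self.rate_constant!r}"
            )
        if self.direction not in ("forward", "reverse"):
            raise NetworkValidationError(
                f"direction must be forward|reverse, got {self.direction!r}"
            )

    @property
    def order(self) -> int:
        return int(sum(self.reactants.values()))


class ReactionNetwork:
    """An ordered collection of species and unidirectional reactions with a
    CSTR exchange configuration.

    Parameters
    ----------
    species : list of Species
    reactions : list of Reaction
    temperature : float, K
    flow_rate : float, s^-1
        CSTR dilution rate applied to every exchanged species.
    """

    def __init__(self, species, reactions, temperature=300.0, flow_rate=0.0,
                 gas_constant=R_GAS):
        self.species = list(species)
        self.reactions = list(reactions)
        self.temperature = float(temperature)
        self.flow_rate = float(flow_rate)
        self.gas_constant = float(gas_constant)
        self._validate()
        self._build_arrays()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise NetworkValidationError("duplicate species names")
        for s in self.species:
            s.validate()
        if self.temperature <= 0:
            raise NetworkValidationError("temperature must be > 0")
        if self.flow_rate < 0:
            raise NetworkValidationError("flow_rate must be >= 0")
        known = set(names)
        by_pair: dict[str, dict[str, Reaction]] = {}
        for r in self.reactions:
            r.validate()
            for name in list(r.reactants) + list(r.products):
                if name not in known:
                    raise NetworkValidationError(
                        f"reaction references unknown species {name!r}"
                    )
            if r.pair_id is not None:
                slot = by_pair.setdefault(r.pair_id, {})
                if r.direction in slot:
                    raise NetworkValidationError(
                        f"duplicate {r.direction} member of pair {r.pair_id!r}"
                    )
                slot[r.direction] = r
        for pid, slot in by_pair.items():
            if set(slot) != {"forward", "reverse"}:
                raise NetworkValidationError(
                    f"pair {pid!r} lacks one of its two directions"
                )
            f, b = slot["forward"], slot["reverse"]
            if f.reactants != b.products or f.products != b.reactants:
                raise NetworkValidationError(
                    f"pair {pid!r}: reverse must mirror forward stoichiometry"
                )
        if self.flow_rate > 0 and not any(s.exchanged for s in self.species):
            raise NetworkValidationError(
                "flow_rate > 0 requires at least one exchanged species"
            )

    def _build_arrays(self) -> None:
        n_s, n_r = len(self.species), len(self.reactions)
        self._index = {s.name: i for i, s in enumerate(self.species)}
        self._reac = np.zeros((n_s, n_r), dtype=float)
        self._prod = np.zeros((n_s, n_r), dtype=float)
        self._k = np.zeros(n_r)
        for j, r in enumerate(self.reactions):
            for name, coef in r.reactants.items():
                self._reac[self._index[name], j] = coef
            for name, coef in r.products.items():
                self._prod[self._index[name], j] = coef
            self._k[j] = r.rate_constant
        self._N = self._prod - self._reac
        self.exchanged_mask = np.array([s.exchanged for s in self.species])
        self.clamped_mask = np.array([s.clamped for s in self.species])
        self.inflow = np.array([s.inflow_conc for s in self.species])
        # pair table: pair_id -> (forward index, reverse index)
        fwd: dict[str, int] = {}
        rev: dict[str, int] = {}
        order: list[str] = []
        for j, r in enumerate(self.reactions):
            if r.pair_id is None:
                continue
            if r.pair_id not in fwd and r.pair_id not in rev:
                order.append(r.pair_id)
            (fwd if r.direction == "forward" else rev)[r.pair_id] = j
        self.pair_ids = order
        self.pairs = {pid: (fwd[pid], rev[pid]) for pid in order}
        self.unpaired = [j for j, r in enumerate(self.reactions)
                         if r.pair_id is None]

    # -- simple accessors --------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_names(self) -> list:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        return self._index[name]

    @property
    def stoichiometric_matrix(self) -> np.ndarray:
        """N with shape (n_species, n_reactions); column = products-reactants."""
        return self._N.copy()

    @property
    def reactant_matrix(self) -> np.ndarray:
        return self._reac.copy()

    @property
    def init_conc(self) -> np.ndarray:
        return np.array([s.init_conc for s in self.species])

    @property
    def is_closed(self) -> bool:
        return self.flow_rate == 0.0 and not self.clamped_mask.any()

    @property
    def thermodynamically_complete(self) -> bool:
        """True when every reaction belongs to a forward/reverse pair."""
        return not self.unpaired

    def with_updates(self, *, species=None, temperature=None, flow_rate=None,
                     reactions=None):
        """Copy of the network with selected fields replaced."""
        return ReactionNetwork(
            species if species is not None else self.species,
            reactions if reactions is not None else self.reactions,
            self.temperature if temperature is None else temperature,
            self.flow_rate if flow_rate is None else flow_rate,
            self.gas_constant,
        )

    def with_init(self, conc) -> "ReactionNetwork":
        conc = np.asarray(conc, dtype=float)
        sp = [replace(s, init_conc=float(c)) for s, c in zip(self.species, conc)]
        return self.with_updates(species=sp)

    def __eq__(self, other):
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return (self.species == other.species
                and self.reactions == other.reactions
                and self.temperature == other.temperature
                and self.flow_rate == other.flow_rate
                and self.gas_constant == other.gas_constant)

    def __repr__(self):
        return (f"ReactionNetwork({self.n_species} species, "
                f"{self.n_reactions} reactions, T={self.temperature} K, "
                f"flow={self.flow_rate}/s)")

    # -- dynamics kernels ---------------------------------------------------

    def rates(self, conc) -> np.ndarray:
        """Mass-action rates v_rho = k_rho * prod_k c_k^order(k,rho)."""
        conc = np.asarray(conc, dtype=float)
        if conc.shape != (self.n_species,):
            raise DomainError(
                f"concentration vector must have length {self.n_species}"
            )
        if (conc < 0).any():
            bad = self.species_names[int(np.argmin(conc))]
            raise DomainError(f"negative concentration for species {bad}")
        # 0**0 == 1.0 in numpy, so zero concentrations are handled correctly.
        return self._k * np.prod(conc[:, None] ** self._reac, axis=0)

    def rate_jacobian(self, conc) -> np.ndarray:
        """d v_rho / d c_j, shape (n_reactions, n_species).

        One-sided at zero concentrations: the mass-action monomial
        derivative k * r * c^(r-1) * prod(others) is evaluated directly.
        """
        conc = np.asarray(conc, dtype=float)
        v = self.rates(conc)
        n_r, n_s = self.n_reactions, self.n_species
        dv = np.zeros((n_r, n_s))
        pos = conc > 0
        # fast path: v * r_j / c_j for strictly positive c_j
        dv[:, pos] = v[:, None] * self._reac[pos, :].T / conc[pos][None, :]
        # zero concentrations: derivative nonzero only for first-order entry
        for j in np.nonzero(~pos)[0]:
            for rho in range(n_r):
                r = self._reac[j, rho]
                if r == 1:
                    others = np.prod(
                        np.delete(conc, j) ** np.delete(self._reac[:, rho], j)
                    )
                    dv[rho, j] = self._k[rho] * others
                # r == 0 or r >= 2 at c_j = 0 -> derivative 0
        return dv

    def time_derivatives(self, conc) -> np.ndarray:
        """dc/dt = N v(c) + flow_rate*(c_in - c) on exchanged species;
        clamped species are held at zero derivative."""
        conc = np.asarray(conc, dtype=float)
        dcdt = self._N @ self.rates(conc)
        if self.flow_rate > 0:
            dcdt = np.where(
                self.exchanged_mask,
                dcdt + self.flow_rate * (self.inflow - conc),
                dcdt,
            )
        if self.clamped_mask.any():
            dcdt = np.where(self.clamped_mask, 0.0, dcdt)
        return dcdt

    def jacobian(self, conc) -> np.ndarray:
        """Analytic Jacobian of time_derivatives, shape (n_s, n_s);
        clamped rows are zero."""
        J = self._N @ self.rate_jacobian(conc)
        if self.flow_rate > 0:
            J[self.exchanged_mask, self.exchanged_mask] -= self.flow_rate
        if self.clamped_mask.any():
            J[self.clamped_mask, :] = 0.0
        return J


# -- module-level operation surface ---------------------------------------


def sna_decompose(network: ReactionNetwork) -> list:
    """The ordered unidirectional reaction list of the network.

    Networks are *stored* in decomposed form, so this simply exposes the
    reaction list; each reversible pair contributes exactly two entries and
    the pair mapping is total on pairs.
    """
    return list(network.reactions)


def reaction_rates(network: ReactionNetwork, conc) -> np.ndarray:
    return network.rates(conc)


def time_derivatives(network: ReactionNetwork, conc) -> np.ndarray:
    return network.time_derivatives(conc)


def pair_rates(network: ReactionNetwork, conc):
    """(v_forward, v_reverse) arrays over the network's pairs."""
    v = network.rates(conc)
    idx = np.array([network.pairs[p] for p in network.pair_ids], dtype=int)
    if idx.size == 0:
        return np.zeros(0), np.zeros(0)
    return v[idx[:, 0]], v[idx[:, 1]]


def _integer_left_nullspace(mat: np.ndarray) -> np.ndarray:
    """Primitive-integer basis of {m : m @ mat == 0} via exact arithmetic."""
    if mat.shape[0] == 0:
        return np.zeros((0, 0))
    M = sympy.Matrix(mat.astype(int).T)
    basis = M.nullspace()
    rows = []
    for vec in basis:
        denoms = [sympy.fraction(sympy.nsimplify(x))[1] for x in vec]
        scale = sympy.lcm([sympy.Integer(d) for d in denoms]) if denoms else 1
        v = [sympy.Integer(x * scale) for x in vec]
        g = sympy.gcd([x for x in v if x != 0] or [1])
        v = [int(x / g) for x in v]
        if sum(1 for x in v if x < 0) > sum(1 for x in v if x > 0):
            v = [-x for x in v]
        rows.append(v)
    if not rows:
        return np.zeros((0, mat.shape[0]))
    return np.array(rows, dtype=float)


def conservation_laws(network: ReactionNetwork) -> np.ndarray:
    """Basis of conserved moieties, shape (n_laws, n_species).

    Conserved vectors are supported on species that are neither exchanged
    nor clamped (flow and clamping both break conservation) and annihilate
    the corresponding rows of the stoichiometric matrix.  Entries on
    exchanged/clamped species are zero.
    """
    free = ~(network.exchanged_mask | network.clamped_mask)
    if not free.any():
        return np.zeros((0, network.n_species))
    basis_free = _integer_left_nullspace(network._N[free, :])
    out = np.zeros((basis_free.shape[0], network.n_species))
    out[:, free] = basis_free
    return out


# -- plain-text network dialect --------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+)\s*)?([A-Za-z_][A-Za-z0-9_]*)$")


def _parse_side(text: str, line: int) -> dict:
    text = text.strip()
    if text in ("", "0"):
        return {}
    side: dict[str, int] = {}
    for term in text.split("+"):
        m = _TERM_RE.match(term.strip())
        if not m:
            raise NetworkParseError(f"cannot parse term {term.strip()!r}", line)
        coef = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        side[name] = side.get(name, 0) + coef
    return side


def _parse_kv(tokens, line, allowed):
    out = {}
    for tok in tokens:
        if "=" not in tok:
            raise NetworkParseError(f"expected key=value, got {tok!r}", line)
        key, val = tok.split("=", 1)
        if key not in allowed:
            raise NetworkParseError(f"unknown option {key!r}", line)
        try:
            out[key] = float(val)
        except ValueError as exc:
            raise NetworkParseError(f"bad number {val!r} for {key}") from exc
    return out


def parse_network(text: str) -> ReactionNetwork:
    """Parse the line-oriented plain-text network dialect.

    ::

        # comment
        species A init=1.0 exchanged inflow=1.0
        species B init=0.0 clamped
        reaction R1: A <-> B ; kf=2.0, kr=1.0
        reaction R2: A + L -> 2 L ; kf=0.5
        system T=300 flow=0.5
    """
    species: list[Species] = []
    reactions: list[Reaction] = []
    seen_labels: set[str] = set()
    temperature, flow_rate = 300.0, 0.0
    known: set[str] = set()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        head, _, rest = line.partition(" ")
        if head == "species":
            tokens = rest.split()
            if not tokens:
                raise NetworkParseError("species line needs a name", lineno)
            name = tokens[0]
            if not _NAME_RE.match(name):
                raise NetworkParseError(f"invalid species name {name!r}", lineno)
            if name in known:
                raise NetworkParseError(f"duplicate species {name!r}", lineno)
            exchanged = "exchanged" in tokens[1:]
            clamped = "clamped" in tokens[1:]
            kv_tokens = [t for t in tokens[1:] if t not in ("exchanged", "clamped")]
            kv = _parse_kv(kv_tokens, lineno, {"init", "inflow"})
            sp = Species(name, kv.get("init", 0.0), exchanged,
                         kv.get("inflow", 0.0), clamped)
            try:
                sp.validate()
            except NetworkValidationError as exc:
                raise NetworkParseError(str(exc), lineno) from exc
            species.append(sp)
            known.add(name)
        elif head == "reaction":
            if ":" not in rest:
                raise NetworkParseError("reaction line needs 'LABEL:'", lineno)
            label, _, body = rest.partition(":")
            label = label.strip()
            if label in seen_labels:
                raise NetworkParseError(f"duplicate reaction label {label!r}",
                                        lineno)
            seen_labels.add(label)
            if ";" not in body:
                raise NetworkParseError("reaction line needs '; kf=...'", lineno)
            eqn, _, ktxt = body.partition(";")
            if "<->" in eqn:
                arrow, reversible = "<->", True
            elif "->" in eqn:
                arrow, reversible = "->", False
            else:
                raise NetworkParseError("reaction needs '->' or '<->'", lineno)
            lhs, _, rhs = eqn.partition(arrow)
            reactants = _parse_side(lhs, lineno)
            products = _parse_side(rhs, lineno)
            for nm in list(reactants) + list(products):
                if nm not in known:
                    raise NetworkParseError(
                        f"unknown species {nm!r} (declare it before use)",
                        lineno)
            kv = _parse_kv([t.strip() for t in ktxt.split(",") if t.strip()],
                           lineno, {"kf", "kr"})
            if "kf" not in kv:
                raise NetworkParseError("missing kf", lineno)
            if reversible and "kr" not in kv:
                raise NetworkParseError("reversible reaction missing kr", lineno)
            if not reversible and "kr" in kv:
                raise NetworkParseError(
                    "unidirectional reaction must not define kr", lineno)
            if kv["kf"] <= 0 or (reversible and kv["kr"] <= 0):
                raise NetworkParseError("rate constants must be > 0", lineno)
            if reversible:
                reactions.append(Reaction(reactants, products, kv["kf"],
                                          pair_id=label, direction="forward"))
                reactions.append(Reaction(products, reactants, kv["kr"],
                                          pair_id=label, direction="reverse"))
            else:
                reactions.append(Reaction(reactants, products, kv["kf"],
                                          pair_id=None, direction="forward"))
        elif head == "system":
            kv = _parse_kv(rest.split(), lineno, {"T", "flow"})
            temperature = kv.get("T", temperature)
            flow_rate = kv.get("flow", flow_rate)
        else:
            raise NetworkParseError(f"unknown directive {head!r}", lineno)

    try:
        return ReactionNetwork(species, reactions, temperature, flow_rate)
    except NetworkValidationError as exc:
        raise NetworkParseError(str(exc)) from exc


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def _fmt_side(side: dict) -> str:
    if not side:
        return "0"
    return " + ".join(
        (f"{coef} {name}" if coef != 1 else name)
        for name, coef in sorted(side.items())
    )


def serialize_network(network: ReactionNetwork) -> str:
    """Emit the network in the plain-text dialect, bit-exactly round-trippable
    (canonical ordering, 17 significant digits)."""
    lines = []
    for s in network.species:
        parts = [f"species {s.name} init={_fmt(s.init_conc)}"]
        if s.exchanged:
            parts.append("exchanged")
            parts.append(f"inflow={_fmt(s.inflow_conc)}")
        if s.clamped:
            parts.append("clamped")
        lines.append(" ".join(parts))
    emitted_pairs: set[str] = set()
    n_auto = 0
    for r in network.reactions:
        if r.pair_id is not None:
            if r.pair_id in emitted_pairs:
                continue
            emitted_pairs.add(r.pair_id)
            jf, jr = network.pairs[r.pair_id]
            f, b = network.reactions[jf], network.reactions[jr]
            lines.append(
                f"reaction {r.pair_id}: {_fmt_side(f.reactants)} <-> "
                f"{_fmt_side(f.products)} ; kf={_fmt(f.rate_constant)}, "
                f"kr={_fmt(b.rate_constant)}"
            )
        else:
            n_auto += 1
            lines.append(
                f"reaction U{n_auto}: {_fmt_side(r.reactants)} -> "
                f"{_fmt_side(r.products)} ; kf={_fmt(r.rate_constant)}"
            )
    lines.append(
        f"system T={_fmt(network.temperature)} flow={_fmt(network.flow_rate)}"
    )
    return "\n".join(lines) + "\n"
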