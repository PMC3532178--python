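"""Reaction-network model: species, reactions, conservation laws, propensities.

A :class:`ReactionNetwork` is the single source of truth for the
stoichiometric matrix ``S``, the macroscopic rate vector ``f`` and the
microscopic propensities ``a_j = Omega * f_j(n / Omega)``.  Species carry a
user-declared timescale class (``slow`` or ``fast``); the slow block always
comes first in every vector and matrix produced here, which is the ordering
assumed by the adiabatic-elimination machinery in :mod:`sslna.lna`.

Rate laws are stored as sympy expressions (mass action laws are built
automatically from the stoichiometry), so Jacobians are exact rather than
finite-differenced.  Conserved species can be eliminated from the explicit
state; their concentrations are re-expressed through the conservation law
inside every rate evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "Species",
    "Reaction",
    "ConservationLaw",
    "ReactionNetwork",
    "PartitionedSystem",
    "NetworkError",
    "stoichiometric_matrix",
    "macroscopic_rates",
    "propensities",
    "eliminate_conserved_species",
    "partition_system",
]


class NetworkError(ValueError):
    """Raised for ill-formed networks or invalid network operations."""


@dataclass(frozen=True)
class Species:
    """A chemical species with a declared timescale class.

    Parameters
    ----------
    name
        Unique identifier; must be a valid Python identifier so it can be
        used inside custom rate-law expressions.
    timescale_class
        ``"slow"`` or ``"fast"``.  The partition is declared by the user,
        exactly as in the deterministic quasi-steady-state reduction.
    initial_concentration
        Reference concentration (arbitrary units, >= 0) used to seed
        integrations and to initialise stochastic simulations.
    """

    name: str
    timescale_class: str = "slow"
    initial_concentration: float = 0.0

    def __post_init__(self) -> None:
        if not self.name.isidentifier():
            raise NetworkError(f"species name {self.name!r} is not an identifier")
        if self.timescale_class not in ("slow", "fast"):
            raise NetworkError(
                f"timescale_class must be 'slow' or 'fast', got {self.timescale_class!r}"
            )
        if self.initial_concentration < 0:
            raise NetworkError("initial_concentration must be >= 0")


@dataclass(frozen=True)
class Reaction:
    """A single reaction with mass-action or custom macroscopic rate law.

    ``reactants`` / ``products`` map species names to non-negative integer
    stoichiometric coefficients (``s_ij`` and ``r_ij``).  For a mass-action
    reaction the macroscopic rate is ``f_j = k_j * prod_m X_m**s_mj``.  A
    custom (non-elementary) law is given as a sympy-parsable expression in
    the species names, e.g. the Michaelis-Menten or Hill forms used for
    coarse-grained networks; numeric constants are baked into the string.
    """

    reactants: Mapping[str, int] = field(default_factory=dict)
    products: Mapping[str, int] = field(default_factory=dict)
    rate_constant: float | None = None
    rate_law: str = "mass_action"
    rate_expression: str | sp.Expr | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        for coeffs in (self.reactants, self.products):
            for s, c in coeffs.items():
                if int(c) != c or c < 0:
                    raise NetworkError(
                        f"stoichiometric coefficient of {s!r} must be a non-negative integer"
                    )
        if self.rate_law == "mass_action":
            if self.rate_constant is None:
                raise NetworkError("mass_action reaction requires rate_constant")
            if self.rate_constant < 0:
                raise NetworkError("rate_constant must be >= 0")
        elif self.rate_law == "custom":
            if self.rate_expression is None:
                raise NetworkError("custom reaction requires rate_expression")
        else:
            raise NetworkError(f"unknown rate_law {self.rate_law!r}")

    @property
    def molecularity(self) -> int:
        return int(sum(self.reactants.values()))

    def rate_expr(self, symbols: Mapping[str, sp.Symbol]) -> sp.Expr:
        """Macroscopic rate f_j as a sympy expression in the species symbols."""
        if self.rate_law == "mass_action":
            expr = sp.Float(self.rate_constant)
            for s, c in self.reactants.items():
                expr = expr * symbols[s] ** int(c)
            return expr
        if isinstance(self.rate_expression, sp.Expr):
            expr = self.rate_expression
        else:
            expr = sp.sympify(self.rate_expression, locals=dict(symbols))
        free = expr.free_symbols - set(symbols.values())
        if free:
            raise NetworkError(
                f"rate expression contains unknown symbols: {sorted(map(str, free))}"
            )
        return expr


@dataclass(frozen=True)
class ConservationLaw:
    """A left-null-space vector of S: ``sum_i c_i [X_i] = total`` at all times."""

    coefficients: Mapping[str, float]
    total: float

    def solve_for(self, name: str, symbols: Mapping[str, sp.Symbol]) -> sp.Expr:
        """Express species ``name`` in terms of the others via the law."""
        c = self.coefficients[name]
        if c == 0:
            raise NetworkError(f"law has zero coefficient for {name!r}")
        expr = sp.Float(self.total)
        for s, ci in self.coefficients.items():
            if s != name:
                expr -= ci * symbols[s]
        return expr / c


@dataclass(frozen=True)
class PartitionedSystem:
    """Slow/fast blocks of the stoichiometry and Jacobian at a reference state.

    ``S_s`` is N_s x R, ``S_f`` is N_f x R; ``J_s``, ``J_sf``, ``J_fs``,
    ``J_f`` are the corresponding blocks of the full-network Jacobian
    evaluated at ``state``; ``rate_vector`` is f evaluated there.
    """

    S_s: np.ndarray
    S_f: np.ndarray
    J_s: np.ndarray
    J_sf: np.ndarray
    J_fs: np.ndarray
    J_f: np.ndarray
    rate_vector: np.ndarray
    state: np.ndarray
    volume: float

    @property
    def n_slow(self) -> int:
        return self.S_s.shape[0]

    @property
    def n_fast(self) -> int:
        return self.S_f.shape[0]


class ReactionNetwork:
    """An ordered collection of species and reactions with a system volume.

    Species are re-ordered so that the slow block comes first (declaration
    order is preserved within each block).  Declared conservation laws are
    validated against the stoichiometric matrix (``c . S = 0`` exactly, in
    integer/rational arithmetic).
    """

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        volume: float = 1.0,
        conservation_laws: Sequence[ConservationLaw] = (),
        _eliminated: Mapping[str, ConservationLaw] | None = None,
    ) -> None:
        if volume <= 0:
            raise NetworkError("volume must be > 0")
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise NetworkError("species names must be unique")
        slow = [s for s in species if s.timescale_class == "slow"]
        fast = [s for s in species if s.timescale_class == "fast"]
        if not slow:
            raise NetworkError("network must contain at least one slow species")
        self.species: tuple[Species, ...] = tuple(slow + fast)
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self.volume = float(volume)
        self.conservation_laws: tuple[ConservationLaw, ...] = tuple(conservation_laws)
        self._eliminated: dict[str, ConservationLaw] = dict(_eliminated or {})
        self._check_reactions()
        self._validate_laws()
        self._compiled = None

    # -- basic introspection ------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def explicit_species(self) -> list[Species]:
        """Species carried in the explicit state (conserved ones removed)."""
        return [s for s in self.species if s.name not in self._eliminated]

    @property
    def explicit_names(self) -> list[str]:
        return [s.name for s in self.explicit_species]

    @property
    def eliminated_names(self) -> list[str]:
        return list(self._eliminated)

    @property
    def n_slow(self) -> int:
        return sum(1 for s in self.explicit_species if s.timescale_class == "slow")

    @property
    def n_fast(self) -> int:
        return sum(1 for s in self.explicit_species if s.timescale_class == "fast")

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def initial_concentrations(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.explicit_species])

    def with_volume(self, volume: float) -> "ReactionNetwork":
        return ReactionNetwork(
            self.species, self.reactions, volume, self.conservation_laws,
            _eliminated=self._eliminated,
        )

    def _check_reactions(self) -> None:
        known = set(self.species_names)
        for i, r in enumerate(self.reactions):
            for s in list(r.reactants) + list(r.products):
                if s not in known:
                    raise NetworkError(f"reaction {i} references unknown species {s!r}")
            if r.rate_law == "mass_action" and any(
                c >= 2 for c in r.reactants.values()
            ):
                warnings.warn(
                    "homodimeric reaction uses the n^2/Omega propensity "
                    "convention a_j = Omega*f(n/Omega), an O(1/Omega) "
                    "difference from the combinatorial form",
                    stacklevel=3,
                )
        appearing = {
            s for r in self.reactions for s in list(r.reactants) + list(r.products)
        }
        for s in self.species:
            if s.timescale_class == "fast" and s.name not in appearing:
                raise NetworkError(f"fast species {s.name!r} appears in no reaction")

    def _full_stoichiometric_matrix(self) -> np.ndarray:
        """N x R integer matrix over *all* species (including eliminated)."""
        names = self.species_names
        S = np.zeros((len(names), len(self.reactions)), dtype=np.int64)
        idx = {n: i for i, n in enumerate(names)}
        for j, r in enumerate(self.reactions):
            for s, c in r.reactants.items():
                S[idx[s], j] -= int(c)
            for s, c in r.products.items():
                S[idx[s], j] += int(c)
        return S

    def _validate_laws(self) -> None:
        S = self._full_stoichiometric_matrix()
        idx = {n: i for i, n in enumerate(self.species_names)}
        for law in self.conservation_laws:
            for s in law.coefficients:
                if s not in idx:
                    raise NetworkError(f"conservation law references unknown species {s!r}")
            c = np.zeros(len(idx))
            for s, ci in law.coefficients.items():
                c[idx[s]] = ci
            resid = c @ S
            if np.any(resid != 0):
                raise NetworkError(
                    "conservation law is not in the left null space of S "
                    f"(c.S = {resid.tolist()})"
                )

    # -- compiled rate functions -------------------------------------------

    def _compile(self):
        if self._compiled is not None:
            return self._compiled
        symbols = {s.name: sp.Symbol(s.name, real=True) for s in self.species}
        subs = {}
        for name, law in self._eliminated.items():
            subs[symbols[name]] = law.solve_for(name, symbols)
        # sequential substitution: laws act on disjoint species sets in
        # practice, but resolve chains defensively
        f_exprs = []
        for r in self.reactions:
            e = r.rate_expr(symbols)
            e = e.subs(subs, simultaneous=True)
            f_exprs.append(sp.simplify(e) if r.rate_law == "custom" else sp.expand(e))
        xs = [symbols[n] for n in self.explicit_names]
        dfdx = [[sp.diff(e, x) for x in xs] for e in f_exprs]
        f_fun = sp.lambdify(xs, f_exprs, modules="numpy")
        dfdx_fun = sp.lambdify(xs, dfdx, modules="numpy")
        custom = [r.rate_law == "custom" for r in self.reactions]
        self._compiled = (f_fun, dfdx_fun, custom)
        return self._compiled

    def rate_vector(self, conc: np.ndarray) -> np.ndarray:
        """Macroscopic rates f(conc) over the explicit-species state."""
        conc = np.asarray(conc, dtype=float)
        if conc.shape != (len(self.explicit_species),):
            raise NetworkError(
                f"expected concentration vector of length {len(self.explicit_species)}"
            )
        if np.any(conc < 0):
            raise NetworkError("concentrations must be >= 0")
        f_fun, _, custom = self._compile()
        f = np.array(f_fun(*conc), dtype=float)
        if any(custom) and np.any(f[np.asarray(custom)] < -1e-12):
            raise NetworkError("custom rate law evaluated to a negative rate")
        return f

    def rate_jacobian(self, conc: np.ndarray) -> np.ndarray:
        """R x N matrix of exact partial derivatives df_j/dX_i."""
        conc = np.asarray(conc, dtype=float)
        _, dfdx_fun, _ = self._compile()
        out = np.array(dfdx_fun(*conc), dtype=float)
        if not np.all(np.isfinite(out)):
            raise NetworkError("non-finite rate derivative encountered")
        return out

    def full_concentrations(self, conc: np.ndarray) -> dict[str, float]:
        """All species concentrations, reconstructing eliminated ones."""
        vals = dict(zip(self.explicit_names, np.asarray(conc, dtype=float)))
        for name, law in self._eliminated.items():
            c = law.coefficients[name]
            rest = sum(
                ci * vals[s] for s, ci in law.coefficients.items() if s != name
            )
            vals[name] = (law.total - rest) / c
        return vals

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ReactionNetwork({self.n_slow} slow + {self.n_fast} fast species, "
            f"{self.n_reactions} reactions, volume={self.volume})"
        )


# -- module-level operations ------------------------------------------------


def stoichiometric_matrix(net: ReactionNetwork) -> np.ndarray:
    """Integer stoichiometric matrix S (explicit species x reactions).

    Entry (i, j) is ``r_ij - s_ij``; rows follow the network's species order
    (slow block first, conserved species removed), columns the declared
    reaction order.
    """
    S = net._full_stoichiometric_matrix()
    keep = [i for i, s in enumerate(net.species) if s.name not in net._eliminated]
    return S[keep, :]


def macroscopic_rates(net: ReactionNetwork, conc: np.ndarray) -> np.ndarray:
    """Macroscopic rate vector f([X]) of length R.

    Mass-action entries are ``k_j * prod_m X_m**s_mj``; custom entries
    evaluate the supplied macroscopic law.  Eliminated species are
    reconstructed from their conservation laws before evaluation.
    """
    return net.rate_vector(conc)


def propensities(net: ReactionNetwork, copy_numbers: np.ndarray) -> np.ndarray:
    """Microscopic propensities ``a_j = Omega * f_j(n / Omega)``.

    This is the convention under which the mesoscopic and macroscopic
    descriptions agree to leading order in the system size; it applies to
    mass-action and to heuristic (extrapolated macroscopic) rate laws alike.
    """
    n = np.asarray(copy_numbers, dtype=float)
    if np.any(n < 0):
        raise NetworkError("copy numbers must be >= 0")
    return net.volume * net.rate_vector(n / net.volume)


def eliminate_conserved_species(
    net: ReactionNetwork,
    choose: Mapping[int, str] | None = None,
) -> tuple[ReactionNetwork, dict[str, ConservationLaw]]:
    """Remove one species per declared conservation law from the explicit state.

    By default the last-declared member of each law is eliminated; ``choose``
    maps a law index to an explicit species name to override this.  The
    eliminated concentration is re-expressed through the law inside every
    rate evaluation.  Returns the reduced network and the elimination map.
    """
    eliminated = dict(net._eliminated)
    for i, law in enumerate(net.conservation_laws):
        if choose and i in choose:
            target = choose[i]
            if target not in law.coefficients:
                raise NetworkError(f"{target!r} does not appear in law {i}")
        else:
            members = [s.name for s in net.species if s.name in law.coefficients]
            candidates = [m for m in members if m not in eliminated]
            if not candidates:
                raise NetworkError(f"no species left to eliminate for law {i}")
            target = candidates[-1]
        if target in eliminated:
            raise NetworkError(f"species {target!r} already eliminated")
        eliminated[target] = law
    reduced = ReactionNetwork(
        net.species, net.reactions, net.volume, net.conservation_laws,
        _eliminated=eliminated,
    )
    return reduced, {k: v for k, v in eliminated.items() if k not in net._eliminated}


def partition_system(
    net: ReactionNetwork,
    steady_state: np.ndarray,
    cond_max: float = 1e12,
) -> PartitionedSystem:
    """Partition S and the full-network Jacobian into slow/fast blocks.

    The Jacobian of ``d[X]/dt = S f`` is evaluated exactly (symbolic
    differentiation of the rate laws) at ``steady_state`` and split into the
    ``J_s``, ``J_sf``, ``J_fs``, ``J_f`` blocks; ``S`` splits into ``S_s``
    and ``S_f``.  A singular fast block almost always means a conservation
    law among the fast species was not eliminated.
    """
    state = np.asarray(steady_state, dtype=float)
    S = stoichiometric_matrix(net)
    J = S @ net.rate_jacobian(state)
    ns = net.n_slow
    part = PartitionedSystem(
        S_s=S[:ns, :].astype(float),
        S_f=S[ns:, :].astype(float),
        J_s=J[:ns, :ns],
        J_sf=J[:ns, ns:],
        J_fs=J[ns:, :ns],
        J_f=J[ns:, ns:],
        rate_vector=net.rate_vector(state),
        state=state,
        volume=net.volume,
    )
    nf = part.n_fast
    if nf:
        if np.linalg.cond(part.J_f) > cond_max:
            raise NetworkError(
                "fast-block Jacobian J_f is singular to numerical tolerance; "
                "a conservation law among the fast species was likely not "
                "eliminated"
            )
    return part
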