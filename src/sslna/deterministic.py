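"""Deterministic layer: rate equations, steady states, reduced Jacobians.

The macroscopic rate equations are ``d[X]/dt = S f([X])`` over the explicit
species.  Steady states are found by ODE relaxation followed by Newton
polishing, and their stability is asserted from the Jacobian spectrum.  The
reduced Jacobian ``J = J_s - J_sf J_f^-1 J_fs`` of a slow/fast-partitioned
system equals the Jacobian of the quasi-steady-state-reduced rate equations,
which is both the deterministic backbone of the slow-scale reduction and a
testable identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import NetworkError, PartitionedSystem, ReactionNetwork, stoichiometric_matrix

__all__ = [
    "SteadyState",
    "TimescaleDiagnostic",
    "SteadyStateError",
    "re_rhs",
    "jacobian",
    "steady_state",
    "reduced_jacobian",
    "timescale_separation_check",
]


class SteadyStateError(RuntimeError):
    """No (stable) steady state could be located."""


@dataclass(frozen=True)
class SteadyState:
    """A fixed point of the rate equations with its stability record."""

    concentrations: np.ndarray
    stable: bool
    jacobian_eigen_real_parts: np.ndarray
    residual: float


@dataclass(frozen=True)
class TimescaleDiagnostic:
    """Agreement of full vs reduced rate-equation trajectories.

    ``max_relative_slow_deviation`` is the maximum over the horizon of the
    relative deviation in slow-species concentrations; good agreement is the
    operational signature of timescale separation.
    """

    max_relative_slow_deviation: float
    horizon: float
    passed: bool
    threshold: float


def re_rhs(net: ReactionNetwork, conc: np.ndarray) -> np.ndarray:
    """Right-hand side S.f of the rate equations over explicit species."""
    return stoichiometric_matrix(net) @ net.rate_vector(conc)


def jacobian(net: ReactionNetwork, conc: np.ndarray) -> np.ndarray:
    """Exact Jacobian J_ij = d(S f)_i / dX_j of the rate equations."""
    return stoichiometric_matrix(net) @ net.rate_jacobian(conc)


def _relax(net: ReactionNetwork, x0: np.ndarray, rtol: float, budget: float):
    S = stoichiometric_matrix(net).astype(float)

    def rhs(t, x):
        return S @ net.rate_vector(np.maximum(x, 0.0))

    def jac(t, x):
        return S @ net.rate_jacobian(np.maximum(x, 0.0))

    x = np.asarray(x0, dtype=float)
    t_span = 10.0
    for _ in range(60):
        sol = solve_ivp(
            rhs, (0.0, t_span), x, method="LSODA", jac=jac,
            rtol=1e-9, atol=1e-12,
        )
        if not sol.success:
            raise SteadyStateError(f"relaxation integration failed: {sol.message}")
        x = np.maximum(sol.y[:, -1], 0.0)
        scale = np.linalg.norm(x) + 1e-300
        if np.linalg.norm(rhs(0.0, x)) / scale < rtol:
            return x
        t_span *= 3.0
        if t_span > budget:
            break
    return x


def steady_state(
    net: ReactionNetwork,
    guess: np.ndarray | None = None,
    require_stable: bool = False,
    relax_rtol: float = 1e-8,
    newton_rtol: float = 1e-10,
    max_horizon: float = 1e12,
) -> SteadyState:
    """Locate a steady state by ODE relaxation followed by Newton polishing.

    Relaxation is declared converged when ``||d[X]/dt|| / ||[X]|| <
    relax_rtol``; the Newton step then pushes the relative residual below
    ``newton_rtol``.  Stability is recomputed post hoc from the Jacobian
    eigenvalues (real parts below ``-1e-12 * ||J||`` count as stable, which
    guards against marginal modes left by uneliminated conservation laws).
    """
    if guess is None:
        guess = net.initial_concentrations()
    guess = np.asarray(guess, dtype=float)
    if np.any(guess < 0):
        raise NetworkError("steady-state guess must be >= 0")
    x = _relax(net, guess, relax_rtol, max_horizon)
    S = stoichiometric_matrix(net).astype(float)

    def fun(z):
        return S @ net.rate_vector(np.maximum(z, 0.0))

    def jac(z):
        return S @ net.rate_jacobian(np.maximum(z, 0.0))

    sol = root(fun, x, jac=jac, method="hybr", tol=1e-14)
    if sol.success and np.all(sol.x >= -1e-12):
        x = np.maximum(sol.x, 0.0)
    # damped Newton polish: hybr can stall above the residual bar when the
    # species scales are very uneven
    for _ in range(50):
        r = fun(x)
        scale = np.linalg.norm(x) + 1e-300
        if np.linalg.norm(r) / scale < 1e-14:
            break
        try:
            dx = np.linalg.solve(jac(x), -r)
        except np.linalg.LinAlgError:
            dx = np.linalg.lstsq(jac(x), -r, rcond=None)[0]
        lam = 1.0
        base = np.linalg.norm(r)
        for _ in range(30):
            xn = x + lam * dx
            if np.all(xn >= 0) and np.linalg.norm(fun(xn)) < base:
                x = xn
                break
            lam *= 0.5
        else:
            break
    scale = np.linalg.norm(x) + 1e-300
    resid = np.linalg.norm(fun(x)) / scale
    if resid > newton_rtol:
        raise SteadyStateError(
            f"no steady state found (relative residual {resid:.2e})"
        )
    J = jac(x)
    eig = np.linalg.eigvals(J)
    tol = 1e-12 * max(np.linalg.norm(J), 1.0)
    stable = bool(np.all(eig.real < -tol))
    if require_stable and not stable:
        raise SteadyStateError(
            "steady state is not stable; the linear noise machinery requires "
            "a stable monostable steady state"
        )
    return SteadyState(
        concentrations=x,
        stable=stable,
        jacobian_eigen_real_parts=np.sort(eig.real),
        residual=resid,
    )


def reduced_jacobian(part: PartitionedSystem) -> np.ndarray:
    """Jacobian ``J = J_s - J_sf J_f^-1 J_fs`` of the reduced slow dynamics.

    Identical to the Jacobian of the quasi-steady-state-reduced rate
    equations evaluated at the same state.
    """
    if part.n_fast == 0:
        return np.array(part.J_s, dtype=float)
    return part.J_s - part.J_sf @ np.linalg.solve(part.J_f, part.J_fs)


def timescale_separation_check(
    full: ReactionNetwork,
    reduced: ReactionNetwork,
    init: np.ndarray,
    horizon: float,
    threshold: float = 0.05,
    n_eval: int = 400,
) -> TimescaleDiagnostic:
    """Integrate full and reduced rate equations and compare slow species.

    ``init`` gives the slow-species initial concentrations, shared by both
    models; fast species in the full model start from their declared initial
    concentrations.  The diagnostic passes when the maximum relative
    deviation of the slow trajectories stays below ``threshold``.
    """
    slow_full = [s.name for s in full.explicit_species if s.timescale_class == "slow"]
    slow_red = [s.name for s in reduced.explicit_species if s.timescale_class == "slow"]
    shared = [n for n in slow_full if n in slow_red]
    if not shared:
        raise NetworkError("models share no slow species")
    init = np.asarray(init, dtype=float)
    t_eval = np.linspace(0.0, horizon, n_eval)

    def integrate(net: ReactionNetwork, x0: np.ndarray) -> np.ndarray:
        S = stoichiometric_matrix(net).astype(float)
        sol = solve_ivp(
            lambda t, x: S @ net.rate_vector(np.maximum(x, 0.0)),
            (0.0, horizon), x0, method="LSODA", t_eval=t_eval,
            jac=lambda t, x: S @ net.rate_jacobian(np.maximum(x, 0.0)),
            rtol=1e-9, atol=1e-12,
        )
        if not sol.success:
            raise SteadyStateError(f"integration failed: {sol.message}")
        return sol.y

    x0_full = full.initial_concentrations()
    for name, v in zip(shared, init):
        x0_full[full.explicit_names.index(name)] = v
    x0_red = reduced.initial_concentrations()
    for name, v in zip(shared, init):
        x0_red[reduced.explicit_names.index(name)] = v

    y_full = integrate(full, x0_full)
    y_red = integrate(reduced, x0_red)
    dev = 0.0
    for name in shared:
        a = y_full[full.explicit_names.index(name)]
        b = y_red[reduced.explicit_names.index(name)]
        scale = np.maximum(np.abs(a), np.max(np.abs(a)) * 1e-3 + 1e-300)
        dev = max(dev, float(np.max(np.abs(a - b) / scale)))
    return TimescaleDiagnostic(
        max_relative_slow_deviation=dev,
        horizon=float(horizon),
        passed=bool(dev <= threshold),
        threshold=threshold,
    )
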