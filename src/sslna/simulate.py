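"""Exact stochastic simulation and reduced Langevin integration.

``ssa_simulate`` runs the Gillespie direct method on any network (full
elementary, or coarse-grained with heuristic propensities): waiting times
``tau = -ln(r)/sum_j a_j``, next reaction drawn with probability
``a_j/sum a``, states recorded on a uniform output grid by piecewise-
constant interpolation.  Mass-action networks run in a compiled kernel;
networks with custom rate laws use a straightforward Python loop (their
coarse-grained event rates are low).

``langevin_sslna`` integrates the reduced slow-scale Langevin equation

    eta(t + dt) = eta + J eta dt + Omega^-1/2 S' diag(sqrt(f)) sqrt(dt) z

by Euler-Maruyama and reports the trajectory as [X_s] + eta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .lna import LNAReduction
from .network import NetworkError, ReactionNetwork, stoichiometric_matrix

__all__ = [
    "Trajectory",
    "TrajectoryStats",
    "ssa_simulate",
    "langevin_sslna",
    "trajectory_statistics",
]


@dataclass(frozen=True)
class Trajectory:
    """Time grid plus per-time state vectors with provenance metadata.

    SSA states are copy numbers (integer-valued); Langevin states are
    slow-species concentrations.
    """

    times: np.ndarray
    states: np.ndarray              # (n_times, n_species)
    method: str                     # "SSA" | "Langevin"
    seed: int
    species: tuple[str, ...]
    volume: float
    units: str                      # "copy_number" | "concentration"
    dt: float | None = None

    def concentrations(self) -> np.ndarray:
        if self.units == "concentration":
            return self.states
        return self.states / self.volume


@dataclass(frozen=True)
class TrajectoryStats:
    """Post-burn-in sample statistics with block-averaged standard errors.

    All quantities are in concentration units; ``omega_fano`` compares
    molecule-number fluctuations against a Poisson law.  The empirical
    spectrum is the periodogram ``|sum eta exp(-i w t) dt|^2 / T``, whose
    expectation matches the analytic stationary spectra.
    """

    species: tuple[str, ...]
    mean: np.ndarray
    variance: np.ndarray
    mean_se: np.ndarray
    variance_se: np.ndarray
    fano_factor: np.ndarray
    omega_fano: np.ndarray
    cv_squared: np.ndarray
    spectrum_freq: np.ndarray
    spectrum_power: np.ndarray      # (n_species, n_freq)
    n_blocks: int


@njit(cache=False)
def _ssa_kernel(n0, t_grid, k, exps, mu, econst, emat, omega, seed):
    np.random.seed(seed)
    n_exp = n0.shape[0]
    n_full = econst.shape[0]
    R = k.shape[0]
    out = np.empty((t_grid.shape[0], n_exp))
    n = n0.copy()
    a = np.empty(R)
    t = 0.0
    gi = 0
    t_end = t_grid[-1]
    while True:
        # reconstruct full copy-number vector (eliminated species via laws)
        total = 0.0
        for j in range(R):
            aj = k[j] * omega
            for m in range(n_full):
                e = exps[j, m]
                if e:
                    nm = econst[m]
                    for q in range(n_exp):
                        nm += emat[m, q] * n[q]
                    x = nm / omega
                    for _ in range(e):
                        aj *= x
            a[j] = aj
            total += aj
        if total <= 0.0:
            while gi < t_grid.shape[0]:
                out[gi] = n
                gi += 1
            break
        r1 = np.random.random()
        while r1 <= 0.0:
            r1 = np.random.random()
        tau = -np.log(r1) / total
        t_new = t + tau
        while gi < t_grid.shape[0] and t_grid[gi] < t_new:
            out[gi] = n
            gi += 1
        if gi >= t_grid.shape[0] or t_new > t_end:
            if gi < t_grid.shape[0]:
                while gi < t_grid.shape[0]:
                    out[gi] = n
                    gi += 1
            break
        u = np.random.random() * total
        acc = 0.0
        j_sel = R - 1
        for j in range(R):
            acc += a[j]
            if u < acc:
                j_sel = j
                break
        for q in range(n_exp):
            n[q] += mu[q, j_sel]
        t = t_new
    return out


@njit(cache=False)
def _langevin_kernel(eta0, J, B, dt, n_steps, stride, seed):
    np.random.seed(seed)
    n = eta0.shape[0]
    R = B.shape[1]
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec, n))
    eta = eta0.copy()
    out[0] = eta
    sq = np.sqrt(dt)
    rec = 1
    for step in range(1, n_steps + 1):
        drift = np.zeros(n)
        for i in range(n):
            s = 0.0
            for jj in range(n):
                s += J[i, jj] * eta[jj]
            drift[i] = s * dt
        z = np.empty(R)
        for r in range(R):
            z[r] = np.random.normal()
        for i in range(n):
            s = 0.0
            for r in range(R):
                s += B[i, r] * z[r]
            eta[i] += drift[i] + s * sq
        if step % stride == 0:
            out[rec] = eta
            rec += 1
    return out


def _mass_action_arrays(net: ReactionNetwork):
    full_names = net.species_names
    exp_names = net.explicit_names
    n_full, n_exp = len(full_names), len(exp_names)
    R = net.n_reactions
    k = np.array([r.rate_constant for r in net.reactions], dtype=float)
    exps = np.zeros((R, n_full), dtype=np.int64)
    fidx = {n: i for i, n in enumerate(full_names)}
    for j, r in enumerate(net.reactions):
        for s, c in r.reactants.items():
            exps[j, fidx[s]] = int(c)
    mu = stoichiometric_matrix(net).astype(np.float64)
    # affine map from explicit copy numbers to full copy numbers
    econst = np.zeros(n_full)
    emat = np.zeros((n_full, n_exp))
    eidx = {n: i for i, n in enumerate(exp_names)}
    for m, name in enumerate(full_names):
        if name in eidx:
            emat[m, eidx[name]] = 1.0
        else:
            law = net._eliminated[name]
            ce = law.coefficients[name]
            econst[m] = net.volume * law.total / ce
            for s, ci in law.coefficients.items():
                if s != name:
                    emat[m, eidx[s]] = -ci / ce
    return k, exps, mu, econst, emat


def ssa_simulate(
    net: ReactionNetwork,
    init_counts: np.ndarray | None = None,
    t_max: float = 100.0,
    seed: int = 0,
    n_grid: int = 10_000,
) -> Trajectory:
    """Gillespie direct-method simulation recorded on a uniform grid.

    ``init_counts`` defaults to ``round(volume * initial_concentration)``
    over the explicit species.  The waiting time between events is
    exponential with rate ``sum_j a_j``; a state where every propensity
    vanishes halts cleanly (the remaining grid is filled with the final
    state).
    """
    if init_counts is None:
        init_counts = np.round(net.volume * net.initial_concentrations())
    n0 = np.asarray(init_counts, dtype=float)
    if np.any(n0 < 0):
        raise NetworkError("initial counts must be >= 0")
    t_grid = np.linspace(0.0, t_max, n_grid)
    if all(r.rate_law == "mass_action" for r in net.reactions):
        k, exps, mu, econst, emat = _mass_action_arrays(net)
        states = _ssa_kernel(
            n0, t_grid, k, exps, mu, econst, emat, net.volume, seed
        )
    else:
        states = _ssa_python(net, n0, t_grid, seed)
    return Trajectory(
        times=t_grid, states=states, method="SSA", seed=int(seed),
        species=tuple(net.explicit_names), volume=net.volume,
        units="copy_number",
    )


def _ssa_python(net: ReactionNetwork, n0, t_grid, seed):
    rng = np.random.RandomState(seed)
    mu = stoichiometric_matrix(net).astype(float)
    f_fun, _, _ = net._compile()
    omega = net.volume
    out = np.empty((len(t_grid), len(n0)))
    n = n0.copy()
    t, gi = 0.0, 0
    while True:
        a = omega * np.asarray(f_fun(*(np.maximum(n, 0.0) / omega)), dtype=float)
        if np.any(a < 0):
            raise NetworkError("negative propensity from a custom rate law")
        total = a.sum()
        if total <= 0:
            out[gi:] = n
            break
        tau = -np.log(rng.random_sample()) / total
        t_new = t + tau
        while gi < len(t_grid) and t_grid[gi] < t_new:
            out[gi] = n
            gi += 1
        if gi >= len(t_grid):
            break
        j = np.searchsorted(np.cumsum(a), rng.random_sample() * total)
        n = n + mu[:, j]
        t = t_new
    return out


def langevin_sslna(
    reduction: LNAReduction,
    steady_state: np.ndarray | None = None,
    dt: float = 0.1,
    t_max: float = 1000.0,
    seed: int = 0,
    record_stride: int = 1,
) -> Trajectory:
    """Euler-Maruyama integration of the slow-scale Langevin equation.

    The fluctuation vector starts at zero and the trajectory is reported as
    ``[X_s] + eta_s(t)``.  A warning is issued when ``dt`` is too large for
    linear stability of the explicit update.
    """
    if reduction.flavor != "ssLNA":
        raise ValueError("langevin_sslna requires an ssLNA reduction")
    if dt <= 0:
        raise ValueError("dt must be positive")
    J = reduction.jacobian
    if reduction.noise_matrix is None:
        raise ValueError("reduction carries no noise matrix")
    B = reduction.noise_matrix / np.sqrt(reduction.volume)
    n = J.shape[0]
    amp = np.max(np.abs(np.linalg.eigvals(np.eye(n) + J * dt)))
    if amp >= 1.0:
        warnings.warn(
            f"Euler-Maruyama step dt={dt} is unstable for this Jacobian "
            f"(spectral radius of I + J dt is {amp:.3f} >= 1)",
            stacklevel=2,
        )
    mean = (
        np.asarray(steady_state, dtype=float)
        if steady_state is not None
        else reduction.means
    )
    n_steps = int(np.ceil(t_max / dt))
    eta = _langevin_kernel(
        np.zeros(n), np.asarray(J, float), np.asarray(B, float),
        float(dt), n_steps, int(record_stride), int(seed),
    )
    times = np.arange(eta.shape[0]) * dt * record_stride
    return Trajectory(
        times=times, states=mean[None, :] + eta, method="Langevin",
        seed=int(seed), species=tuple(reduction.species),
        volume=reduction.volume, units="concentration", dt=float(dt),
    )


def trajectory_statistics(
    traj: Trajectory,
    burn_in_fraction: float = 0.2,
    n_blocks: int = 20,
) -> TrajectoryStats:
    """Stationary sample statistics, block-averaged errors and periodogram.

    The first ``burn_in_fraction`` of the trajectory is discarded; means
    and variances are estimated from the remainder, with standard errors
    from the spread of per-block estimates over ``n_blocks`` contiguous
    blocks.  The periodogram of the concentration fluctuations is returned
    on the positive angular-frequency grid of the record.
    """
    if not 0 <= burn_in_fraction < 1:
        raise ValueError("burn_in_fraction must lie in [0, 1)")
    x = traj.concentrations()
    n_burn = int(len(x) * burn_in_fraction)
    y = x[n_burn:]
    if len(y) < max(n_blocks, 2):
        raise ValueError("trajectory shorter than burn-in plus one block")
    mean = y.mean(axis=0)
    var = y.var(axis=0)
    blocks = np.array_split(y, n_blocks, axis=0)
    bmeans = np.array([b.mean(axis=0) for b in blocks])
    # block variances about the global mean: their average is the full-sample
    # variance, so the block spread is a consistent error bar for it
    bvars = np.array([((b - mean) ** 2).mean(axis=0) for b in blocks])
    mean_se = bmeans.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    var_se = bvars.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    dtg = traj.times[1] - traj.times[0] if len(traj.times) > 1 else 1.0
    eta = y - mean
    T = len(y) * dtg
    ft = np.fft.rfft(eta, axis=0) * dtg
    power = (np.abs(ft) ** 2 / T).T
    freq = 2.0 * np.pi * np.fft.rfftfreq(len(y), d=dtg)
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = var / mean
        cv2 = var / mean**2
    return TrajectoryStats(
        species=traj.species,
        mean=mean,
        variance=var,
        mean_se=mean_se,
        variance_se=var_se,
        fano_factor=ff,
        omega_fano=traj.volume * ff,
        cv_squared=cv2,
        spectrum_freq=freq[1:],
        spectrum_power=power[:, 1:],
        n_blocks=n_blocks,
    )
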