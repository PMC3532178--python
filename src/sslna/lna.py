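"""Linear noise approximation flavors and stationary noise statistics.

Three diffusion matrices are computed for a monostable network at a stable
steady state:

* full LNA: ``D_F = Omega^-1 S diag(f) S^T`` over all explicit species;
* heuristic LNA (hLNA): the same formula applied to a coarse-grained
  network whose propensities are extrapolated from macroscopic
  (QSSA-reduced) rate laws;
* slow-scale LNA (ssLNA): ``D_ss = Omega^-1 S' diag(f) S'^T`` over the
  slow species only, with the effective stoichiometry
  ``S' = S_s - J_sf J_f^-1 S_f`` selected by adiabatic elimination of the
  fast fluctuations.

The stationary covariance ``H`` solves the Lyapunov equation
``J H + H J^T + D = 0`` and the power spectrum is
``P_j(w) = [(iIw + J)^-1 D (-iIw + J^T)^-1]_jj``; a peak at w > 0 signals
noise-induced oscillations.  The entries of ``S'`` are generally neither
integer nor state-independent, which is exactly why a reduced master
equation does not exist in general even though the reduced Langevin
description always does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.linalg import solve_continuous_lyapunov
from scipy.optimize import minimize_scalar

from .deterministic import reduced_jacobian
from .network import PartitionedSystem, ReactionNetwork, stoichiometric_matrix

__all__ = [
    "LNAReduction",
    "SpectrumResult",
    "NoiseSummary",
    "diffusion_full",
    "diffusion_hlna",
    "diffusion_sslna",
    "effective_stoichiometry",
    "reduced_cme_exists",
    "solve_lyapunov",
    "power_spectrum",
    "spectrum_peak",
    "spectrum_variance",
    "noise_summary",
    "full_lna",
    "heuristic_lna",
    "slow_scale_lna",
]


class StabilityError(RuntimeError):
    """Raised when the LNA is requested at a non-Hurwitz Jacobian."""


@dataclass(frozen=True)
class LNAReduction:
    """Jacobian, diffusion and stationary covariance of one LNA flavor."""

    flavor: str  # "full" | "hLNA" | "ssLNA"
    jacobian: np.ndarray
    diffusion: np.ndarray
    covariance: np.ndarray
    volume: float
    species: tuple[str, ...]
    means: np.ndarray
    effective_stoichiometry: np.ndarray | None = None
    reduced_cme_exists: bool | None = None
    noise_matrix: np.ndarray | None = None  # S' diag(sqrt(f)); D = B B^T / volume

    def summary(self) -> "NoiseSummary":
        return noise_summary(self.covariance, self.means, self.volume, self.species)


@dataclass(frozen=True)
class SpectrumResult:
    """Analytic power spectra on a frequency grid, with peak diagnostics."""

    frequencies: np.ndarray            # angular frequency grid
    power: np.ndarray                  # (n_species, n_freq), >= 0
    has_peak: np.ndarray               # bool per species
    peak_frequency: np.ndarray         # nan where no peak
    species: tuple[str, ...] = ()


@dataclass(frozen=True)
class NoiseSummary:
    """Per-species stationary noise measures.

    ``fano_factor`` is variance over mean concentration; multiplied by the
    volume it compares molecule-number fluctuations against a Poisson law
    (``omega_fano > 1``: super-Poissonian).  ``cv`` is standard deviation
    over mean.
    """

    species: tuple[str, ...]
    mean: np.ndarray
    variance: np.ndarray
    fano_factor: np.ndarray
    omega_fano: np.ndarray
    cv: np.ndarray
    cv_squared: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "species": list(self.species),
                "mean": self.mean,
                "variance": self.variance,
                "fano_factor": self.fano_factor,
                "omega_fano": self.omega_fano,
                "cv_squared": self.cv_squared,
            }
        )


# -- diffusion matrices -----------------------------------------------------


def diffusion_full(net: ReactionNetwork, steady_state: np.ndarray) -> np.ndarray:
    """Full-network LNA diffusion ``D_F = Omega^-1 S diag(f) S^T``."""
    S = stoichiometric_matrix(net).astype(float)
    f = net.rate_vector(np.asarray(steady_state, dtype=float))
    return (S * f) @ S.T / net.volume


def diffusion_hlna(coarse_net: ReactionNetwork, steady_state: np.ndarray) -> np.ndarray:
    """Heuristic-LNA diffusion: equation of ``diffusion_full`` applied to a
    coarse-grained network with extrapolated macroscopic rate laws."""
    return diffusion_full(coarse_net, steady_state)


def effective_stoichiometry(part: PartitionedSystem) -> np.ndarray:
    """Effective stoichiometry ``S' = S_s - J_sf J_f^-1 S_f`` (N_s x R)."""
    if part.n_fast == 0:
        return np.array(part.S_s, dtype=float)
    return part.S_s - part.J_sf @ np.linalg.solve(part.J_f, part.S_f)


def diffusion_sslna(
    part: PartitionedSystem, volume: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Slow-scale diffusion ``D_ss = Omega^-1 S' diag(f) S'^T`` and ``S'``.

    Symmetric positive semi-definite by construction.
    """
    omega = part.volume if volume is None else float(volume)
    Sp = effective_stoichiometry(part)
    D = (Sp * part.rate_vector) @ Sp.T / omega
    return 0.5 * (D + D.T), Sp


def reduced_cme_exists(S_prime: np.ndarray, atol: float = 1e-9) -> bool:
    """Whether every entry of S' is integer-valued to tolerance.

    Integer, state-independent entries are necessary for a physically
    meaningful reduced master equation; real-valued entries mean only the
    reduced Langevin description exists.
    """
    Sp = np.asarray(S_prime, dtype=float)
    return bool(np.all(np.abs(Sp - np.round(Sp)) <= atol))


# -- covariance and spectra -------------------------------------------------


def _require_hurwitz(J: np.ndarray) -> None:
    if np.any(np.linalg.eigvals(J).real >= 0):
        raise StabilityError(
            "Jacobian is not Hurwitz: the LNA requires a stable monostable "
            "steady state"
        )


def solve_lyapunov(J: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Unique symmetric PSD solution H of ``J H + H J^T + D = 0``."""
    J = np.atleast_2d(np.asarray(J, dtype=float))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    _require_hurwitz(J)
    H = solve_continuous_lyapunov(J, -D)
    H = 0.5 * (H + H.T)
    # iterative refinement: stiff Jacobians (decay rates spanning many
    # orders) leave a residual the direct solve alone cannot remove
    scale = max(np.linalg.norm(D), 1e-300)
    for _ in range(10):
        R = J @ H + H @ J.T + D
        if np.linalg.norm(R) <= 1e-12 * scale:
            break
        dH = solve_continuous_lyapunov(J, -R)
        H = 0.5 * (H + dH + (H + dH).T)
    resid = np.linalg.norm(J @ H + H @ J.T + D)
    if resid > 1e-10 * scale:
        raise RuntimeError(f"Lyapunov residual too large: {resid:.2e}")
    return H


def _power_at(J: np.ndarray, D: np.ndarray, w: float) -> np.ndarray:
    n = J.shape[0]
    M = np.linalg.inv(1j * w * np.eye(n) + J)
    P = M @ D @ M.conj().T
    return np.maximum(P.diagonal().real, 0.0)


def default_frequency_grid(J: np.ndarray, n: int = 400) -> np.ndarray:
    """Log grid spanning 1e-3 to 1e3 times the Jacobian decay-rate range."""
    re = np.abs(np.linalg.eigvals(np.atleast_2d(J)).real)
    lo, hi = 1e-3 * re.min(), 1e3 * re.max()
    return np.logspace(np.log10(lo), np.log10(hi), n)


def power_spectrum(
    J: np.ndarray,
    D: np.ndarray,
    frequencies: np.ndarray | None = None,
    species: tuple[str, ...] = (),
    prominence: float = 1e-6,
) -> SpectrumResult:
    """Analytic stationary power spectra of the concentration fluctuations.

    ``P_j(w)`` is real and non-negative; its two-sided integral over
    ``dw / 2 pi`` recovers the stationary variance ``H_jj``.
    """
    J = np.atleast_2d(np.asarray(J, dtype=float))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    _require_hurwitz(J)
    if frequencies is None:
        frequencies = default_frequency_grid(J)
    w = np.asarray(frequencies, dtype=float)
    P = np.column_stack([_power_at(J, D, wi) for wi in w])
    n = J.shape[0]
    has_peak = np.zeros(n, dtype=bool)
    peak_freq = np.full(n, np.nan)
    for j in range(n):
        ok, wstar = _numeric_peak(J, D, j, prominence)
        has_peak[j] = ok
        peak_freq[j] = wstar if ok else np.nan
    if not species:
        species = tuple(f"X{j + 1}" for j in range(n))
    return SpectrumResult(
        frequencies=w, power=P, has_peak=has_peak, peak_frequency=peak_freq,
        species=species,
    )


def _numeric_peak(
    J: np.ndarray, D: np.ndarray, j: int, prominence: float
) -> tuple[bool, float]:
    grid = np.concatenate(([0.0], default_frequency_grid(J, 600)))
    p = np.array([_power_at(J, D, w)[j] for w in grid])
    k = int(np.argmax(p))
    if k == 0 or k == len(grid) - 1:
        return False, np.nan
    res = minimize_scalar(
        lambda w: -_power_at(J, D, w)[j],
        bounds=(grid[k - 1], grid[k + 1]),
        method="bounded",
        options={"xatol": 1e-12 * grid[k] + 1e-300},
    )
    wstar = float(res.x)
    p0 = _power_at(J, D, 0.0)[j]
    pstar = _power_at(J, D, wstar)[j]
    if pstar > p0 * (1.0 + prominence) and wstar > 0:
        return True, wstar
    return False, np.nan


def analytic_peak_condition(J: np.ndarray, D: np.ndarray, j: int = 0) -> bool:
    """Closed-form peak criterion for a two-species system with diagonal D.

    For species j with partner k the spectrum is
    ``P_j = [(J_kk^2 + w^2) D_jj + J_jk^2 D_kk] / |det(iIw + J)|^2`` and an
    interior maximum exists iff
    ``(J_kk^2 D_jj + J_jk^2 D_kk) (Tr^2 J - 2 Det J) - D_jj Det^2 J < 0``.
    """
    J = np.atleast_2d(np.asarray(J, dtype=float))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    if J.shape != (2, 2):
        raise ValueError("analytic peak condition applies to 2x2 systems only")
    if abs(D[0, 1]) > 1e-12 * max(abs(D[0, 0]), abs(D[1, 1]), 1e-300):
        raise ValueError("analytic peak condition assumes diagonal diffusion")
    k = 1 - j
    C = J[k, k] ** 2 * D[j, j] + J[j, k] ** 2 * D[k, k]
    tr, det = np.trace(J), np.linalg.det(J)
    return bool(C * (tr**2 - 2 * det) - D[j, j] * det**2 < 0)


def spectrum_peak(
    J: np.ndarray, D: np.ndarray, species_index: int = 0, prominence: float = 1e-6
) -> tuple[bool, float]:
    """Locate a noise-induced-oscillation peak in one species' spectrum.

    Numeric route: interior maximum of ``P_j`` on a log grid refined by
    bounded scalar minimisation, accepted when it exceeds ``P_j(0)`` by the
    prominence factor.  For two-species systems with diagonal diffusion the
    closed-form sign condition is evaluated as well and the two routes are
    required to agree.  Single-species spectra are monotonic in frequency,
    so they never peak.
    """
    J = np.atleast_2d(np.asarray(J, dtype=float))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    _require_hurwitz(J)
    if J.shape[0] == 1:
        return False, np.nan
    ok, wstar = _numeric_peak(J, D, species_index, prominence)
    if J.shape == (2, 2) and abs(D[0, 1]) <= 1e-12 * max(
        abs(D[0, 0]), abs(D[1, 1]), 1e-300
    ):
        analytic = analytic_peak_condition(J, D, species_index)
        if analytic != ok:
            raise RuntimeError(
                "numeric peak detection disagrees with the closed-form "
                f"criterion (numeric={ok}, analytic={analytic}); the spectrum "
                "is marginal at this parameter point"
            )
    return ok, wstar


def spectrum_variance(J: np.ndarray, D: np.ndarray, j: int) -> float:
    """Two-sided quadrature ``int P_j(w) dw / 2 pi`` (equals ``H_jj``)."""
    J = np.atleast_2d(np.asarray(J, dtype=float))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    re = np.abs(np.linalg.eigvals(J).real)
    # piecewise quadrature: spectra of stiff systems have Lorentzian
    # features at every decay-rate scale, which one global quad misses
    edges = np.logspace(
        np.log10(re.min()) - 4.0, np.log10(re.max()) + 4.0,
        int(np.ceil(np.log10(re.max() / re.min())) + 9) * 2,
    )
    f = lambda w: _power_at(J, D, w)[j]
    val = quad(f, 0.0, edges[0], limit=200)[0]
    for lo, hi in zip(edges[:-1], edges[1:]):
        val += quad(f, lo, hi, limit=200)[0]
    val += quad(f, edges[-1], np.inf, limit=200)[0]
    return 2.0 * val / (2.0 * np.pi)


# -- noise summaries and flavor builders ------------------------------------


def noise_summary(
    H: np.ndarray,
    means: np.ndarray,
    volume: float,
    species: tuple[str, ...] = (),
) -> NoiseSummary:
    """Fano factors, volume-scaled Fano factors and coefficients of variation."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    means = np.asarray(means, dtype=float)
    if np.any(means <= 0):
        raise ValueError("noise summary requires strictly positive means")
    var = H.diagonal().copy()
    ff = var / means
    if not species:
        species = tuple(f"X{j + 1}" for j in range(len(means)))
    return NoiseSummary(
        species=species,
        mean=means,
        variance=var,
        fano_factor=ff,
        omega_fano=volume * ff,
        cv=np.sqrt(var) / means,
        cv_squared=var / means**2,
    )


def full_lna(net: ReactionNetwork, steady_state: np.ndarray) -> LNAReduction:
    """LNA of the full network over all explicit species."""
    from .deterministic import jacobian as _jac

    x = np.asarray(steady_state, dtype=float)
    J = _jac(net, x)
    D = diffusion_full(net, x)
    return LNAReduction(
        flavor="full", jacobian=J, diffusion=D, covariance=solve_lyapunov(J, D),
        volume=net.volume, species=tuple(net.explicit_names), means=x,
    )


def heuristic_lna(coarse_net: ReactionNetwork, steady_state: np.ndarray) -> LNAReduction:
    """hLNA of a coarse-grained network (heuristic propensities)."""
    from .deterministic import jacobian as _jac

    x = np.asarray(steady_state, dtype=float)
    J = _jac(coarse_net, x)
    D = diffusion_hlna(coarse_net, x)
    return LNAReduction(
        flavor="hLNA", jacobian=J, diffusion=D, covariance=solve_lyapunov(J, D),
        volume=coarse_net.volume, species=tuple(coarse_net.explicit_names), means=x,
    )


def slow_scale_lna(
    net: ReactionNetwork, steady_state: np.ndarray
) -> LNAReduction:
    """ssLNA of a slow/fast-partitioned full network.

    Builds the partition at the steady state, forms the reduced Jacobian
    ``J = J_s - J_sf J_f^-1 J_fs`` and the slow-scale diffusion, and solves
    for the stationary slow-species covariance.
    """
    from .network import partition_system

    x = np.asarray(steady_state, dtype=float)
    part = partition_system(net, x)
    J = reduced_jacobian(part)
    D, Sp = diffusion_sslna(part)
    slow = tuple(
        s.name for s in net.explicit_species if s.timescale_class == "slow"
    )
    return LNAReduction(
        flavor="ssLNA", jacobian=J, diffusion=D, covariance=solve_lyapunov(J, D),
        volume=net.volume, species=slow, means=x[: part.n_slow],
        effective_stoichiometry=Sp, reduced_cme_exists=reduced_cme_exists(Sp),
        noise_matrix=Sp * np.sqrt(part.rate_vector),
    )
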