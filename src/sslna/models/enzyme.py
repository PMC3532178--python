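"""Two-subunit enzyme catalysis with substrate input.

The full elementary network is

    0 -> S            (rate k_in, substrate input)
    S + EE  <-> EES   (k1 / km1, first binding)
    EES     -> EE + P (k3, catalysis from the singly-bound complex)
    S + EES <-> SEES  (k2 / km2, second binding)
    SEES    -> EES + P(k4, catalysis from the doubly-bound complex)

with total enzyme conserved, EET = [EE] + [EES] + [SEES].  Under timescale
separation (enzyme and complexes fast, substrate slow) the deterministic
reduction is d[S]/dt = k_in - k'(S) [S] with the Tyson effective rate

    k'(S) = EET (k3/Km1 + k4 [S]/(Km1 Km2)) / (1 + [S]/Km1 + [S]^2/(Km1 Km2)),

Km1 = (km1 + k3)/k1, Km2 = (km2 + k4)/k2.  Two limits are of special
interest: k2 -> 0 gives Michaelis-Menten kinetics, and k2 -> inf, Km2 -> 0
at constant Km^2 = Km1 Km2 gives Hill kinetics with coefficient 2.  The
saturation fraction Theta = k_in / (k4 EET) parameterises the steady state;
in the Hill limit [S]^2 = Km^2 Theta / (1 - Theta).

The closed-form slow-scale noise statistics involve the weights

    q1 = (k3 Km2 + k4 [S]) / (k1 ([S]^2 + [S] Km2 + Km1 Km2)),
    q2 = (k4 Km1 + (k4 - k3) [S]) / (k2 ([S]^2 + [S] Km2 + Km1 Km2)),

the entries of the effective stoichiometry
S' = (1, -q1, q1, -(1-q1), -q2, q2, -(1-q2)); the heuristic description is
recovered exactly by forcing q1 = q2 = 0, i.e. by ignoring the noise of the
reversible binding steps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from ..network import (
    ConservationLaw,
    Reaction,
    ReactionNetwork,
    Species,
    eliminate_conserved_species,
)

__all__ = [
    "EnzymeParams",
    "enzyme_full_network",
    "enzyme_coarse_network",
    "enzyme_qss_concentrations",
    "enzyme_closed_forms",
    "theta_steady_state",
    "mm_variances",
    "hill_variances",
]


@dataclass(frozen=True)
class EnzymeParams:
    """Rate constants and totals for the two-subunit enzyme network.

    Defaults are the headline parameter set used throughout: EET = 1,
    k2 = 1000, km1 = km2 = 100, k3 = k4 = 1, k1 = 5e-7, volume 100, and an
    input flux at half saturation (Theta = 1/2).
    """

    k_in: float = 0.5
    k1: float = 5e-7
    km1: float = 100.0
    k2: float = 1000.0
    km2: float = 100.0
    k3: float = 1.0
    k4: float = 1.0
    EET: float = 1.0
    omega: float = 100.0

    def __post_init__(self) -> None:
        for name in ("k_in", "k1", "km1", "k2", "km2", "k3", "k4", "EET", "omega"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def Km1(self) -> float:
        return (self.km1 + self.k3) / self.k1

    @property
    def Km2(self) -> float:
        return (self.km2 + self.k4) / self.k2

    @property
    def Km(self) -> float:
        """Hill-limit half-saturation constant, Km = sqrt(Km1 Km2)."""
        return float(np.sqrt(self.Km1 * self.Km2))

    @property
    def theta(self) -> float:
        """Enzyme saturation fraction Theta = k_in / (k4 EET)."""
        return self.k_in / (self.k4 * self.EET)

    def at_theta(self, theta: float) -> "EnzymeParams":
        return replace(self, k_in=theta * self.k4 * self.EET)


def enzyme_full_network(p: EnzymeParams, eliminate: bool = True) -> ReactionNetwork:
    """Full elementary network; by default the conserved free enzyme EE is
    eliminated so that the explicit state is (S; EES, SEES)."""
    s0 = enzyme_qss_concentrations(p, theta_steady_state(p.theta, p))
    species = [
        Species("S", "slow", s0["S"]),
        Species("EE", "fast", s0["EE"]),
        Species("EES", "fast", s0["EES"]),
        Species("SEES", "fast", s0["SEES"]),
    ]
    reactions = [
        Reaction({}, {"S": 1}, p.k_in, name="input"),
        Reaction({"S": 1, "EE": 1}, {"EES": 1}, p.k1, name="bind1"),
        Reaction({"EES": 1}, {"S": 1, "EE": 1}, p.km1, name="unbind1"),
        Reaction({"EES": 1}, {"EE": 1}, p.k3, name="cat1"),
        Reaction({"S": 1, "EES": 1}, {"SEES": 1}, p.k2, name="bind2"),
        Reaction({"SEES": 1}, {"S": 1, "EES": 1}, p.km2, name="unbind2"),
        Reaction({"SEES": 1}, {"EES": 1}, p.k4, name="cat2"),
    ]
    law = ConservationLaw({"EE": 1, "EES": 1, "SEES": 1}, p.EET)
    net = ReactionNetwork(species, reactions, p.omega, [law])
    if eliminate:
        net, _ = eliminate_conserved_species(net, choose={0: "EE"})
    return net


def _kprime_expression(p: EnzymeParams) -> str:
    return (
        f"{p.EET!r}*({p.k3!r}/{p.Km1!r} + {p.k4!r}*S/({p.Km1!r}*{p.Km2!r}))"
        f"/(1 + S/{p.Km1!r} + S**2/({p.Km1!r}*{p.Km2!r}))"
    )


def enzyme_coarse_network(p: EnzymeParams) -> ReactionNetwork:
    """Coarse-grained heuristic network 0 -> S -> P with the effective
    first-order rate k'(S); the catalysis step is non-elementary."""
    s0 = theta_steady_state(p.theta, p)
    species = [Species("S", "slow", s0)]
    reactions = [
        Reaction({}, {"S": 1}, p.k_in, name="input"),
        Reaction(
            {"S": 1}, {}, rate_law="custom",
            rate_expression=f"S*({_kprime_expression(p)})",
            name="catalysis",
        ),
    ]
    return ReactionNetwork(species, reactions, p.omega)


def enzyme_qss_concentrations(p: EnzymeParams, S: float) -> dict[str, float]:
    """Quasi-steady-state enzyme-form concentrations at substrate level S."""
    den = 1.0 + S / p.Km1 + S**2 / (p.Km1 * p.Km2)
    return {
        "S": S,
        "EE": p.EET / den,
        "EES": p.EET * (S / p.Km1) / den,
        "SEES": p.EET * (S**2 / (p.Km1 * p.Km2)) / den,
    }


def _kprime(p: EnzymeParams, S: float) -> float:
    den = 1.0 + S / p.Km1 + S**2 / (p.Km1 * p.Km2)
    return p.EET * (p.k3 / p.Km1 + p.k4 * S / (p.Km1 * p.Km2)) / den


def reduced_re_jacobian(p: EnzymeParams, S: float) -> float:
    """d/d[S] of (k_in - k'(S) [S]): the scalar reduced Jacobian."""
    # exact rational derivative, written out to avoid cancellation
    a, b = p.k3 / p.Km1, p.k4 / (p.Km1 * p.Km2)
    c, d = 1.0 / p.Km1, 1.0 / (p.Km1 * p.Km2)
    num = a * S + b * S**2
    den = 1.0 + c * S + d * S**2
    dnum = a + 2 * b * S
    dden = c + 2 * d * S
    return -p.EET * (dnum * den - num * dden) / den**2


def theta_steady_state(theta: float, p: EnzymeParams, limit: str | None = None) -> float:
    """Steady-state substrate concentration at saturation fraction Theta.

    ``limit='hill'`` returns the closed form Km sqrt(Theta/(1-Theta));
    ``limit='mm'`` returns Km1 * (k_in/k3 EET)/(1 - k_in/(k3 EET));
    otherwise the finite-parameter balance k_in = k'(S) S is solved
    numerically.  Theta >= 1 exceeds the maximal catalytic flux.
    """
    if not 0 < theta < 1:
        raise ValueError("no steady state: Theta must lie in (0, 1)")
    if limit == "hill":
        return p.Km * float(np.sqrt(theta / (1 - theta)))
    if limit == "mm":
        frac = theta * p.k4 / p.k3
        if frac >= 1:
            raise ValueError("no steady state: input exceeds maximal MM flux")
        return p.Km1 * frac / (1 - frac)
    pp = p.at_theta(theta)

    def g(S: float) -> float:
        return pp.k_in - _kprime(pp, S) * S

    hi = p.Km
    while g(hi) > 0:
        hi *= 4.0
        if hi > 1e200:
            raise ValueError("no steady state found for this Theta")
    return float(brentq(g, 0.0, hi, xtol=1e-300, rtol=1e-15))


def q_weights(p: EnzymeParams, S: float) -> tuple[float, float]:
    """Effective-stoichiometry weights q1, q2 at substrate level S."""
    den = S**2 + S * p.Km2 + p.Km1 * p.Km2
    q1 = (p.k3 * p.Km2 + p.k4 * S) / (p.k1 * den)
    q2 = (p.k4 * p.Km1 + (p.k4 - p.k3) * S) / (p.k2 * den)
    return q1, q2


def enzyme_closed_forms(p: EnzymeParams, S: float | None = None) -> dict[str, float]:
    """Closed-form noise statistics of the substrate fluctuations.

    Evaluated at the steady state implied by k_in (or at a supplied S).
    Returns q1, q2, the reduced Jacobian, the slow-scale and heuristic
    variances, and the corresponding Fano factors / coefficients of
    variation, all in concentration units.
    """
    if S is None:
        S = theta_steady_state(p.theta, p)
    conc = enzyme_qss_concentrations(p, S)
    q1, q2 = q_weights(p, S)
    J = reduced_re_jacobian(p, S)
    f2 = p.k1 * S * conc["EE"]
    f3 = p.km1 * conc["EES"]
    f4 = p.k3 * conc["EES"]
    f5 = p.k2 * S * conc["EES"]
    f6 = p.km2 * conc["SEES"]
    f7 = p.k4 * conc["SEES"]
    d_ss = (
        p.k_in
        + q1**2 * (f2 + f3)
        + (1 - q1) ** 2 * f4
        + q2**2 * (f5 + f6)
        + (1 - q2) ** 2 * f7
    ) / p.omega
    d_h = (p.k_in + f4 + f7) / p.omega
    var_ss = -d_ss / (2 * J)
    var_h = -d_h / (2 * J)
    out = {
        "S": S,
        "q1": q1,
        "q2": q2,
        "jacobian": J,
        "sigma2_sslna": var_ss,
        "sigma2_hlna": var_h,
        "ff_sslna": var_ss / S,
        "ff_hlna": var_h / S,
        "omega_ff_sslna": p.omega * var_ss / S,
        "omega_ff_hlna": p.omega * var_h / S,
        "cv_sslna": float(np.sqrt(var_ss)) / S,
        "cv_hlna": float(np.sqrt(var_h)) / S,
    }
    return out


def mm_variances(p: EnzymeParams, S: float) -> tuple[float, float]:
    """Michaelis-Menten-limit (k2 -> 0) substrate variances (ssLNA, hLNA).

    sigma2_ssLNA = ([S]/Omega) (1 + (km1/k1 + [S])/(Km1 + [S]) * [S]/Km1),
    sigma2_hLNA  = ([S]/Omega) (1 + [S]/Km1); the heuristic route
    overestimates, and both agree as [S] -> 0 or [S] -> inf.
    """
    var_h = (S / p.omega) * (1 + S / p.Km1)
    var_ss = (S / p.omega) * (
        1 + (p.km1 / p.k1 + S) / (p.Km1 + S) * (S / p.Km1)
    )
    return var_ss, var_h


def hill_variances(p: EnzymeParams, S: float) -> tuple[float, float]:
    """Hill-limit (k2 -> inf at constant Km) substrate variances (ssLNA, hLNA).

    sigma2_hLNA = ([S]/(2 Omega)) (Km^2 + [S]^2)/Km^2 and the slow-scale
    result adds (k4/(2 k1 Omega)) [S]^2/([S]^2 + Km^2): the heuristic route
    underestimates cooperative noise, strongly so when binding (k1) is the
    rate-limiting step.
    """
    Km2sq = p.Km1 * p.Km2
    var_h = (S / (2 * p.omega)) * (Km2sq + S**2) / Km2sq
    var_ss = var_h + (p.k4 / (2 * p.k1 * p.omega)) * S**2 / (S**2 + Km2sq)
    return var_ss, var_h
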