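"""Negative-feedback gene circuit: transcription, translation, enzymatic
protein degradation and cooperative transcriptional self-repression.

Full network (11 elementary reactions, numbered as used throughout):

     1  G   -> G + M        (k0)    transcription from free gene
     2  GP  -> GP + M       (k0)    transcription from singly-bound gene
     3  P + G  -> GP        (k1)    first repressor binding
     4  GP -> P + G         (km1)
     5  P + GP -> GP2       (k2)    second repressor binding
     6  GP2 -> P + GP       (km2)
     7  M -> 0              (kdM)   mRNA decay
     8  M -> M + P          (ks)    translation
     9  P + E -> EP         (k3)    binding to the degrading enzyme
    10  EP -> P + E         (km3)
    11  EP -> E             (k4)    catalysed protein degradation

The doubly-bound gene GP2 is transcriptionally silent, closing the negative
feedback loop.  Gene and enzyme totals are conserved (GT, ET); M and P are
the slow species, the gene and enzyme forms are fast.  Cooperative binding
is the limit k2 -> inf, k1 -> 0 at constant k1 k2, under which the active
gene fraction becomes K^2/(K^2 + [P]^2) with K^2 = km1 km2 / (k1 k2).

The quasi-steady-state weights entering the slow-scale diffusion are

    p1 = (k0/k1) [P] / (K^2 + K2 [P] + [P]^2),
    p2 = (k0/k2) (K1 + [P]) / (K^2 + K2 [P] + [P]^2),
    q  = ([P] + K3) / ([P] + KM),

with K1 = km1/k1, K2 = km2/k2, K3 = km3/k3 and KM = (km3 + k4)/k3.  In the
cooperative limit p2 -> 0: the second binding step contributes no noise.
The heuristic description corresponds to p1 = 0, q = 1, i.e. to discarding
the noise of both reversible fast reactions; when repression is strong the
slow rate-limiting binding of P to G then goes unaccounted and the protein
noise is underestimated by orders of magnitude.
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
    "GeneParams",
    "gene_full_network",
    "gene_coarse_network",
    "gene_steady_state",
    "gene_qss_concentrations",
    "gene_reduced_model",
    "GeneReducedModel",
    "classify_point",
    "bifurcation_scan",
]


@dataclass(frozen=True)
class GeneParams:
    """Rate constants, totals and volume for the feedback circuit.

    Defaults are the noise-comparison parameter set: GT = 0.01, ET = 1,
    k1 = 1e-5, k2 = 100, km1 = km2 = km3 = 10, k3 = k4 = ks = kdM = 1,
    k0 = 100, volume 100 (one gene copy, one hundred enzyme molecules).
    """

    k0: float = 100.0
    ks: float = 1.0
    kdM: float = 1.0
    k1: float = 1e-5
    km1: float = 10.0
    k2: float = 100.0
    km2: float = 10.0
    k3: float = 1.0
    km3: float = 10.0
    k4: float = 1.0
    GT: float = 0.01
    ET: float = 1.0
    omega: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "k0", "ks", "kdM", "k1", "km1", "k2", "km2", "k3", "km3", "k4",
            "GT", "ET", "omega",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def oscillatory(cls, k0: float = 1.0, ks: float = 1.0) -> "GeneParams":
        """Parameter set of the noise-induced-oscillation study: volume 1000,
        one gene copy (GT = 1/volume), ten enzyme molecules."""
        return cls(
            k0=k0, ks=ks, kdM=0.01, k1=0.001, km1=100.0, k2=1000.0, km2=1.0,
            k3=0.1, km3=10.0, k4=10.0, GT=0.001, ET=0.01, omega=1000.0,
        )

    @property
    def K1(self) -> float:
        return self.km1 / self.k1

    @property
    def K2(self) -> float:
        return self.km2 / self.k2

    @property
    def Ksq(self) -> float:
        """Cooperative repression constant K^2 = km1 km2 / (k1 k2)."""
        return self.K1 * self.K2

    @property
    def K3(self) -> float:
        return self.km3 / self.k3

    @property
    def KM(self) -> float:
        return (self.km3 + self.k4) / self.k3


def gene_full_network(p: GeneParams, eliminate: bool = True) -> ReactionNetwork:
    """The 11-reaction elementary network; with ``eliminate=True`` the free
    gene G and free enzyme E are removed via the two conservation laws so
    the explicit state is (M, P; GP, GP2, EP)."""
    M0, P0 = gene_steady_state(p)
    c = gene_qss_concentrations(p, P0)
    species = [
        Species("M", "slow", M0),
        Species("P", "slow", P0),
        Species("G", "fast", c["G"]),
        Species("GP", "fast", c["GP"]),
        Species("GP2", "fast", c["GP2"]),
        Species("E", "fast", c["E"]),
        Species("EP", "fast", c["EP"]),
    ]
    reactions = [
        Reaction({"G": 1}, {"G": 1, "M": 1}, p.k0, name="txn_G"),
        Reaction({"GP": 1}, {"GP": 1, "M": 1}, p.k0, name="txn_GP"),
        Reaction({"P": 1, "G": 1}, {"GP": 1}, p.k1, name="bindP1"),
        Reaction({"GP": 1}, {"P": 1, "G": 1}, p.km1, name="unbindP1"),
        Reaction({"P": 1, "GP": 1}, {"GP2": 1}, p.k2, name="bindP2"),
        Reaction({"GP2": 1}, {"P": 1, "GP": 1}, p.km2, name="unbindP2"),
        Reaction({"M": 1}, {}, p.kdM, name="mrna_decay"),
        Reaction({"M": 1}, {"M": 1, "P": 1}, p.ks, name="translation"),
        Reaction({"P": 1, "E": 1}, {"EP": 1}, p.k3, name="bindE"),
        Reaction({"EP": 1}, {"P": 1, "E": 1}, p.km3, name="unbindE"),
        Reaction({"EP": 1}, {"E": 1}, p.k4, name="degrade"),
    ]
    laws = [
        ConservationLaw({"G": 1, "GP": 1, "GP2": 1}, p.GT),
        ConservationLaw({"E": 1, "EP": 1}, p.ET),
    ]
    net = ReactionNetwork(species, reactions, p.omega, laws)
    if eliminate:
        net, _ = eliminate_conserved_species(net, choose={0: "G", 1: "E"})
    return net


def gene_coarse_network(p: GeneParams) -> ReactionNetwork:
    """Coarse-grained heuristic network over (M, P): cooperative-limit
    transcription, linear mRNA decay, translation, Michaelis-Menten protein
    degradation."""
    M0, P0 = gene_steady_state(p)
    species = [Species("M", "slow", M0), Species("P", "slow", P0)]
    reactions = [
        Reaction(
            {}, {"M": 1}, rate_law="custom",
            rate_expression=f"{p.k0!r}*{p.GT!r}*{p.Ksq!r}/({p.Ksq!r} + P**2)",
            name="txn",
        ),
        Reaction({"M": 1}, {}, p.kdM, name="mrna_decay"),
        Reaction({"M": 1}, {"M": 1, "P": 1}, p.ks, name="translation"),
        Reaction(
            {"P": 1}, {}, rate_law="custom",
            rate_expression=f"{p.k4!r}*{p.ET!r}*P/({p.KM!r} + P)",
            name="degrade",
        ),
    ]
    return ReactionNetwork(species, reactions, p.omega)


def gene_qss_concentrations(p: GeneParams, P: float) -> dict[str, float]:
    """Fast-species concentrations in quasi-steady state at protein level P."""
    den = p.Ksq + p.K2 * P + P**2
    return {
        "G": p.GT * p.Ksq / den,
        "GP": p.GT * p.K2 * P / den,
        "GP2": p.GT * P**2 / den,
        "E": p.ET * p.KM / (p.KM + P),
        "EP": p.ET * P / (p.KM + P),
    }


def gene_steady_state(
    p: GeneParams, cooperative_limit: bool = False
) -> tuple[float, float]:
    """Steady-state (M, P) of the reduced rate equations.

    With ``cooperative_limit`` the active gene fraction is K^2/(K^2+P^2);
    otherwise the finite-parameter fraction (K^2 + K2 P)/(K^2 + K2 P + P^2)
    is used, which is exact for the full network.  The scalar fixed-point
    equation in P is solved by bracketing.
    """

    def active(P: float) -> float:
        if cooperative_limit:
            return p.Ksq / (p.Ksq + P**2)
        return (p.Ksq + p.K2 * P) / (p.Ksq + p.K2 * P + P**2)

    def g(P: float) -> float:
        M = p.k0 * p.GT * active(P) / p.kdM
        return p.ks * M - p.k4 * p.ET * P / (p.KM + P)

    hi = 1.0
    while g(hi) > 0:
        hi *= 4.0
        if hi > 1e250:
            raise RuntimeError("no steady state found")
    P = float(brentq(g, 0.0, hi, xtol=1e-300, rtol=1e-15))
    M = p.k0 * p.GT * active(P) / p.kdM
    return M, P


# -- reduced (cooperative-limit) model with closed-form noise statistics ----


@dataclass(frozen=True)
class GeneReducedModel:
    """Closed-form slow-variable description of the feedback circuit.

    All quantities are evaluated at the cooperative-limit steady state of
    the reduced rate equations

        d[M]/dt = k0 GT K^2/(K^2 + [P]^2) - kdM [M],
        d[P]/dt = ks [M] - k4 ET [P]/(KM + [P]).
    """

    params: GeneParams
    M: float
    P: float
    jacobian: np.ndarray
    diffusion_sslna: np.ndarray
    diffusion_hlna: np.ndarray
    p1: float
    p2: float
    q: float

    def variances(self, flavor: str = "ssLNA") -> tuple[float, float]:
        """Stationary (sigma2_M, sigma2_P) from the 2x2 Lyapunov solution,

        sigma2_M = -[(Det J + J22^2) D_M + J12^2 D_P] / (2 Tr J Det J),
        sigma2_P = -[J21^2 D_M + (Det J + J11^2) D_P] / (2 Tr J Det J).
        """
        J = self.jacobian
        D = self.diffusion_sslna if flavor == "ssLNA" else self.diffusion_hlna
        tr, det = float(np.trace(J)), float(np.linalg.det(J))
        dm, dp = D[0, 0], D[1, 1]
        s2m = ((det + J[1, 1] ** 2) * dm + J[0, 1] ** 2 * dp) / (-2 * tr * det)
        s2p = (J[1, 0] ** 2 * dm + (det + J[0, 0] ** 2) * dp) / (-2 * tr * det)
        return s2m, s2p

    def spectra(self, omega_grid: np.ndarray, flavor: str = "ssLNA"):
        """Closed-form power spectra (P_M, P_P) on an angular-frequency grid,

        P_M = [(J22^2 + w^2) D_M + J12^2 D_P] / (Det^2 + (Tr^2 - 2 Det) w^2 + w^4)
        and symmetrically for P_P.
        """
        J = self.jacobian
        D = self.diffusion_sslna if flavor == "ssLNA" else self.diffusion_hlna
        w2 = np.asarray(omega_grid, dtype=float) ** 2
        tr, det = float(np.trace(J)), float(np.linalg.det(J))
        den = det**2 + (tr**2 - 2 * det) * w2 + w2**2
        pm = ((J[1, 1] ** 2 + w2) * D[0, 0] + J[0, 1] ** 2 * D[1, 1]) / den
        pp = (J[1, 0] ** 2 * D[0, 0] + (J[0, 0] ** 2 + w2) * D[1, 1]) / den
        return pm, pp

    def mrna_peak_condition(self, flavor: str = "ssLNA") -> bool:
        """Sign criterion for a noise-induced-oscillation peak in the mRNA
        spectrum: (J22^2 D_M + J12^2 D_P)(Tr^2 - 2 Det) - D_M Det^2 < 0."""
        J = self.jacobian
        D = self.diffusion_sslna if flavor == "ssLNA" else self.diffusion_hlna
        tr, det = float(np.trace(J)), float(np.linalg.det(J))
        C = J[1, 1] ** 2 * D[0, 0] + J[0, 1] ** 2 * D[1, 1]
        return bool(C * (tr**2 - 2 * det) - D[0, 0] * det**2 < 0)


def gene_reduced_model(
    p: GeneParams, cooperative_limit: bool = True
) -> GeneReducedModel:
    """Evaluate the reduced-model closed forms at the steady state.

    With ``cooperative_limit=False`` the finite-parameter weights p1, p2, q
    and quasi-steady-state rates are used throughout, which reproduces the
    generic slow-scale pipeline applied to the full network exactly.
    """
    M, P = gene_steady_state(p, cooperative_limit=cooperative_limit)
    c = gene_qss_concentrations(p, P)
    den = p.Ksq + p.K2 * P + P**2
    if cooperative_limit:
        den_lim = p.Ksq + P**2
        p1 = (p.k0 / p.k1) * P / den_lim
        p2 = 0.0
        frac = p.Ksq / den_lim
        f34 = 2 * p.k1 * P * p.GT * p.Ksq / den_lim
        f56 = 0.0
    else:
        p1 = (p.k0 / p.k1) * P / den
        p2 = (p.k0 / p.k2) * (p.K1 + P) / den
        frac = (p.Ksq + p.K2 * P) / den
        f34 = p.k1 * P * c["G"] + p.km1 * c["GP"]
        f56 = p.k2 * P * c["GP"] + p.km2 * c["GP2"]
    q = (P + p.K3) / (P + p.KM)
    f9 = p.k3 * c["E"] * P
    f10 = p.km3 * c["EP"]
    f11 = p.k4 * c["EP"]
    DM = (p.kdM * M + p.k0 * p.GT * frac + p1**2 * f34 + p2**2 * f56) / p.omega
    DP = (p.ks * M + (1 - q) ** 2 * (f9 + f10) + q**2 * f11) / p.omega
    DhM = (p.kdM * M + p.k0 * p.GT * frac) / p.omega
    DhP = (p.ks * M + f11) / p.omega
    if cooperative_limit:
        dfrac = -2 * p.k0 * p.GT * p.Ksq * P / den_lim**2
    else:
        dfrac = p.k0 * p.GT * (
            p.K2 * den - (p.Ksq + p.K2 * P) * (p.K2 + 2 * P)
        ) / den**2
    J = np.array(
        [
            [-p.kdM, dfrac],
            [p.ks, -p.ET * p.k4 * p.KM / (p.KM + P) ** 2],
        ]
    )
    return GeneReducedModel(
        params=p, M=M, P=P, jacobian=J,
        diffusion_sslna=np.diag([DM, DP]),
        diffusion_hlna=np.diag([DhM, DhP]),
        p1=p1, p2=p2, q=q,
    )


# -- stochastic bifurcation scan --------------------------------------------

_LABELS = ("no_steady_state", "neither_peak", "both_peak", "sslna_only_peak",
           "hlna_only_peak")


def _full_jacobian(p: GeneParams, M: float, P: float) -> np.ndarray:
    """5x5 Jacobian of the full network over (M, P, GP, GP2, EP), with G and
    E expressed through the conservation totals; assembled from the explicit
    mass-action derivatives (independent of the symbolic pipeline)."""
    c = gene_qss_concentrations(p, P)
    G, GP, GP2, E, EP = c["G"], c["GP"], c["GP2"], c["E"], c["EP"]
    J = np.zeros((5, 5))
    # d M/dt = k0 (GT - GP2) - kdM M     (since G + GP = GT - GP2)
    J[0, 0] = -p.kdM
    J[0, 3] = -p.k0
    # d P/dt = -k1 P G + km1 GP - k2 P GP + km2 GP2 + ks M - k3 P E + km3 EP
    J[1, 0] = p.ks
    J[1, 1] = -p.k1 * G - p.k2 * GP - p.k3 * E
    J[1, 2] = p.km1 + p.k1 * P - p.k2 * P
    J[1, 3] = p.km2 + p.k1 * P
    J[1, 4] = p.km3 + p.k3 * P
    # d GP/dt = k1 P G - km1 GP - k2 P GP + km2 GP2
    J[2, 1] = p.k1 * G - p.k2 * GP
    J[2, 2] = -p.km1 - (p.k1 + p.k2) * P
    J[2, 3] = p.km2 - p.k1 * P
    # d GP2/dt = k2 P GP - km2 GP2
    J[3, 1] = p.k2 * GP
    J[3, 2] = p.k2 * P
    J[3, 3] = -p.km2
    # d EP/dt = k3 P E - (km3 + k4) EP
    J[4, 1] = p.k3 * E
    J[4, 4] = -p.km3 - p.k4 - p.k3 * P
    return J


def classify_point(p: GeneParams, full_stability: bool = True) -> str:
    """Label one parameter point of the stochastic bifurcation diagram.

    The steady state is solved from the exact scalar balance; stability is
    judged from the full-network Jacobian (the reduced two-variable system
    is unconditionally stable, but the full circuit can lose stability at
    strong drive, which is the deterministically oscillatory regime).  Peak
    flags for the mRNA spectrum come from the closed-form sign criterion
    applied to the finite-parameter slow-scale and heuristic diffusions.
    """
    try:
        M, P = gene_steady_state(p)
    except RuntimeError:
        return "no_steady_state"
    if full_stability:
        J5 = _full_jacobian(p, M, P)
        eig = np.linalg.eigvals(J5)
        if np.any(eig.real >= -1e-12 * np.linalg.norm(J5)):
            return "no_steady_state"
    m = gene_reduced_model(p, cooperative_limit=False)
    ss_peak = m.mrna_peak_condition("ssLNA")
    h_peak = m.mrna_peak_condition("hLNA")
    if ss_peak and h_peak:
        return "both_peak"
    if ss_peak:
        return "sslna_only_peak"
    if h_peak:
        return "hlna_only_peak"
    return "neither_peak"


def bifurcation_scan(
    k0_range: tuple[float, float],
    ks_range: tuple[float, float],
    p: GeneParams,
    n_k0: int = 60,
    n_ks: int = 60,
):
    """Classify a log-spaced (k0, ks) grid into oscillation regimes.

    Returns (k0 grid, ks grid, label array of shape (n_ks, n_k0)).  Labels:
    ``no_steady_state`` (none found, or the full network is deterministically
    unstable), ``neither_peak``, ``both_peak``, ``sslna_only_peak`` and the
    in-principle possible ``hlna_only_peak``.
    """
    if n_k0 < 2 or n_ks < 2:
        raise ValueError("grid resolutions must be >= 2")
    k0s = np.logspace(np.log10(k0_range[0]), np.log10(k0_range[1]), n_k0)
    kss = np.logspace(np.log10(ks_range[0]), np.log10(ks_range[1]), n_ks)
    labels = np.empty((n_ks, n_k0), dtype=object)
    for i, ks in enumerate(kss):
        for j, k0 in enumerate(k0s):
            labels[i, j] = classify_point(replace(p, k0=k0, ks=ks))
    return k0s, kss, labels
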