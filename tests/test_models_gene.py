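"""Gene-circuit closed forms, oscillation diagnostics and the two-stage model."""

import numpy as np
import pytest

from sslna import (
    partition_system,
    power_spectrum,
    slow_scale_lna,
    solve_lyapunov,
    spectrum_peak,
    steady_state,
)
from sslna.models import (
    GeneParams,
    SimpleGeneParams,
    bifurcation_scan,
    classify_point,
    gene_full_network,
    gene_reduced_model,
    gene_steady_state,
    simple_gene_model,
    twostage_network,
)
from sslna.models.gene import gene_qss_concentrations

from conftest import random_gene_params


def test_qss_gene_fractions():
    p = GeneParams()
    P = 37.0
    c = gene_qss_concentrations(p, P)
    den = p.Ksq + p.K2 * P + P**2
    assert c["G"] == pytest.approx(p.GT * p.Ksq / den, rel=1e-12)
    assert c["GP"] == pytest.approx(p.GT * p.K2 * P / den, rel=1e-12)
    assert c["GP2"] == pytest.approx(p.GT * P**2 / den, rel=1e-12)
    assert c["G"] + c["GP"] + c["GP2"] == pytest.approx(p.GT, rel=1e-12)
    assert c["E"] + c["EP"] == pytest.approx(p.ET, rel=1e-12)


def test_active_gene_fraction_cooperative_limit():
    """As k2 -> inf at fixed K the active fraction tends to K^2/(K^2+P^2)."""
    P = 50.0
    p_lim = GeneParams(k2=1e8, km2=1e4)  # same K2 ratio scale, tiny K2 = km2/k2
    c = gene_qss_concentrations(p_lim, P)
    active = (c["G"] + c["GP"]) / p_lim.GT
    assert active == pytest.approx(p_lim.Ksq / (p_lim.Ksq + P**2), rel=1e-3)


def test_closed_form_diffusions_match_generic_pipeline_on_random_draws():
    """Finite-parameter p1, p2, q closed forms reproduce the generic
    slow-scale diffusion, Jacobian and variances to 1e-8 relative."""
    rng = np.random.default_rng(23)
    for _ in range(100):
        p = random_gene_params(rng)
        net = gene_full_network(p)
        ss = steady_state(net)
        red = slow_scale_lna(net, ss.concentrations)
        m = gene_reduced_model(p, cooperative_limit=False)
        np.testing.assert_allclose(red.jacobian, m.jacobian, rtol=1e-8)
        np.testing.assert_allclose(
            np.diag(red.diffusion), np.diag(m.diffusion_sslna), rtol=1e-8
        )
        # off-diagonal slow-scale diffusion vanishes for this circuit
        assert abs(red.diffusion[0, 1]) <= 1e-10 * np.diag(red.diffusion).max()
        s2m, s2p = m.variances("ssLNA")
        assert red.covariance[0, 0] == pytest.approx(s2m, rel=1e-8)
        assert red.covariance[1, 1] == pytest.approx(s2p, rel=1e-8)


def test_closed_form_variances_and_spectra_match_lyapunov_and_direct_formula():
    """The 2x2 closed-form variances and spectra equal the generic Lyapunov
    solve and resolvent spectrum for both flavors."""
    for p in (GeneParams(), GeneParams.oscillatory(k0=1.0, ks=10.0)):
        m = gene_reduced_model(p, cooperative_limit=False)
        w = np.logspace(-4, 2, 200)
        for flavor, D in (
            ("ssLNA", m.diffusion_sslna), ("hLNA", m.diffusion_hlna),
        ):
            H = solve_lyapunov(m.jacobian, D)
            s2m, s2p = m.variances(flavor)
            assert H[0, 0] == pytest.approx(s2m, rel=1e-8)
            assert H[1, 1] == pytest.approx(s2p, rel=1e-8)
            spec = power_spectrum(m.jacobian, D, w)
            pm, pp = m.spectra(w, flavor)
            np.testing.assert_allclose(spec.power[0], pm, rtol=1e-8)
            np.testing.assert_allclose(spec.power[1], pp, rtol=1e-8)


def test_flavors_coincide_when_fast_reversible_noise_is_discarded():
    """Forcing p1 -> 0 and q -> 1 in the slow-scale diffusion recovers the
    heuristic diffusion entrywise."""
    p = GeneParams()
    m = gene_reduced_model(p, cooperative_limit=True)
    c = gene_qss_concentrations(p, m.P)
    f9 = p.k3 * c["E"] * m.P
    f10 = p.km3 * c["EP"]
    f11 = p.k4 * c["EP"]
    DM_forced = (p.kdM * m.M + p.k0 * p.GT * p.Ksq / (p.Ksq + m.P**2)) / p.omega
    DP_forced = (p.ks * m.M + 0.0 * (f9 + f10) + 1.0 * f11) / p.omega
    np.testing.assert_allclose(
        [DM_forced, DP_forced], np.diag(m.diffusion_hlna), rtol=1e-12
    )


def test_protein_noise_amplification_at_strong_repression(gene_params):
    """At k3 = 1, k0 = 100 the slow-scale protein Fano factor exceeds the
    heuristic prediction by about three orders of magnitude."""
    m = gene_reduced_model(gene_params)
    _, s2p_ss = m.variances("ssLNA")
    _, s2p_h = m.variances("hLNA")
    assert 2.5 < np.log10(s2p_ss / s2p_h) < 3.5


def test_peak_condition_agrees_with_numeric_detection_on_random_draws():
    """The closed-form mRNA peak criterion and the numeric spectrum maximum
    agree on 100 random stable parameter draws."""
    rng = np.random.default_rng(29)
    count_peaks = 0
    for _ in range(100):
        p = random_gene_params(rng)
        m = gene_reduced_model(p, cooperative_limit=False)
        analytic = m.mrna_peak_condition("ssLNA")
        numeric, _ = spectrum_peak(m.jacobian, m.diffusion_sslna, 0,
                                   prominence=1e-12)
        assert numeric == analytic
        count_peaks += numeric
    # the draw distribution straddles the oscillation boundary
    assert 0 < count_peaks < 100


def test_bifurcation_regions_and_marked_points():
    """A coarse scan of the oscillation study grid contains all four region
    labels, and representative points classify blue/red/black."""
    p = GeneParams.oscillatory()
    _, _, labels = bifurcation_scan((1e-2, 1e4), (1e-3, 1e3), p, n_k0=14, n_ks=14)
    found = set(labels.ravel())
    assert {"no_steady_state", "neither_peak", "both_peak",
            "sslna_only_peak"} <= found
    assert classify_point(GeneParams.oscillatory(k0=316.0, ks=1e-3)) == "sslna_only_peak"
    assert classify_point(GeneParams.oscillatory(k0=1.0, ks=10.0)) == "both_peak"
    assert classify_point(GeneParams.oscillatory(k0=0.01, ks=0.01)) == "neither_peak"
    assert classify_point(GeneParams.oscillatory(k0=1e4, ks=1e3)) == "no_steady_state"


def test_marked_point_spectra_confirm_classifications():
    """At the three representative points the numeric spectra of both
    flavors reproduce the region labels."""
    blue = gene_reduced_model(GeneParams.oscillatory(k0=316.0, ks=1e-3),
                              cooperative_limit=False)
    assert spectrum_peak(blue.jacobian, blue.diffusion_sslna, 0)[0]
    assert not spectrum_peak(blue.jacobian, blue.diffusion_hlna, 0)[0]
    red = gene_reduced_model(GeneParams.oscillatory(k0=1.0, ks=10.0),
                             cooperative_limit=False)
    assert spectrum_peak(red.jacobian, red.diffusion_sslna, 0)[0]
    assert spectrum_peak(red.jacobian, red.diffusion_hlna, 0)[0]
    black = gene_reduced_model(GeneParams.oscillatory(k0=0.01, ks=0.01),
                               cooperative_limit=False)
    assert not spectrum_peak(black.jacobian, black.diffusion_sslna, 0)[0]
    assert not spectrum_peak(black.jacobian, black.diffusion_hlna, 0)[0]


# -- two-stage gene expression ----------------------------------------------


def test_twostage_sslna_variance_is_burst_corrected_poisson():
    """Generic slow-scale pipeline gives var_P = [P](1+b)/Omega exactly."""
    p = SimpleGeneParams()
    net = twostage_network(p)
    ss = steady_state(net)
    red = slow_scale_lna(net, ss.concentrations)
    closed = simple_gene_model(p)
    assert red.covariance[0, 0] == pytest.approx(closed["sslna_variance"],
                                                 rel=1e-10)
    assert closed["sslna_omega_fano"] == pytest.approx(1.0 + p.burst_size)


def test_twostage_block_diagonal_variant_loses_the_burst_factor():
    """Discarding the fast-reaction noise term leaves the bare Poisson
    variance [P]/Omega (the b << 1 special case)."""
    from sslna import diffusion_full, reduced_jacobian, stoichiometric_matrix

    p = SimpleGeneParams()
    net = twostage_network(p)
    ss = steady_state(net)
    part = partition_system(net, ss.concentrations)
    # block-diagonal reduction keeps only the slow-slow block of D_F
    D_s = diffusion_full(net, ss.concentrations)[:1, :1]
    J = reduced_jacobian(part)
    var_pahlajani = solve_lyapunov(J, D_s)[0, 0]
    closed = simple_gene_model(p)
    assert var_pahlajani == pytest.approx(closed["pahlajani_variance"], rel=1e-10)


def test_twostage_variants_agree_for_vanishing_burst():
    p = SimpleGeneParams(ks=0.001, kdM=10.0)  # b = 1e-4
    closed = simple_gene_model(p)
    assert closed["sslna_variance"] == pytest.approx(
        closed["pahlajani_variance"], rel=2e-4
    )


def test_twostage_warns_without_timescale_separation():
    with pytest.warns(UserWarning, match="gamma"):
        simple_gene_model(SimpleGeneParams(kdM=0.1, kdP=0.1))
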