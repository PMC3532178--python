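"""LNA flavors: diffusion matrices, Lyapunov covariances, spectra, peaks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sslna import (
    diffusion_full,
    diffusion_hlna,
    diffusion_sslna,
    effective_stoichiometry,
    full_lna,
    heuristic_lna,
    jacobian,
    noise_summary,
    partition_system,
    power_spectrum,
    reduced_cme_exists,
    reduced_jacobian,
    slow_scale_lna,
    solve_lyapunov,
    spectrum_peak,
    spectrum_variance,
    steady_state,
)
from sslna.lna import StabilityError, analytic_peak_condition
from sslna.models import (
    EnzymeParams,
    GeneParams,
    enzyme_coarse_network,
    enzyme_full_network,
    gene_full_network,
    gene_reduced_model,
)

from conftest import random_enzyme_params


def kron_lyapunov(J, D):
    """Independent Kronecker-vectorisation solve of J H + H J^T = -D."""
    n = J.shape[0]
    A = np.kron(J, np.eye(n)) + np.kron(np.eye(n), J)
    return np.linalg.solve(A, -D.reshape(-1)).reshape(n, n)


def random_stable_system(rng, n):
    A = rng.normal(size=(n, n))
    J = A - (np.abs(np.linalg.eigvals(A).real).max() + 0.5) * np.eye(n)
    B = rng.normal(size=(n, n + 2))
    D = B @ B.T
    return J, D


def test_birth_death_diffusion_scalar(birth_death):
    x = np.array([10.0])
    D = diffusion_full(birth_death, x)
    assert D[0, 0] == pytest.approx((5.0 + 0.5 * 10.0) / 100.0)


def test_full_diffusions_are_symmetric_psd():
    for net, x in [
        (enzyme_full_network(EnzymeParams()), None),
        (gene_full_network(GeneParams()), None),
    ]:
        ss = steady_state(net)
        D = diffusion_full(net, ss.concentrations)
        np.testing.assert_allclose(D, D.T)
        assert np.linalg.eigvalsh(D).min() >= -1e-12 * np.abs(D).max()


def test_sslna_diffusion_reduces_to_slow_block_without_coupling(birth_death):
    part = partition_system(birth_death, np.array([10.0]))
    D, Sp = diffusion_sslna(part)
    np.testing.assert_allclose(D, diffusion_full(birth_death, np.array([10.0])))
    np.testing.assert_allclose(Sp, part.S_s)
    assert reduced_cme_exists(Sp)


def test_effective_stoichiometry_not_integer_at_generic_parameters():
    net = enzyme_full_network(EnzymeParams())
    ss = steady_state(net)
    Sp = effective_stoichiometry(partition_system(net, ss.concentrations))
    assert not reduced_cme_exists(Sp)
    # forcing the q-weights to zero restores the heuristic integer pattern
    assert reduced_cme_exists(np.array([[1, 0, 0, -1, 0, 0, -1.0]]))


def test_sslna_diffusion_psd_on_random_parameter_draws():
    rng = np.random.default_rng(7)
    for _ in range(20):
        p = random_enzyme_params(rng)
        net = enzyme_full_network(p)
        ss = steady_state(net)
        D, _ = diffusion_sslna(partition_system(net, ss.concentrations))
        np.testing.assert_allclose(D, D.T)
        assert np.linalg.eigvalsh(D).min() >= -1e-12 * max(np.abs(D).max(), 1e-300)


def test_lyapunov_scalar_and_identity_cases():
    assert solve_lyapunov(np.array([[-2.0]]), np.array([[4.0]]))[0, 0] == pytest.approx(1.0)
    H = solve_lyapunov(-0.5 * np.eye(3), np.eye(3))
    np.testing.assert_allclose(H, np.eye(3), rtol=1e-12)


def test_lyapunov_matches_kronecker_oracle():
    rng = np.random.default_rng(3)
    for n in (2, 3, 5):
        J, D = random_stable_system(rng, n)
        H = solve_lyapunov(J, D)
        np.testing.assert_allclose(H, kron_lyapunov(J, D), rtol=1e-9)
        resid = np.linalg.norm(J @ H + H @ J.T + D)
        assert resid <= 1e-10 * np.linalg.norm(D)


def test_lyapunov_rejects_unstable_jacobian():
    with pytest.raises(StabilityError, match="monostable"):
        solve_lyapunov(np.array([[0.1]]), np.array([[1.0]]))


def test_scalar_spectrum_is_lorentzian():
    J, D = np.array([[-2.0]]), np.array([[4.0]])
    w = np.logspace(-2, 2, 50)
    spec = power_spectrum(J, D, w)
    np.testing.assert_allclose(spec.power[0], 4.0 / (w**2 + 4.0), rtol=1e-10)
    assert not spec.has_peak[0]


@pytest.mark.parametrize("n", [1, 2, 3])
def test_spectrum_integral_recovers_variance(n):
    """Wiener-Khinchin consistency: int P_j dw / 2 pi = H_jj."""
    rng = np.random.default_rng(n)
    J, D = random_stable_system(rng, n)
    H = solve_lyapunov(J, D)
    for j in range(n):
        assert spectrum_variance(J, D, j) == pytest.approx(H[j, j], rel=1e-4)


def test_spectrum_integral_for_all_three_flavors_of_the_enzyme_model():
    p = EnzymeParams(k1=5e-3)
    net = enzyme_full_network(p)
    ss = steady_state(net)
    coarse = enzyme_coarse_network(p)
    ssc = steady_state(coarse)
    reductions = [
        full_lna(net, ss.concentrations),
        slow_scale_lna(net, ss.concentrations),
        heuristic_lna(coarse, ssc.concentrations),
    ]
    for red in reductions:
        for j in range(red.jacobian.shape[0]):
            assert spectrum_variance(red.jacobian, red.diffusion, j) == pytest.approx(
                red.covariance[j, j], rel=1e-4
            )


def test_single_slow_species_never_peaks():
    p = EnzymeParams()
    net = enzyme_full_network(p)
    ss = steady_state(net)
    red = slow_scale_lna(net, ss.concentrations)
    has_peak, _ = spectrum_peak(red.jacobian, red.diffusion)
    assert not has_peak


def test_numeric_peak_agrees_with_analytic_condition_in_oscillatory_regime():
    red_point = GeneParams.oscillatory(k0=1.0, ks=10.0)
    m = gene_reduced_model(red_point, cooperative_limit=False)
    assert m.mrna_peak_condition("ssLNA")
    has_peak, wstar = spectrum_peak(m.jacobian, m.diffusion_sslna, 0)
    assert has_peak and wstar > 0
    assert analytic_peak_condition(m.jacobian, m.diffusion_sslna, 0)


def test_noise_summary_poissonian_case(birth_death):
    red = full_lna(birth_death, np.array([10.0]))
    s = red.summary()
    assert s.omega_fano[0] == pytest.approx(1.0, rel=1e-10)
    assert s.cv_squared[0] == pytest.approx(1.0 / (100.0 * 10.0), rel=1e-10)


def test_noise_summary_requires_positive_means():
    with pytest.raises(ValueError, match="positive means"):
        noise_summary(np.eye(1), np.array([0.0]), 100.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(1, 4), st.integers(0, 10_000))
def test_lyapunov_solution_is_symmetric_psd(n, seed):
    rng = np.random.default_rng(seed)
    J, D = random_stable_system(rng, n)
    H = solve_lyapunov(J, D)
    np.testing.assert_allclose(H, H.T, atol=1e-10 * np.abs(H).max())
    assert np.linalg.eigvalsh(H).min() >= -1e-9 * np.abs(H).max()


def test_full_and_slow_scale_variances_agree_under_separation():
    """With strong timescale separation the slow-species variance from the
    full LNA matches the slow-scale reduction."""
    net = enzyme_full_network(EnzymeParams())
    ss = steady_state(net)
    var_full = full_lna(net, ss.concentrations).covariance[0, 0]
    var_ss = slow_scale_lna(net, ss.concentrations).covariance[0, 0]
    assert var_ss == pytest.approx(var_full, rel=1e-6)
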