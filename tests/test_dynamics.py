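"""Equations of motion, integration, and linearized diagnostics."""

import numpy as np
import pytest

import dnapendulum as dp
from _oracle import pair_mode_rates, rk4_oracle

# strand-1 constants for poly(A)·poly(T), frozen from the published table
I_A, R_A, K_A = 7.61e-44, 5.80e-10, 2.35e-18
R_T = 4.80e-10
K12_AT = 6.20e-2


def _polyA(n, lam=1.0, **kw):
    return dp.build_system("A" * n, lam=lam, **kw)


def test_zero_state_is_an_exact_fixed_point_of_the_rhs():
    s = dp.build_system("ACGT")
    st = dp.initial_state(s)
    d = dp.rhs(st, 0.0, s, dp.ForcingSpec(mode="zero"))
    assert np.all(d.phi == 0.0)
    assert np.all(d.omega == 0.0)


def test_interior_site_acceleration_matches_hand_evaluation():
    """Term-by-term evaluation of the interior equation for strand 1.

    3-site poly(A)·poly(T), angle eps only at strand-1 site 2 (middle):
    backbone gives K_A(0 - 2eps + 0); the pair term -k12 R_A (R_A+R_T) sin eps;
    the cross term -k12 R_A R_T sin eps; no forcing.
    """
    eps = 1e-6
    s = _polyA(3)
    phi = np.zeros((2, 3))
    phi[0, 1] = eps
    st = dp.State(t=0.0, phi=phi, omega=np.zeros((2, 3)))
    d = dp.rhs(st, 0.0, s, dp.ForcingSpec(mode="zero"))
    expected = (
        K_A * (0.0 - 2.0 * eps + 0.0)
        - K12_AT * R_A * (R_A + R_T) * np.sin(eps)
        - K12_AT * R_A * R_T * np.sin(eps)
    ) / I_A
    assert d.omega[0, 1] == pytest.approx(expected, rel=1e-14)


def test_boundary_site_uses_single_neighbour_coupling():
    eps = 1e-6
    s = _polyA(3)
    phi = np.zeros((2, 3))
    phi[0, 0] = eps
    st = dp.State(t=0.0, phi=phi, omega=np.zeros((2, 3)))
    d = dp.rhs(st, 0.0, s, dp.ForcingSpec(mode="zero"))
    # K_A (phi_12 - phi_11) = K_A (0 - eps): one neighbour only
    expected = (
        K_A * (0.0 - eps)
        - K12_AT * R_A * (R_A + R_T) * np.sin(eps)
        - K12_AT * R_A * R_T * np.sin(eps)
    ) / I_A
    assert d.omega[0, 0] == pytest.approx(expected, rel=1e-14)


def test_rhs_matches_scalar_oracle_on_random_state(system10):
    rng = np.random.default_rng(0)
    phi = rng.normal(scale=0.3, size=(2, 10))
    om = rng.normal(scale=1e10, size=(2, 10))
    st = dp.State(t=0.0, phi=phi, omega=om)
    d = dp.rhs(st, 0.0, system10, dp.ForcingSpec(mode="constant", amplitude=1e-22))
    from _oracle import scalar_rhs

    y = np.concatenate([phi[0], phi[1], om[0], om[1]])
    s = system10
    dy = scalar_rhs(y, 0.0, 10, s.I1, s.I2, s.R1, s.R2, s.K1, s.K2, s.k12,
                    s.effective_beta1, s.effective_beta2, 1e-22)
    np.testing.assert_allclose(
        np.concatenate([d.omega[0], d.omega[1]]), dy[20:], rtol=1e-13
    )


@pytest.mark.parametrize(
    "forcing,t,expected",
    [
        (dp.ForcingSpec(mode="constant", amplitude=1e-22), 3.7e-10, 1e-22),
        (dp.ForcingSpec(mode="cosine", amplitude=1e-22, omega=1e9), 0.0, 1e-22),
        (dp.ForcingSpec(mode="zero"), 1e-9, 0.0),
    ],
)
def test_external_torque_modes(forcing, t, expected):
    assert dp.external_torque(t, forcing) == pytest.approx(expected, abs=0)


def test_cosine_torque_oscillates():
    f = dp.ForcingSpec(mode="cosine", amplitude=1e-22, omega=1e9)
    t = np.pi / 1e9  # half period
    assert dp.external_torque(t, f) == pytest.approx(-1e-22, rel=1e-12)


def test_initial_state_defaults_to_equilibrium(system10):
    st = dp.initial_state(system10)
    assert st.t == 0.0
    assert np.all(st.phi == 0.0) and np.all(st.omega == 0.0)


def test_initial_state_override_is_stored_verbatim(system10):
    phi0 = np.full((2, 10), 0.123)
    st = dp.initial_state(system10, phi0=phi0)
    np.testing.assert_array_equal(st.phi, phi0)


def test_initial_state_rejects_wrong_shapes(system10):
    with pytest.raises(ValueError, match="shape"):
        dp.initial_state(system10, phi0=np.zeros((2, 7)))


def test_state_rejects_non_finite_entries():
    phi = np.zeros((2, 3))
    phi[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        dp.State(t=0.0, phi=phi, omega=np.zeros((2, 3)))


def test_equilibrium_is_preserved_bitwise(system10):
    tr = dp.integrate(system10, dp.ForcingSpec(mode="zero"), t_end=1e-12, n_out=20)
    assert np.all(tr.phi == 0.0)
    assert np.all(tr.omega == 0.0)


def test_integration_is_bitwise_deterministic(system10):
    f = dp.ForcingSpec()
    tr1 = dp.integrate(system10, f, t_end=2e-12, n_out=50)
    tr2 = dp.integrate(system10, f, t_end=2e-12, n_out=50)
    np.testing.assert_array_equal(tr1.phi, tr2.phi)
    np.testing.assert_array_equal(tr1.omega, tr2.omega)
    np.testing.assert_array_equal(tr1.times, tr2.times)


def test_overlong_step_is_rejected(system10):
    with pytest.raises(ValueError, match="too large"):
        dp.integrate(system10, dp.ForcingSpec(), t_end=1e-11, dt=1e-12)


def test_invalid_horizon_is_rejected(system10):
    with pytest.raises(ValueError, match="t_end"):
        dp.integrate(system10, dp.ForcingSpec(), t_end=0.0)


def test_output_decimation_counts(system10):
    tr = dp.integrate(system10, dp.ForcingSpec(), t_end=1e-12, dt=1e-14, n_out=25)
    # 100 steps decimated by stride 4 -> 26 snapshots, endpoints included
    assert len(tr.times) == 26
    assert tr.times[0] == 0.0
    assert tr.times[-1] == pytest.approx(1e-12)


def test_full_resolution_storage(system10):
    tr = dp.integrate(system10, dp.ForcingSpec(), t_end=1e-12, dt=1e-14, n_out=0)
    assert len(tr.times) == 101


def test_production_integrator_matches_tiny_step_oracle(system10):
    """Two-route check on a short window: vectorized fixed-step integrator
    against the independently coded scalar-loop tiny-step integrator."""
    t_end = 5e-12
    tr = dp.integrate(system10, dp.ForcingSpec(), t_end=t_end, dt=1e-14, n_out=10)
    y = rk4_oracle(system10, 1e-22, t_end, 1e-15)
    phi = np.concatenate([tr.phi[-1, 0], tr.phi[-1, 1]])
    assert np.abs(phi - y[:20]).max() < 1e-8


def test_adaptive_backend_agrees_with_fixed_step(system10):
    t_end = 2e-12
    tr_rk4 = dp.integrate(system10, dp.ForcingSpec(), t_end=t_end, n_out=50)
    tr_sp = dp.integrate(
        system10, dp.ForcingSpec(), t_end=t_end, n_out=51, method="scipy",
        rtol=1e-10, atol=1e-16,
    )
    assert np.abs(tr_sp.phi[-1] - tr_rk4.phi[-1]).max() < 1e-7


def test_step_halving_self_convergence(system10):
    t_end = 1e-11
    a = dp.integrate(system10, dp.ForcingSpec(), t_end=t_end, dt=1e-14, n_out=1)
    b = dp.integrate(system10, dp.ForcingSpec(), t_end=t_end, dt=5e-15, n_out=1)
    assert np.abs(a.phi[-1] - b.phi[-1]).max() < 1e-6


def test_pair_oscillation_frequency_matches_closed_form():
    """An isolated A·T pair (uniform mode of a homogeneous 2-chain) must
    oscillate at the eigenfrequency of the analytically linearized 2x2
    system; the unstable mode's growth rate is checked too."""
    s = dp.build_system("AA", lam=1.0)
    s.beta1[:] = 0.0
    s.beta2[:] = 0.0
    phi0 = np.zeros((2, 2))
    phi0[0, :] = 1e-4
    tr = dp.integrate(
        s, dp.ForcingSpec(mode="zero"), t_end=6e-12, dt=1e-14,
        initial=dp.initial_state(s, phi0=phi0), n_out=0,
    )
    mu = dp.modal_frequencies(tr.phi[:, 0, 0], 1e-14, n_modes=4)
    measured_osc = max(abs(m.imag) for m in mu)
    measured_growth = max(m.real for m in mu)
    osc, growth = pair_mode_rates()
    assert measured_osc == pytest.approx(osc[0], rel=1e-3)
    assert measured_growth == pytest.approx(growth[0], rel=1e-3)


def test_uniform_state_of_homogeneous_chain_stays_uniform():
    s = dp.build_system("AAAA", lam=1.0)
    phi0 = np.zeros((2, 4))
    phi0[0, :] = 1e-4
    tr = dp.integrate(
        s, dp.ForcingSpec(mode="zero"), t_end=1e-12, dt=1e-14,
        initial=dp.initial_state(s, phi0=phi0), n_out=10,
    )
    assert np.abs(tr.phi - tr.phi[:, :, :1]).max() == 0.0


def test_linearized_steady_state_is_zero_without_torque():
    s = _polyA(6)
    with pytest.warns(RuntimeWarning):  # printed signs: indefinite stiffness
        prof = dp.linearized_steady_state(
            s, dp.ForcingSpec(mode="constant", amplitude=0.0)
        )
    np.testing.assert_array_equal(prof, np.zeros((2, 6)))


def test_linearized_steady_state_is_linear_in_torque():
    s = dp.build_system("ACGTGA")
    with pytest.warns(RuntimeWarning):  # printed signs: indefinite stiffness
        p1 = dp.linearized_steady_state(s, dp.ForcingSpec(amplitude=1e-22))
        p2 = dp.linearized_steady_state(s, dp.ForcingSpec(amplitude=2e-22))
    np.testing.assert_allclose(p2, 2.0 * p1, rtol=1e-12)


def test_printed_signs_make_static_profile_a_saddle():
    s = _polyA(6)
    with pytest.warns(RuntimeWarning, match="indefinite"):
        dp.linearized_steady_state(s, dp.ForcingSpec())


def test_symmetrized_variant_relaxes_onto_the_static_profile():
    """With the strand-2 sign mirrored to match strand 1 the zero state is
    stable, and damped integration converges to the linear static solve."""
    s = _polyA(10, sign_convention="symmetrized")
    prof = dp.linearized_steady_state(s, dp.ForcingSpec())
    tr = dp.integrate(s, dp.ForcingSpec(), t_end=3e-9, n_out=10)
    np.testing.assert_allclose(tr.phi[-1], prof, rtol=1e-3)


def test_rejects_non_constant_forcing_for_static_solve():
    s = _polyA(4)
    with pytest.raises(ValueError, match="constant"):
        dp.linearized_steady_state(s, dp.ForcingSpec(mode="zero"))


def test_kinetic_energy_decays_after_the_transient():
    """With no applied torque and lambda > 0 the vibration energy pumped in
    by the initial displacement (and by the strand-2 pair-flip transient of
    the published sign structure) is dissipated: late-window kinetic energy
    falls well below the post-transient level, faster at higher lambda."""
    seq = "ACGTA"

    def late_energy(lam):
        s = dp.build_system(seq, lam=lam)
        phi0 = np.zeros((2, 5))
        phi0[0, :] = 1e-3
        tr = dp.integrate(
            s, dp.ForcingSpec(mode="zero"), t_end=1.2e-9,
            initial=dp.initial_state(s, phi0=phi0), n_out=600,
        )
        I = np.stack([s.I1, s.I2])
        ke = 0.5 * (I[None] * tr.omega**2).sum(axis=(1, 2))
        third = len(ke) // 3
        return ke[third : 2 * third].mean(), ke[-third:].mean()

    mid1, late1 = late_energy(1.0)
    assert late1 < 0.2 * mid1
    _, late_low = late_energy(0.25)
    assert late1 < late_low


def test_forcing_target_masks_restrict_torque():
    f = dp.ForcingSpec(strands=(1,), sites=(1, 3))
    m1, m2 = f.target_masks(5)
    np.testing.assert_array_equal(m1, [0, 1, 1, 0, 0])
    np.testing.assert_array_equal(m2, np.zeros(5))


def test_forcing_validation():
    with pytest.raises(ValueError, match="mode"):
        dp.ForcingSpec(mode="ramp")
    with pytest.raises(ValueError, match="omega"):
        dp.ForcingSpec(mode="cosine", omega=-1.0)
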