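import numpy as np
import pytest

import sefmd
from sefmd.decoupling import DecouplingSpec
from sefmd.diagnostics import (
    canonical_j,
    energy_drift,
    energy_series,
    monodromy_by_finite_difference,
    quadratic_decoupled_energy_series,
    reversibility_deviation,
    symplectic_deviation,
)
from sefmd.sef_integrators import PhaseState, SimulationConfig, propagate


def direct_spec(pairs):
    return DecouplingSpec(
        group_pairs=tuple(
            (frozenset(a), frozenset(b), alpha) for a, b, alpha in pairs
        ),
        frame="normal_mode",
    )


class TestCanonicalJ:
    def test_defining_properties(self):
        j = canonical_j(3)
        np.testing.assert_array_equal(j @ j, -np.eye(6))
        np.testing.assert_array_equal(j.T, -j)


class TestSymplecticDeviation:
    def test_identity(self):
        assert symplectic_deviation(np.eye(4)) == 0.0

    def test_scaled_identity_forced_arithmetic(self):
        # 1-DOF M = 2 I: M^T J M - J = 3 J, so the max-abs entry is 3
        assert symplectic_deviation(2.0 * np.eye(2)) == pytest.approx(3.0)

    def test_analytic_harmonic_flow_is_symplectic(self):
        omega = 0.013
        for t in (0.0, 57.0, 431.0):
            m = np.array([
                [np.cos(omega * t), np.sin(omega * t) / omega],
                [-omega * np.sin(omega * t), np.cos(omega * t)],
            ])
            assert symplectic_deviation(m) <= 1e-12

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            symplectic_deviation(np.eye(3))


class TestMonodromyFiniteDifference:
    def test_free_particle_closed_form(self):
        surface = sefmd.build_harmonic_surface(np.zeros((2, 2)), [0.0, 0.0])
        init = PhaseState([0.1, -0.2], [0.3, 0.4], [0.0, 0.0], [0.1, -0.2])
        cfg = SimulationConfig(dt=10.0, n_steps=50, scheme="SEF2")
        trace = monodromy_by_finite_difference(init, surface, cfg,
                                               check_convergence=False)
        t = 500.0
        expected = np.eye(4)
        expected[:2, 2:] = t * np.eye(2)
        np.testing.assert_allclose(trace.matrices[-1], expected, atol=1e-7)
        np.testing.assert_array_equal(trace.matrices[0], np.eye(4))

    def test_harmonic_analytic_flow(self):
        omega = 0.01
        surface = sefmd.build_harmonic_surface([[omega**2]], [0.0])
        init = PhaseState([0.0], [np.sqrt(omega)], [0.0], [0.0])
        cfg = SimulationConfig(dt=1.0, n_steps=200, scheme="SE4")
        trace = monodromy_by_finite_difference(init, surface, cfg,
                                               check_convergence=False)
        t = 200.0
        expected = np.array([
            [np.cos(omega * t), np.sin(omega * t) / omega],
            [-omega * np.sin(omega * t), np.cos(omega * t)],
        ])
        # dt = 1 au makes the integrator error ~ (w dt)^4 ~ 1e-8-level
        np.testing.assert_allclose(trace.matrices[-1], expected, atol=1e-6)

    def test_convergence_check(self, coupled_pair):
        basis = sefmd.dof_normal_modes(coupled_pair)
        init = sefmd.site_zpe_state(basis, coupled_pair.reference_geometry)
        cfg = SimulationConfig(dt=10.0, n_steps=100, scheme="SEF2")
        trace = monodromy_by_finite_difference(init, coupled_pair, cfg)
        assert trace.converged
        assert trace.convergence_change < 1e-5

    @pytest.mark.parametrize("scheme", ["SE2", "SE4", "SEF2", "SEF4"])
    @pytest.mark.parametrize("alpha", [1.0, 0.0])
    def test_symplecticity_preserved_with_and_without_decoupling(
        self, coupled_pair, scheme, alpha
    ):
        """Y(t) stays at roundoff level over 3000 steps of 10 au for every
        scheme, decoupled or not."""
        basis = sefmd.dof_normal_modes(coupled_pair)
        init = sefmd.site_zpe_state(basis, coupled_pair.reference_geometry)
        spec = None if alpha == 1.0 else direct_spec([({0}, {1}, alpha)])
        cfg = SimulationConfig(dt=10.0, n_steps=3000, scheme=scheme, spec=spec)
        trace = monodromy_by_finite_difference(
            init, coupled_pair, cfg, basis=basis, check_convergence=False
        )
        assert trace.max_symplectic_deviation() < 1e-6


class TestReversibility:
    def test_zero_steps(self, coupled_pair):
        basis = sefmd.dof_normal_modes(coupled_pair)
        init = sefmd.site_zpe_state(basis, coupled_pair.reference_geometry)
        cfg = SimulationConfig(dt=10.0, n_steps=10, scheme="SEF2")
        assert reversibility_deviation(init, coupled_pair, cfg, t_half=0.0) == 0.0

    @pytest.mark.parametrize("scheme", ["SEF2", "SEF4"])
    @pytest.mark.parametrize("alpha", [1.0, 0.5, 0.0])
    def test_quadratic_round_trip_exact(self, coupled_pair, scheme, alpha):
        """On quadratic surfaces the SEF evolution is exactly time
        reversible (deviation at roundoff, far below 1e-10)."""
        basis = sefmd.dof_normal_modes(coupled_pair)
        init = sefmd.site_zpe_state(basis, coupled_pair.reference_geometry)
        spec = None if alpha == 1.0 else direct_spec([({0}, {1}, alpha)])
        cfg = SimulationConfig(dt=10.0, n_steps=600, scheme=scheme, spec=spec)
        dev = reversibility_deviation(init, coupled_pair, cfg, t_half=6000.0,
                                      basis=basis)
        assert dev <= 1e-10

    def test_morse_se2_round_trip(self):
        """Time-symmetric SE2 on an anharmonic Morse oscillator retraces
        to roundoff over the standard protocol (T = 6000 au, dt = 10)."""
        surface = sefmd.build_morse_surface(0.1, 0.04)
        basis = sefmd.dof_normal_modes(surface)
        init = sefmd.site_zpe_state(basis, surface.reference_geometry)
        cfg = SimulationConfig(dt=10.0, n_steps=600, scheme="SE2")
        dev = reversibility_deviation(init, surface, cfg, t_half=6000.0)
        assert dev <= 1e-8

    def test_requires_commensurate_t_half(self, coupled_pair):
        basis = sefmd.dof_normal_modes(coupled_pair)
        init = sefmd.site_zpe_state(basis, coupled_pair.reference_geometry)
        cfg = SimulationConfig(dt=10.0, n_steps=10, scheme="SEF2")
        with pytest.raises(ValueError):
            reversibility_deviation(init, coupled_pair, cfg, t_half=15.0)


class TestEnergySeries:
    def test_exact_harmonic_flow_constant(self):
        omega = 0.01
        surface = sefmd.build_harmonic_surface([[omega**2]], [0.0])
        t = np.arange(100) * 10.0
        q = (np.sqrt(omega) / omega) * np.sin(omega * t)
        p = np.sqrt(omega) * np.cos(omega * t)
        traj = sefmd.Trajectory(
            times=t, q=q[:, None], p=p[:, None],
            f_tilde=np.zeros((100, 1)), energies=np.zeros(100),
            dt=10.0, scheme="exact",
        )
        e = energy_series(traj, surface)
        assert np.max(np.abs(e - 0.5 * omega)) < 1e-12

    def test_sef2_morse_drift_free(self):
        surface = sefmd.build_morse_surface(0.1, 0.04)
        basis = sefmd.dof_normal_modes(surface)
        init = sefmd.site_zpe_state(basis, surface.reference_geometry)
        cfg = SimulationConfig(dt=10.0, n_steps=3000, scheme="SEF2")
        traj = propagate(init, surface, cfg)
        summary = energy_drift(traj.energies, 10.0)
        assert abs(summary["drift_slope_per_step"]) < 1e-10

    def test_sef2_vs_se2_oscillation_comparison(self, coupled_pair):
        """Informational: the SEF2 energy oscillation is of the same
        order of magnitude as SE2's (the force is locally harmonic)."""
        basis = sefmd.dof_normal_modes(coupled_pair)
        init = sefmd.site_zpe_state(basis, coupled_pair.reference_geometry)
        amps = {}
        for scheme in ("SE2", "SEF2"):
            cfg = SimulationConfig(dt=10.0, n_steps=1000, scheme=scheme)
            traj = propagate(init, coupled_pair, cfg, basis=basis)
            amps[scheme] = energy_drift(traj.energies, 10.0)["amplitude"]
        assert 0.1 < amps["SEF2"] / amps["SE2"] < 10.0

    @pytest.mark.parametrize("alpha", [1.0, 0.5, 0.0])
    def test_decoupled_invariant_conserved_on_quadratics(self, coupled_pair, alpha):
        """The pair-decoupled Hamiltonian's discrete invariant is conserved
        to roundoff by SEF2 for every alpha."""
        basis = sefmd.dof_normal_modes(coupled_pair)
        init = sefmd.site_zpe_state(basis, coupled_pair.reference_geometry)
        spec = None if alpha == 1.0 else direct_spec([({0}, {1}, alpha)])
        cfg = SimulationConfig(dt=10.0, n_steps=1000, scheme="SEF2", spec=spec)
        traj = propagate(init, coupled_pair, cfg, basis=basis)
        shadow = quadratic_decoupled_energy_series(
            traj, coupled_pair, spec, basis=basis, shadow=True
        )
        assert np.max(shadow) - np.min(shadow) < 1e-14
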